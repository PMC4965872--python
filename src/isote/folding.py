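"""RNA secondary-structure folding engines.

Two interchangeable engines compute the minimum free energy (MFE) of short
RNA windows, and where supported the ensemble free energy (EFE, the
Boltzmann-weighted free energy of all structures, always <= MFE):

* :class:`ViennaEngine` wraps the ViennaRNA thermodynamic (Turner parameter)
  package at 37 degrees C, including the partition function for EFE.  This is
  the engine on which absolute kcal/mol stability thresholds are meaningful.
* :class:`StackingEngine` is a self-contained simplified nearest-neighbour
  model (per-pair energies plus a stacking bonus, Nussinov-style dynamic
  programming).  It ranks structured against unstructured windows correctly
  and keeps the package usable without ViennaRNA, but its energies are not on
  the Turner scale and it has no partition function.
"""

from __future__ import annotations

import numpy as np

_PAIR_ENERGY = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}
_STACK_BONUS = -1.0
_MIN_LOOP = 3


def to_rna(seq: str) -> str:
    """Uppercase and transcribe DNA input to the RNA alphabet (T -> U)."""
    return seq.upper().replace("T", "U")


class StackingEngine:
    """Simplified stacking-energy folding (no partition function)."""

    supports_efe = False
    name = "builtin"

    def fold(self, seq: str) -> tuple[float, None]:
        s = to_rna(seq)
        n = len(s)
        if n < _MIN_LOOP + 2:
            return 0.0, None
        big = np.inf
        # V[i, j]: best energy with (i, j) paired; W[i, j]: best energy on [i, j]
        V = np.full((n, n), big)
        W = np.zeros((n, n))
        for span in range(_MIN_LOOP + 1, n):
            for i in range(0, n - span):
                j = i + span
                e = _PAIR_ENERGY.get((s[i], s[j]))
                if e is not None:
                    inner = W[i + 1, j - 1]
                    if V[i + 1, j - 1] + _STACK_BONUS < inner:
                        inner = V[i + 1, j - 1] + _STACK_BONUS
                    V[i, j] = e + inner
                best = min(W[i + 1, j], W[i, j - 1], V[i, j])
                split = W[i, i:j] + W[i + 1 : j + 1, j]
                if split.size:
                    best = min(best, float(split.min()))
                W[i, j] = best
        return float(min(W[0, n - 1], 0.0)), None


class ViennaEngine:
    """ViennaRNA thermodynamic folding at 37 C, with ensemble free energy."""

    supports_efe = True
    name = "vienna"

    def __init__(self) -> None:
        import RNA  # noqa: deferred so the package imports without ViennaRNA

        self._rna = RNA

    def fold(self, seq: str) -> tuple[float, float]:
        fc = self._rna.fold_compound(to_rna(seq))
        _, mfe = fc.mfe()
        fc.exp_params_rescale(mfe)
        _, efe = fc.pf()
        return float(mfe), float(efe)


def get_engine(name: str = "auto"):
    """Return a folding engine: ``vienna``, ``builtin``, or ``auto`` (vienna
    when importable, builtin otherwise)."""
    if name == "builtin":
        return StackingEngine()
    if name == "vienna":
        return ViennaEngine()
    if name == "auto":
        try:
            return ViennaEngine()
        except ImportError:
            return StackingEngine()
    raise ValueError(f"unknown folding engine {name!r}")
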