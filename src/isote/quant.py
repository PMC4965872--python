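"""Spike-in normalization and translational-efficiency (TE) quantification.

Polysome profiling separates mRNAs on a sucrose gradient into seven fractions
by the number of bound ribosomes: free RNP, 40S/60S, 80S monosome, and four
polysome fractions.  Each fraction *j* is assigned an average ribosome load
``r_j``; for a TSS isoform *i* with normalized per-fraction 5' tag counts
``C_ij`` the quantities of interest are

    T_i  = sum_j C_ij                 (total isoform abundance)
    R_i  = sum_j r_j * C_ij           (total associated ribosomes)
    TE_i = R_i / l_i / T_i            (ribosomes per mRNA per nt of ORF)

where ``l_i`` is the ORF length in nt.  Counts are made comparable across
fractions by scaling with per-fraction factors derived from exogenous
spike-in RNA clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Average ribosomes per mRNA in each of the seven gradient fractions:
#: free RNP, 40S/60S, 80S monosome, then polysome fractions.
RIBOSOME_WEIGHTS = np.array([0.0, 0.0, 1.0, 2.5, 4.5, 7.5, 12.0])

N_FRACTIONS = 7

#: Minimum tag count (strict) a spike cluster must reach in every fraction of
#: every replicate to qualify for factor estimation.
SPIKE_MIN_TAGS = 10

#: Quantile of qualifying spike-cluster counts used as the per-fraction factor.
SPIKE_QUANTILE = 0.75


@dataclass
class IsoformQuant:
    """Per-isoform TE quantification on a single replicate."""

    isoform: str
    counts: np.ndarray  # normalized counts, length 7
    orf_length: int
    total: float = field(init=False)            # T_i
    ribosomes: float = field(init=False)        # R_i
    ribosomes_per_mrna: float = field(init=False)
    te: float = field(init=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (N_FRACTIONS,):
            raise ValueError(f"expected {N_FRACTIONS} fraction counts, got {c.shape}")
        if np.any(c < 0):
            raise ValueError("negative fraction counts")
        if self.orf_length <= 0:
            raise ValueError("ORF length must be positive")
        self.counts = c
        self.total = float(c.sum())
        if self.total == 0:
            raise ValueError(f"isoform {self.isoform}: zero total count, TE undefined")
        self.ribosomes = float(RIBOSOME_WEIGHTS @ c)
        self.ribosomes_per_mrna = self.ribosomes / self.total
        self.te = self.ribosomes / self.orf_length / self.total


def spike_factors(spike_counts: pd.DataFrame) -> dict[int, np.ndarray]:
    """Per-fraction normalization factors from spike-in cluster counts.

    Parameters
    ----------
    spike_counts
        Long-format table with columns ``cluster``, ``replicate``,
        ``fraction`` (1-based, 1..7) and ``count``.

    Returns
    -------
    dict mapping replicate id to a length-7 array of factors.  Factor *j* is
    the upper quartile of counts, in fraction *j* of that replicate, over the
    spike clusters that have strictly more than 10 tags in every fraction of
    every replicate.  Factors are rescaled by their within-replicate geometric
    mean so normalization preserves the overall count scale:
    ``normalized = raw / factor_j * gmean(factors)``.
    """
    required = {"cluster", "replicate", "fraction", "count"}
    if not required.issubset(spike_counts.columns):
        raise ValueError(f"spike table must have columns {sorted(required)}")
    wide = spike_counts.pivot_table(
        index="cluster", columns=["replicate", "fraction"], values="count", fill_value=0
    )
    qualifying = wide.index[(wide > SPIKE_MIN_TAGS).all(axis=1)]
    if len(qualifying) == 0:
        raise ValueError(
            "no spike-in cluster has more than "
            f"{SPIKE_MIN_TAGS} tags in every fraction of every replicate; "
            "relax the threshold explicitly if the spike-in depth is low"
        )
    out: dict[int, np.ndarray] = {}
    replicates = sorted({r for r, _ in wide.columns})
    for rep in replicates:
        factors = np.array(
            [
                float(np.quantile(wide.loc[qualifying, (rep, j)], SPIKE_QUANTILE))
                for j in range(1, N_FRACTIONS + 1)
            ]
        )
        if np.any(factors <= 0):
            raise ValueError(f"replicate {rep}: non-positive spike factor")
        out[rep] = factors
    return out


def normalization_multipliers(factors: np.ndarray) -> np.ndarray:
    """Per-fraction multipliers ``gmean(factors) / factor_j`` (scale-preserving)."""
    factors = np.asarray(factors, dtype=float)
    gmean = float(np.exp(np.mean(np.log(factors))))
    return gmean / factors


def normalize_counts(raw: np.ndarray, factors: np.ndarray) -> np.ndarray:
    """Apply spike-in normalization to a 7-vector (or (n,7) matrix) of raw counts."""
    return np.asarray(raw, dtype=float) * normalization_multipliers(factors)


def isoform_te(counts: np.ndarray, orf_length: int, isoform: str = "") -> IsoformQuant:
    """TE quantification for one isoform from its normalized 7-fraction counts."""
    return IsoformQuant(isoform=isoform, counts=np.asarray(counts, float), orf_length=orf_length)


def gene_te(isoform_counts: list[np.ndarray], orf_length: int, gene: str = "") -> IsoformQuant:
    """Gene-level TE: counts summed across the gene's isoforms per fraction."""
    if not isoform_counts:
        raise ValueError("gene has no isoforms")
    summed = np.sum([np.asarray(c, float) for c in isoform_counts], axis=0)
    return isoform_te(summed, orf_length, isoform=gene)


def leave_one_fraction_out(counts: np.ndarray, orf_length: int, leave: int) -> IsoformQuant:
    """TE recomputed over six fractions with fraction ``leave`` (0-based) removed.

    The ribosome weights of the remaining fractions are unchanged.
    """
    if not 0 <= leave < N_FRACTIONS:
        raise ValueError("leave must be a 0-based fraction index in [0, 7)")
    c = np.asarray(counts, dtype=float).copy()
    c[leave] = 0.0
    return isoform_te(c, orf_length)


def monosome_polysome_ratio(counts: np.ndarray) -> float:
    """Abundance ratio of the 80S monosome fraction to the summed polysome fractions.

    Returns NaN when the polysome sum is zero (ratio undefined).
    """
    c = np.asarray(counts, dtype=float)
    poly = c[3:].sum()
    if poly == 0:
        return float("nan")
    return float(c[2] / poly)
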