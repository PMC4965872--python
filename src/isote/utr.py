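"""5'UTR reconstruction and cis-element feature extraction.

A TSS isoform's mature 5'UTR runs from its cap site to the main start codon
(exclusive).  Where splicing events overlap that span, the percent-spliced-in
(PSI, here the fraction of transcripts *retaining* the event region) decides
whether the region is part of the mature UTR: events with PSI <= 0.1 are
constitutively removed, PSI >= 0.9 constitutively retained, and anything in
between leaves the UTR sequence ambiguous, excluding the isoform from
sequence analyses.

Features extracted from the mature UTR:

* uORFs — upstream AUGs with an in-frame stop codon still inside the UTR;
* uAUGs — upstream AUGs without such a stop, split by reading frame relative
  to the main ORF (in-frame iff the distance to the main AUG is 0 mod 3);
* 5' TOP — a C at the cap site followed by at least four pyrimidines;
* hexamer occurrences over the 3,841 hexamers that do not contain AUG;
* local RNA structure — MFE/EFE of the 50-nt cap window and the minimum over
  downstream 50-nt sliding windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .folding import get_engine, to_rna

STOP_CODONS = {"UAA", "UAG", "UGA"}

#: Lexicographically ordered hexamers (A<C<G<U) without AUG as a substring.
AUG_FREE_HEXAMERS: tuple[str, ...] = tuple(
    "".join(h) for h in product("ACGU", repeat=6) if "AUG" not in "".join(h)
)
_HEXAMER_INDEX = {h: i for i, h in enumerate(AUG_FREE_HEXAMERS)}

PSI_REMOVED_MAX = 0.1
PSI_RETAINED_MIN = 0.9


@dataclass
class SpliceEvent:
    """A splicing event in a 5'UTR, treated as intron-retention PSI.

    ``splice_in`` reads support retention of the region, ``splice_out`` reads
    support its excision.  ``annotation`` is one of ``constitutive``
    (annotated constitutively spliced out), ``alternative`` (annotated
    alternative) or ``novel``.
    """

    chrom: str
    strand: str
    donor0: int
    acceptor0: int
    splice_out: int
    splice_in: int
    annotation: str = "novel"

    def __post_init__(self) -> None:
        if self.splice_out < 0 or self.splice_in < 0:
            raise ValueError("negative read counts")
        if self.acceptor0 <= self.donor0:
            raise ValueError("acceptor must lie 3' of donor (genomic coordinates)")
        if self.annotation not in {"constitutive", "alternative", "novel"}:
            raise ValueError(f"unknown annotation status {self.annotation!r}")


def compute_psi(event: SpliceEvent) -> tuple[float, str]:
    """PSI with annotation pseudo-reads, plus the trichotomized status.

    Annotated-constitutive events get 10 pseudo splice-out reads; annotated
    alternative events get 5 splice-in and 5 splice-out pseudo-reads; novel
    events get none.  Status is ``removed`` (PSI <= 0.1), ``retained``
    (PSI >= 0.9) or ``ambiguous``.
    """
    s_in, s_out = float(event.splice_in), float(event.splice_out)
    if event.annotation == "constitutive":
        s_out += 10.0
    elif event.annotation == "alternative":
        s_in += 5.0
        s_out += 5.0
    total = s_in + s_out
    if total == 0:
        return float("nan"), "ambiguous"
    psi = s_in / total
    if psi <= PSI_REMOVED_MAX:
        return psi, "removed"
    if psi >= PSI_RETAINED_MIN:
        return psi, "retained"
    return psi, "ambiguous"


@dataclass
class UtrModel:
    """Mature 5'UTR of one TSS isoform (cap to main start codon, exclusive)."""

    isoform: str
    chrom: str
    strand: str
    tss0: int
    start_codon0: int
    segments: list[tuple[int, int]] = field(default_factory=list)
    sequence: str = ""
    status: str = "resolved"  # or "ambiguous-excluded"

    @property
    def length(self) -> int:
        return len(self.sequence)


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Genomic slice from a dict of strings or a pyfaidx.Fasta-like object."""
    seq = genome[chrom]
    if isinstance(seq, str):
        return seq[start:end]
    return str(seq[start:end])


_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def reconstruct_utr(
    isoform: str,
    chrom: str,
    strand: str,
    tss0: int,
    start_codon0: int,
    events: list[SpliceEvent],
    genome,
) -> UtrModel:
    """Build the mature 5'UTR sequence between a TSS and the main start codon.

    ``start_codon0`` is the genomic position of the first base of the main
    AUG (on the minus strand, the base with the highest coordinate).  With no
    splicing the UTR is the genomic span; events with status ``removed`` are
    excised; an ``ambiguous`` event overlapping the span marks the whole
    isoform ``ambiguous-excluded``.  The sequence is emitted 5'->3' in
    transcript orientation.
    """
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    if strand == "+":
        span = (tss0, start_codon0)
    else:
        span = (start_codon0 + 1, tss0 + 1)
    if span[0] >= span[1]:
        raise ValueError(
            f"isoform {isoform}: TSS is not 5' of the start codon "
            "(downstream TSS classes are out of scope here)"
        )
    model = UtrModel(isoform, chrom, strand, tss0, start_codon0)
    removed: list[tuple[int, int]] = []
    for ev in events:
        if ev.chrom != chrom or ev.strand != strand:
            continue
        if ev.acceptor0 <= span[0] or ev.donor0 >= span[1]:
            continue
        _, status = compute_psi(ev)
        if status == "ambiguous":
            model.status = "ambiguous-excluded"
            return model
        if status == "removed":
            removed.append((max(ev.donor0, span[0]), min(ev.acceptor0, span[1])))
    removed.sort()
    segments: list[tuple[int, int]] = []
    cursor = span[0]
    for r0, r1 in removed:
        if r0 > cursor:
            segments.append((cursor, r0))
        cursor = max(cursor, r1)
    if cursor < span[1]:
        segments.append((cursor, span[1]))
    seq = "".join(_fetch(genome, chrom, s, e) for s, e in segments)
    if strand == "-":
        seq = revcomp(seq)
    model.segments = segments
    model.sequence = to_rna(seq)
    return model


def scan_augs(utr: str) -> list[tuple[int, str]]:
    """Classify every AUG in a 5'UTR sequence.

    The UTR sequence excludes the main AUG, which sits immediately 3' of it.
    Each upstream AUG is a ``uorf`` when an in-frame stop codon lies fully
    within the UTR, otherwise a ``uaug_in`` / ``uaug_out`` depending on
    whether its distance to the main AUG (= UTR length - AUG position) is
    divisible by 3.  Returns ``[(position, kind), ...]`` in 5'->3' order.
    """
    seq = to_rna(utr)
    if any(c not in "ACGU" for c in seq):
        raise ValueError("non-nucleotide characters in UTR sequence")
    n = len(seq)
    out: list[tuple[int, str]] = []
    for i in range(n - 2):
        if seq[i : i + 3] != "AUG":
            continue
        has_stop = any(
            seq[k : k + 3] in STOP_CODONS for k in range(i + 3, n - 2, 3)
        )
        if has_stop:
            out.append((i, "uorf"))
        elif (n - i) % 3 == 0:
            out.append((i, "uaug_in"))
        else:
            out.append((i, "uaug_out"))
    return out


def find_uorfs(utr: str) -> tuple[int, int, int]:
    """Count uORFs and in/out-of-frame uAUGs in a 5'UTR.

    Returns ``(n_uorf, n_uaug_in_frame, n_uaug_out_of_frame)``; see
    :func:`scan_augs` for the classification rule.
    """
    kinds = [k for _, k in scan_augs(utr)]
    return kinds.count("uorf"), kinds.count("uaug_in"), kinds.count("uaug_out")


def detect_top(utr: str) -> bool:
    """True iff the cap site is a C followed by at least 4 pyrimidines."""
    seq = to_rna(utr)
    if len(seq) < 5:
        return False
    return seq[0] == "C" and all(c in "CU" for c in seq[1:5])


def count_hexamers(utr: str) -> np.ndarray:
    """Overlapping occurrence counts of the 3,841 AUG-free hexamers.

    Returns a vector aligned with :data:`AUG_FREE_HEXAMERS`; windows that do
    contain AUG are not counted anywhere.
    """
    seq = to_rna(utr)
    counts = np.zeros(len(AUG_FREE_HEXAMERS), dtype=np.int32)
    for i in range(len(seq) - 5):
        idx = _HEXAMER_INDEX.get(seq[i : i + 6])
        if idx is not None:
            counts[idx] += 1
    return counts


@dataclass
class FoldProfile:
    cap_mfe: float
    cap_efe: float | None
    min_window_mfe: float          # NaN when the UTR has no downstream window
    min_window_efe: float | None
    cap_stable: bool
    downstream_stable: bool


def fold_windows(
    utr: str,
    engine=None,
    cap_thresh: float = -30.0,
    window_thresh: float = -35.0,
    window: int = 50,
    step: int = 1,
) -> FoldProfile:
    """Fold the cap window and downstream sliding windows of a 5'UTR.

    The cap window is the first ``window`` nt (the whole UTR when shorter);
    downstream windows are every ``window``-nt window starting at offsets
    ``step, 2*step, ...``.  Stability flags use strict inequality against the
    thresholds; EFE values are reported when the engine supports the
    partition function.
    """
    if engine is None:
        engine = get_engine("auto")
    seq = to_rna(utr)
    if not seq:
        raise ValueError("empty UTR sequence")
    cap_mfe, cap_efe = engine.fold(seq[:window])
    min_mfe = float("nan")
    min_efe: float | None = float("nan") if engine.supports_efe else None
    for start in range(step, len(seq) - window + 1, step):
        mfe, efe = engine.fold(seq[start : start + window])
        if not (min_mfe <= mfe):  # also catches the initial NaN
            min_mfe = mfe
        if engine.supports_efe and not (min_efe <= efe):
            min_efe = efe
    return FoldProfile(
        cap_mfe=cap_mfe,
        cap_efe=cap_efe,
        min_window_mfe=min_mfe,
        min_window_efe=min_efe,
        cap_stable=cap_mfe < cap_thresh,
        downstream_stable=bool(np.isfinite(min_mfe) and min_mfe < window_thresh),
    )


@dataclass
class UtrFeatureVector:
    """All cis-element features of one mature 5'UTR."""

    utr_length: int
    n_uorf: int
    n_uaug_in_frame: int
    n_uaug_out_of_frame: int
    has_top: bool
    fold: FoldProfile
    hexamers: np.ndarray


def extract_features(
    utr: str,
    engine=None,
    cap_thresh: float = -30.0,
    window_thresh: float = -35.0,
    window: int = 50,
    step: int = 1,
) -> UtrFeatureVector:
    """Full feature extraction for one mature 5'UTR sequence."""
    seq = to_rna(utr)
    n_uorf, n_in, n_out = find_uorfs(seq)
    return UtrFeatureVector(
        utr_length=len(seq),
        n_uorf=n_uorf,
        n_uaug_in_frame=n_in,
        n_uaug_out_of_frame=n_out,
        has_top=detect_top(seq),
        fold=fold_windows(seq, engine, cap_thresh, window_thresh, window, step),
        hexamers=count_hexamers(seq),
    )


def divergent_region(long_utr: UtrModel | str, short_utr: UtrModel | str) -> str | None:
    """The 5' sequence unique to the longer isoform of a shared-gene pair.

    Both mature UTRs must share their 3' portion (the shorter UTR is a suffix
    of the longer).  Returns the 5' divergent segment, ``""`` for identical
    UTRs, or ``None`` when the suffix relation fails (e.g. splicing differs
    downstream), in which case the pair is excluded from divergent-region
    analyses.
    """
    long_seq = long_utr.sequence if isinstance(long_utr, UtrModel) else to_rna(long_utr)
    short_seq = short_utr.sequence if isinstance(short_utr, UtrModel) else to_rna(short_utr)
    if len(short_seq) > len(long_seq):
        raise ValueError("first argument must be the longer UTR")
    if not long_seq.endswith(short_seq):
        return None
    return long_seq[: len(long_seq) - len(short_seq)]
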