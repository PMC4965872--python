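"""Synthetic polysome-fractionated 5' end sequencing data with full ground truth.

The generator emulates the assay end to end: multi-TSS genes whose isoforms
differ only in their 5'UTRs, per-mRNA ribosome loads drawn from a truncated
Poisson and binned into the seven gradient fractions, 5' tag positions
scattering geometrically downstream of the true cap site, uniform background
tags within expressed gene spans, per-fraction spike-in depth distortions,
RNA-seq coverage (in tag-equivalent units) and splice junctions with known
PSI, and 5'UTR sequences with planted cis-elements (uORFs, in/out-of-frame
uAUGs, 5' TOP, a stable cap-proximal hairpin, an effect hexamer).

The mapping from per-mRNA ribosome count K to gradient fraction mirrors the
fraction weights used downstream: K=0 goes to the free-RNP / 40S-60S
fractions (split evenly; both carry weight 0), K=1 to the 80S monosome,
K in {2,3} to the first polysome fraction, {4,5} to the second, {6..9} to
the third and K>=10 to the heaviest.

5'UTR background sequence is generated free of AUG and of stop trigrams in
every frame, so planted features are recoverable verbatim and a planted bare
AUG stays a uAUG instead of gaining an accidental in-frame stop.  Sequence
blocks that are concatenated (divergent blocks, retained introns) always end
in C, which no AUG or stop trigram can span, so junctions never create
accidental features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Annotation, Transcript, write_fasta, write_tags, write_bedgraph
from .quant import RIBOSOME_WEIGHTS
from .utr import detect_top, find_uorfs, revcomp, to_rna

FORBIDDEN_TRIGRAMS = ("ATG", "TAA", "TAG", "TGA")
STOPS = ("TAA", "TAG", "TGA")

TOP_MOTIF = "CTTCTC"                       # cap C + 5 pyrimidines
_HAIRPIN_STEM = "GGCGGCGCGGCGGC"           # 14 bp GC stem
HAIRPIN = _HAIRPIN_STEM + "GAAA" + revcomp(_HAIRPIN_STEM)
DEFAULT_EFFECT_HEXAMER = "AATCCC"

#: per-mRNA ribosome count (1..12) -> 0-based fraction index; K=0 is split
#: between fractions 0 and 1 at random.
_K_TO_FRACTION = np.array([1, 2, 3, 3, 4, 4, 5, 5, 5, 5, 6, 6, 6])
MAX_LOAD = 12


def expected_ribosomes_per_mrna(lam: float) -> float:
    """Analytic r-weighted expectation for load K ~ min(Poisson(lam), 12)."""
    from scipy.stats import poisson

    ks = np.arange(0, MAX_LOAD)
    pmf = poisson.pmf(ks, lam)
    tail = poisson.sf(MAX_LOAD - 1, lam)
    weights = np.concatenate([[0.0], RIBOSOME_WEIGHTS[_K_TO_FRACTION[1:MAX_LOAD]]])
    return float(pmf @ weights + tail * RIBOSOME_WEIGHTS[6])


# ---------------------------------------------------------------------------
# Sequence construction
# ---------------------------------------------------------------------------


def random_background(rng: np.random.Generator, length: int) -> str:
    """Random DNA free of ATG and stop trigrams in every frame."""
    bases = "ACGT"
    out: list[str] = []
    while len(out) < length:
        c = bases[rng.integers(4)]
        if len(out) >= 2 and "".join(out[-2:]) + c in FORBIDDEN_TRIGRAMS:
            continue
        out.append(c)
    return "".join(out)


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """Random codons without in-frame stops (CDS body)."""
    codons: list[str] = []
    bases = "ACGT"
    while len(codons) < n:
        c = "".join(bases[rng.integers(4)] for _ in range(3))
        if c in STOPS:
            continue
        codons.append(c)
    return "".join(codons)


class FeaturePlantingError(ValueError):
    pass


def _stop_positions(seq: str) -> list[int]:
    return [i for i in range(len(seq) - 2) if seq[i : i + 3] in STOPS]


def plant_utr_features(
    seq: str,
    features: list,
    rng: np.random.Generator | int | None = None,
    downstream_seq: str = "",
) -> str:
    """Plant cis-element features into an AUG-free background sequence.

    ``features`` is a list of kind strings (``uorf``, ``uaug_in``,
    ``uaug_out``, ``top``, ``structure``) or ``("hexamer", motif)`` tuples.
    ``downstream_seq`` is the mature-UTR sequence between the end of ``seq``
    and the main start codon; it fixes the reading frame of planted uAUGs
    and is scanned so no planted uAUG picks up a downstream in-frame stop.
    The returned sequence has the same length, ends in C (so concatenation
    cannot create AUG or stop trigrams across the junction), contains
    exactly the requested features, and introduces no accidental AUGs; the
    cap site is forced to a purine unless a TOP is requested.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    s = list(seq.upper())
    L = len(s)
    total_len = L + len(downstream_seq)
    occupied: list[tuple[int, int]] = []

    def free(a: int, b: int) -> bool:
        return 0 <= a and b <= L and all(b <= o0 or a >= o1 for o0, o1 in occupied)

    def place(motif: str, lo: int, hi: int, label: str) -> int:
        span = len(motif)
        starts = np.arange(lo, hi - span + 1)
        if len(starts) > 0:
            for start in rng.permutation(starts):
                if free(start, start + span):
                    s[start : start + span] = motif
                    occupied.append((int(start), int(start) + span))
                    return int(start)
        raise FeaturePlantingError(f"cannot place feature {label!r} in {L}-nt UTR")

    kinds: list[tuple[str, object]] = []
    for f in features:
        if isinstance(f, str):
            kinds.append((f, None))
        else:
            kinds.append((f[0], f[1]))
    known = {"uorf", "uaug_in", "uaug_out", "top", "structure", "hexamer"}
    unknown = [k for k, _ in kinds if k not in known]
    if unknown:
        raise ValueError(f"unknown feature kinds {unknown}")

    if ("top", None) in kinds:
        place(TOP_MOTIF, 0, len(TOP_MOTIF), "top")
    elif s[0] == "C":
        s[0] = "G"  # suppress an accidental cap-site TOP

    if ("structure", None) in kinds:
        lo = len(TOP_MOTIF) if ("top", None) in kinds else 0
        place(HAIRPIN, lo, 50, "structure")

    cap_zone = max((b for _, b in occupied), default=0)
    # uORFs first (5' of any uAUG so their stops cannot terminate one)
    uorf_end = cap_zone
    downstream_stops = [L + q for q in _stop_positions(downstream_seq)]
    uorf_stop_starts: list[int] = []
    for kind, _ in kinds:
        if kind == "uorf":
            filler = random_background(rng, 3 * int(rng.integers(1, 5)))
            motif = "ATG" + filler + "TAA"
            start = place(motif, cap_zone, L - 4, "uorf")
            uorf_end = max(uorf_end, start + len(motif))
            uorf_stop_starts.append(start + len(motif) - 3)
    all_stops = sorted(uorf_stop_starts + downstream_stops)
    for kind, _ in kinds:
        if kind in ("uaug_in", "uaug_out"):
            want_in = kind == "uaug_in"
            candidates = [
                i for i in range(uorf_end, L - 4)
                if ((total_len - i) % 3 == 0) == want_in
                and free(i, i + 3)
                and not any(q >= i + 3 and (q - i) % 3 == 0 for q in all_stops)
            ]
            if not candidates:
                raise FeaturePlantingError(f"cannot place feature {kind!r}")
            i = int(rng.choice(candidates))
            s[i : i + 3] = "ATG"
            occupied.append((i, i + 3))
    for kind, payload in kinds:
        if kind == "hexamer":
            motif = str(payload or DEFAULT_EFFECT_HEXAMER)
            place(motif, cap_zone, L - 1, "hexamer")

    # repair any within-block junction artifact (planted block vs background)
    intended_aug = {a for a, b in occupied if "".join(s[a : a + 3]) == "ATG"}
    for _ in range(10):
        dirty = False
        text = "".join(s)
        for p in range(L - 2):
            tri = text[p : p + 3]
            if tri == "ATG" and p not in intended_aug:
                bad = True
            elif tri in STOPS and not any(a <= p and p + 3 <= b for a, b in occupied):
                bad = True
            else:
                bad = False
            if bad:
                for q in range(p, p + 3):
                    if not any(a <= q < b for a, b in occupied):
                        s[q] = "C"
                        dirty = True
                        break
        if not dirty:
            break
    s[L - 1] = "C"  # junction safety: no forbidden trigram contains C first/last
    return "".join(s)


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults encode the conditions the pipeline presumes: ~42% of genes with
    multiple TSSs, log-normal isoform abundances around a few hundred
    copies, ribosome loads spanning the gradient's dynamic range, short
    geometric 5'-end scatter, a uniform within-gene background, mild
    per-fraction spike distortions, and repressive feature penalties with
    uORFs strongest and in-frame uAUGs neutral.
    """

    n_genes: int = 100
    tss_per_gene_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.58, 2: 0.32, 3: 0.10}
    )
    utr_length_range: tuple[int, int] = (60, 300)        # shared 5'UTR block, nt
    divergent_length_range: tuple[int, int] = (80, 400)  # per extra TSS, nt
    abundance_law: tuple[float, float] = (np.log(300.0), 0.6)  # log-normal mu, sigma
    ribosome_lambda_range: tuple[float, float] = (0.5, 9.0)
    tag_scatter: float = 2.0            # mean geometric downstream offset, nt
    background_rate: float = 0.01       # tags per nt per fraction within genes
    spike_factors: np.ndarray = field(
        default_factory=lambda: np.array(
            [[1.0, 1.25, 0.8, 1.1, 0.9, 1.3, 0.75],
             [0.9, 1.1, 1.2, 0.85, 1.05, 0.8, 1.15]]
        )
    )
    n_spike_clusters: int = 60
    rnaseq_coverage: float = 5.0        # tag-equivalent units per nt
    junction_depth: int = 40            # informative RNA-seq reads per event
    splice_prob: float = 0.15
    orf_length_range: tuple[int, int] = (300, 1800)      # nt, multiple of 3
    feature_plant_probs: dict[str, float] = field(
        default_factory=lambda: {
            "uorf": 0.35, "uaug_out": 0.20, "uaug_in": 0.15,
            "top": 0.08, "structure": 0.12, "hexamer": 0.25,
        }
    )
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: {
            "uorf": 0.55, "uaug_out": 0.70, "uaug_in": 1.0,
            "top": 0.60, "structure": 0.65, "hexamer": 0.40,
        }
    )
    effect_hexamer: str = DEFAULT_EFFECT_HEXAMER
    n_replicates: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("need at least one gene")
        probs = self.tss_per_gene_probs
        if not np.isclose(sum(probs.values()), 1.0) or any(
            p < 0 for p in probs.values()
        ):
            raise ValueError("tss_per_gene_probs must be a distribution over {1,2,3}")
        if self.utr_length_range[0] <= 0 or self.divergent_length_range[0] <= 0:
            raise ValueError("UTR length ranges must be positive")
        if self.ribosome_lambda_range[0] < 0:
            raise ValueError("ribosome loads must be non-negative")
        if self.background_rate < 0 or self.tag_scatter < 0:
            raise ValueError("rates must be non-negative")
        for p in self.feature_plant_probs.values():
            if not 0 <= p <= 1:
                raise ValueError("feature probabilities must lie in [0, 1]")
        sf = np.asarray(self.spike_factors, dtype=float)
        if sf.ndim != 2 or sf.shape[1] != 7 or np.any(sf <= 0):
            raise ValueError("spike_factors must be (n_replicates, 7) positive")
        if sf.shape[0] < self.n_replicates:
            raise ValueError("need spike factors for every replicate")


@dataclass
class SimTruth:
    isoforms: pd.DataFrame      # one row per TSS isoform with full ground truth
    genes: pd.DataFrame         # gene, chrom, strand, tss0, start_codon0, orf_length
    events: pd.DataFrame        # splice events with true PSI and status
    spike_factors: np.ndarray   # (n_replicates, 7) applied distortions


@dataclass
class SimulatedDataset:
    genome: dict[str, str]
    annotation: Annotation
    tags: pd.DataFrame
    spikes: pd.DataFrame
    coverage: pd.DataFrame
    junctions: pd.DataFrame
    truth: SimTruth
    config: SimConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        self.annotation.write(outdir / "annotation.bed12", outdir / "genes.tsv")
        write_tags(self.tags, outdir / "tags.tsv")
        self.spikes.to_csv(outdir / "spikes.tsv", sep="\t", index=False)
        write_bedgraph(self.coverage, outdir / "coverage.bedgraph")
        self.junctions.to_csv(outdir / "junctions.tsv", sep="\t", index=False)
        self.truth.isoforms.to_csv(outdir / "truth_isoforms.tsv", sep="\t", index=False)
        self.truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        self.truth.events.to_csv(outdir / "truth_events.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def _draw_features(cfg: SimConfig, rng: np.random.Generator) -> list:
    feats: list = []
    for kind, p in cfg.feature_plant_probs.items():
        if rng.random() < p:
            if kind == "uorf":
                # geometric dose gives the 1 / 2 / >=3 uORF strata
                feats.extend(["uorf"] * int(rng.geometric(0.6)))
            elif kind == "hexamer":
                feats.append(("hexamer", cfg.effect_hexamer))
            else:
                feats.append(kind)
    return feats


def _block_multiplier(cfg: SimConfig, feats: list, include_top: bool) -> float:
    mult = 1.0
    for f in feats:
        kind = f if isinstance(f, str) else f[0]
        if kind == "top" and not include_top:
            continue  # a TOP only acts from the cap site of its own isoform
        mult *= cfg.effect_sizes.get(kind, 1.0)
    return mult


def _load_to_fraction(k: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Map per-mRNA ribosome counts to 0-based fraction indices."""
    k = np.minimum(np.asarray(k), MAX_LOAD)
    frac = _K_TO_FRACTION[np.maximum(k, 1)].copy()
    zero = k == 0
    frac[zero] = rng.integers(0, 2, size=int(zero.sum()))
    return frac


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate a full synthetic dataset plus ground truth.

    Per isoform copy a ribosome load K ~ min(Poisson(lambda), 12) is drawn
    and binned into a gradient fraction; the copy's 5' tag lands a geometric
    offset downstream of the true TSS.  Per-fraction counts are multiplied
    by the replicate's spike distortion factor before emission, and spike-in
    cluster counts scale with the same factors.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom = "chr1"
    genome_parts: list[str] = []
    cursor = 0
    transcripts: list[Transcript] = []
    gene_rows = []
    iso_rows = []
    event_rows = []
    tag_chunks = []
    coverage_rows = []

    lam_lo, lam_hi = config.ribosome_lambda_range
    n_reps = config.n_replicates
    spike = np.asarray(config.spike_factors, dtype=float)[:n_reps]
    scatter_p = 1.0 / (1.0 + config.tag_scatter)

    for gi in range(config.n_genes):
        gene = f"g{gi:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_tss = int(
            rng.choice(list(config.tss_per_gene_probs),
                       p=list(config.tss_per_gene_probs.values()))
        )
        shared_len = int(rng.integers(*config.utr_length_range))
        orf_len = int(rng.integers(config.orf_length_range[0] // 3,
                                   config.orf_length_range[1] // 3 + 1)) * 3
        utr3_len = 200

        shared_bg = random_background(rng, shared_len)
        if detect_top(shared_bg):
            shared_bg = "G" + shared_bg[1:]

        # optional intron in the shared UTR block
        event = None
        if rng.random() < config.splice_prob and shared_len >= 80:
            status = str(rng.choice(["removed", "retained", "ambiguous"],
                                    p=[0.6, 0.2, 0.2]))
            true_psi = {"removed": 0.02, "retained": 0.97, "ambiguous": 0.5}[status]
            annotation_status = {"removed": "constitutive", "retained": "novel",
                                 "ambiguous": "alternative"}[status]
            intron_len = int(rng.integers(60, 200))
            intron_seq = random_background(rng, intron_len - 1) + "C"
            insert_at = int(rng.integers(20, shared_len - 20))
            shared_bg = (shared_bg[: insert_at - 1] + "C" + shared_bg[insert_at:])
            event = dict(status=status, true_psi=true_psi,
                         annotation=annotation_status, intron_len=intron_len,
                         intron_seq=intron_seq, insert_at=insert_at)

        genomic_shared = shared_bg
        if event:
            genomic_shared = (shared_bg[: event["insert_at"]] + event["intron_seq"]
                              + shared_bg[event["insert_at"]:])
        if event and event["status"] == "removed":
            mature_shared = shared_bg
        else:  # retained, ambiguous, or no event
            mature_shared = genomic_shared

        # divergent blocks, planted proximal-first so downstream content is known
        blocks: list[str] = []
        block_feats: list[list] = []
        div_lens = [int(rng.integers(*config.divergent_length_range))
                    for _ in range(n_tss - 1)]
        for bi in range(n_tss - 1):
            feats = _draw_features(config, rng)
            downstream_seq = "".join(blocks) + mature_shared
            length = div_lens[bi]
            planted = None
            for attempt in range(30):
                bg = random_background(rng, length)
                try:
                    planted = plant_utr_features(bg, feats, rng, downstream_seq)
                    break
                except FeaturePlantingError as err:
                    length = min(length + 100, 800)
                    # a uAUG whose frame always meets a downstream stop would
                    # really be a uORF; such a feature cannot exist here
                    if attempt >= 8 and "uaug" in str(err):
                        kind = str(err).split("'")[1]
                        if kind in feats:
                            feats.remove(kind)
                    elif attempt >= 15 and feats:
                        feats.pop()
            if planted is None:
                raise FeaturePlantingError(f"gene {gene}: could not plant {feats}")
            blocks.insert(0, planted)
            block_feats.insert(0, feats)

        cds = "ATG" + _random_codons(rng, orf_len // 3 - 2) + "TAA"
        utr3 = "".join("ACGT"[b] for b in rng.integers(0, 4, utr3_len))
        gene_seq = "".join(blocks) + genomic_shared + cds + utr3
        glen = len(gene_seq)

        gap = 1600 + int(rng.integers(0, 400))
        genome_parts.append("".join("ACGT"[b] for b in rng.integers(0, 4, gap)))
        cursor += gap
        gene_off = cursor
        genome_parts.append(gene_seq if strand == "+" else revcomp(gene_seq))
        cursor += glen

        def to_genomic(local: int) -> int:
            return gene_off + local if strand == "+" else gene_off + glen - 1 - local

        def seg_to_genomic(a: int, b: int) -> tuple[int, int]:
            if strand == "+":
                return gene_off + a, gene_off + b
            return gene_off + glen - b, gene_off + glen - a

        tss_locals = []
        off = 0
        for b in blocks:
            tss_locals.append(off)
            off += len(b)
        tss_locals.append(off)  # proximal TSS at the shared block start
        start_codon_local = sum(len(b) for b in blocks) + len(genomic_shared)

        # per-isoform truth
        base_lam = float(rng.uniform(lam_lo, lam_hi))
        utr_status = ("ambiguous-excluded"
                      if event and event["status"] == "ambiguous" else "resolved")
        gene_iso_truth = []
        for ii in range(n_tss):
            mult = 1.0
            feats_named: list[str] = []
            for bj in range(ii, n_tss - 1):
                mult *= _block_multiplier(config, block_feats[bj], include_top=bj == ii)
                for f in block_feats[bj]:
                    kind = f if isinstance(f, str) else f"hexamer:{f[1]}"
                    if kind == "top" and bj != ii:
                        continue  # an interior TOP motif is not a cap TOP
                    feats_named.append(kind)
            mature = "".join(blocks[ii:]) + mature_shared
            abundance = float(rng.lognormal(*config.abundance_law))
            gene_iso_truth.append(dict(
                gene=gene, isoform=f"{gene}.t{ii}", chrom=chrom, strand=strand,
                tss0=to_genomic(tss_locals[ii]), tss_local=tss_locals[ii],
                abundance=abundance, lam=base_lam * mult,
                features=",".join(feats_named), utr_seq=to_rna(mature),
                utr_status=utr_status, orf_length=orf_len,
            ))
        iso_rows.extend(gene_iso_truth)

        # annotation: the proximal isoform is the annotated transcript
        ann_tss_local = tss_locals[-1]
        tx_start_local, tx_end_local = ann_tss_local, glen
        if event and event["annotation"] != "novel":
            ev_start_local = sum(len(b) for b in blocks) + event["insert_at"]
            ev_end_local = ev_start_local + event["intron_len"]
            exons_local = [(tx_start_local, ev_start_local),
                           (ev_end_local, tx_end_local)]
        else:
            exons_local = [(tx_start_local, tx_end_local)]
        exons_g = sorted(seg_to_genomic(a, b) for a, b in exons_local)
        cds_g = seg_to_genomic(start_codon_local, start_codon_local + orf_len)
        tx_g = seg_to_genomic(tx_start_local, tx_end_local)
        transcripts.append(Transcript(
            name=f"{gene}.ann", gene=gene, chrom=chrom, strand=strand,
            tx_start=min(tx_g), tx_end=max(tx_g), cds_start=min(cds_g),
            cds_end=max(cds_g), exons=exons_g,
        ))
        gene_rows.append(dict(
            gene=gene, chrom=chrom, strand=strand,
            tss0=to_genomic(ann_tss_local),
            start_codon0=to_genomic(start_codon_local),
            orf_length=orf_len,
        ))

        if event:
            ev_start_local = sum(len(b) for b in blocks) + event["insert_at"]
            ev_end_local = ev_start_local + event["intron_len"]
            ev_g = seg_to_genomic(ev_start_local, ev_end_local)
            depth = config.junction_depth
            s_in = int(rng.binomial(depth, event["true_psi"]))
            event_rows.append(dict(
                chrom=chrom, donor0=min(ev_g), acceptor0=max(ev_g), strand=strand,
                reads_spliceout=depth - s_in, reads_splicein=s_in,
                annotation=event["annotation"], gene=gene,
                true_psi=event["true_psi"], status=event["status"],
            ))

        # tag emission
        gene_chunks = []
        for rep in range(1, n_reps + 1):
            for ii, tr in enumerate(gene_iso_truth):
                n_copies = int(rng.poisson(tr["abundance"]))
                if n_copies == 0:
                    continue
                k = np.minimum(rng.poisson(tr["lam"], n_copies), MAX_LOAD)
                frac = _load_to_fraction(k, rng)
                offsets = rng.geometric(scatter_p, n_copies) - 1
                local_pos = np.minimum(tss_locals[ii] + offsets, glen - 1)
                gpos = (gene_off + local_pos if strand == "+"
                        else gene_off + glen - 1 - local_pos)
                df = pd.DataFrame({"pos0": gpos, "fraction": frac + 1})
                agg = df.groupby(["pos0", "fraction"]).size().reset_index(name="count")
                agg["replicate"] = rep
                gene_chunks.append(agg)
            if config.background_rate > 0:
                for j in range(7):
                    n_bg = int(rng.poisson(config.background_rate * glen))
                    if n_bg == 0:
                        continue
                    pos = gene_off + rng.integers(0, glen, n_bg)
                    df = pd.DataFrame({"pos0": pos, "fraction": j + 1})
                    agg = df.groupby(["pos0", "fraction"]).size().reset_index(name="count")
                    agg["replicate"] = rep
                    gene_chunks.append(agg)
        for chunk in gene_chunks:
            chunk["chrom"] = chrom
            chunk["strand"] = strand
        tag_chunks.extend(gene_chunks)

        coverage_rows.append(dict(
            chrom=chrom, start0=max(gene_off - 1500, 0),
            end0=gene_off + glen + 1500, value=config.rnaseq_coverage,
        ))

    genome = {chrom: "".join(genome_parts)
              + "".join("ACGT"[b] for b in rng.integers(0, 4, 2000))}

    tags = pd.concat(tag_chunks, ignore_index=True)
    tags = tags.groupby(["chrom", "pos0", "strand", "replicate", "fraction"],
                        as_index=False)["count"].sum()
    # per-fraction spike distortion applied before emission
    mult = spike[tags["replicate"].to_numpy(int) - 1,
                 tags["fraction"].to_numpy(int) - 1]
    tags["count"] = np.rint(tags["count"].to_numpy(float) * mult).astype(int)
    tags = tags[tags["count"] > 0]
    tags = tags.sort_values(["chrom", "strand", "replicate", "fraction", "pos0"],
                            ignore_index=True)

    # spike-in clusters scale with the same per-fraction factors
    base = rng.lognormal(np.log(60.0), 0.5, config.n_spike_clusters)
    spike_rows = []
    for ci, b in enumerate(base):
        for rep in range(1, n_reps + 1):
            for j in range(7):
                spike_rows.append(dict(
                    cluster=f"spike{ci:03d}", replicate=rep, fraction=j + 1,
                    count=int(rng.poisson(b * spike[rep - 1, j])),
                ))
    spikes = pd.DataFrame(spike_rows)

    coverage = _merge_coverage(pd.DataFrame(coverage_rows))
    junction_cols = ["chrom", "donor0", "acceptor0", "strand", "reads_spliceout",
                     "reads_splicein", "annotation"]
    events_df = pd.DataFrame(
        event_rows, columns=junction_cols + ["gene", "true_psi", "status"]
    )
    iso_df = pd.DataFrame(iso_rows)
    _verify_truth(iso_df)

    truth = SimTruth(
        isoforms=iso_df,
        genes=pd.DataFrame(gene_rows),
        events=events_df,
        spike_factors=spike,
    )
    return SimulatedDataset(
        genome=genome,
        annotation=Annotation(transcripts, pd.DataFrame(gene_rows)),
        tags=tags,
        spikes=spikes,
        coverage=coverage,
        junctions=events_df[junction_cols].copy(),
        truth=truth,
        config=config,
    )


def simulate_isoform_pairs(
    n_pairs: int = 200,
    tags_per_isoform: int = 2000,
    lfc_range: tuple[float, float] = (-3.0, 3.0),
    rng: np.random.Generator | int | None = None,
) -> list[dict]:
    """Two-isoform genes with controlled TE ratios, as raw fraction counts.

    Each pair targets a log2 ratio of ribosomes-per-mRNA drawn uniformly from
    ``lfc_range``: both isoforms' target loads sit symmetrically around the
    geometric mid-load sqrt(12), realized as a monosome/heavy-polysome
    mixture with a 5% uniform spread over all seven fractions, and
    ``tags_per_isoform`` tags are drawn multinomially.  Returns one dict per
    pair with ``counts_a``, ``counts_b``, ``target_lfc`` and ``plugin_lfc``
    (the realized log2 TE fold change).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    center = np.sqrt(RIBOSOME_WEIGHTS[6] * RIBOSOME_WEIGHTS[2])

    def fraction_probs(rho: float) -> np.ndarray:
        w = (rho - RIBOSOME_WEIGHTS[2]) / (RIBOSOME_WEIGHTS[6] - RIBOSOME_WEIGHTS[2])
        p = np.full(7, 0.05 / 7)
        p[2] += 0.95 * (1.0 - w)
        p[6] += 0.95 * w
        return p / p.sum()

    out = []
    for _ in range(n_pairs):
        delta = float(rng.uniform(*lfc_range))
        rho_a = center * 2 ** (delta / 2)
        rho_b = center * 2 ** (-delta / 2)
        a = rng.multinomial(tags_per_isoform, fraction_probs(rho_a)).astype(float)
        b = rng.multinomial(tags_per_isoform, fraction_probs(rho_b)).astype(float)
        plugin = float(np.log2(
            (RIBOSOME_WEIGHTS @ a / a.sum()) / (RIBOSOME_WEIGHTS @ b / b.sum())
        ))
        out.append(dict(counts_a=a, counts_b=b, target_lfc=delta,
                        plugin_lfc=plugin))
    return out


def _merge_coverage(coverage: pd.DataFrame) -> pd.DataFrame:
    """Collapse overlapping coverage intervals (max value wins)."""
    out = []
    for _, sub in coverage.groupby("chrom"):
        sub = sub.sort_values("start0")
        cur = None
        for _, row in sub.iterrows():
            if cur is None or row["start0"] > cur["end0"]:
                if cur is not None:
                    out.append(cur)
                cur = dict(row)
            else:
                cur["end0"] = max(cur["end0"], row["end0"])
                cur["value"] = max(cur["value"], row["value"])
        if cur is not None:
            out.append(cur)
    return pd.DataFrame(out)


def _verify_truth(iso_df: pd.DataFrame) -> None:
    """Planted features must be recoverable verbatim from the emitted UTRs."""
    for _, row in iso_df.iterrows():
        if row["utr_status"] != "resolved":
            continue
        feats = [f for f in str(row["features"]).split(",") if f]
        n_uorf, n_in, n_out = find_uorfs(row["utr_seq"])
        want = (sum(f == "uorf" for f in feats),
                sum(f == "uaug_in" for f in feats),
                sum(f == "uaug_out" for f in feats))
        if (n_uorf, n_in, n_out) != want:
            raise AssertionError(
                f"{row['isoform']}: planted {want} recovered ({n_uorf},{n_in},{n_out})"
            )
        if ("top" in feats) != detect_top(row["utr_seq"]):
            raise AssertionError(f"{row['isoform']}: TOP round-trip failed")
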