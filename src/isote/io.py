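"""Readers, writers and light genomic containers.

All genomic coordinates are 0-based, half-open.  Tags, junctions, spike-in
counts and truth tables travel as TSV (pandas); the genome as FASTA; gene
models as BED12 (one line per transcript, thickStart/thickEnd delimiting the
CDS) plus a per-gene TSV of annotated TSSs and start codons; RNA-seq
coverage as bedGraph.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

TAG_COLUMNS = ["chrom", "pos0", "strand", "replicate", "fraction", "count"]
JUNCTION_COLUMNS = [
    "chrom", "donor0", "acceptor0", "strand", "reads_spliceout", "reads_splicein",
    "annotation",
]


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences


def read_tags(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TAG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"tag table missing columns {sorted(missing)}")
    return df


def write_tags(df: pd.DataFrame, path: str | Path) -> None:
    df[TAG_COLUMNS].to_csv(path, sep="\t", index=False)


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start0", "end0", "value"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", names=["chrom", "start0", "end0", "value"], header=None
    )


class CoverageTrack:
    """Piecewise-constant genomic coverage with O(log n) window means.

    Built from bedGraph-style intervals; the integral of coverage is
    piecewise linear, so window means reduce to two interpolations.
    """

    def __init__(self, intervals: pd.DataFrame):
        self._knots: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in intervals.groupby("chrom"):
            sub = sub.sort_values("start0")
            starts = sub["start0"].to_numpy(float)
            ends = sub["end0"].to_numpy(float)
            values = sub["value"].to_numpy(float)
            xs = np.empty(2 * len(sub))
            xs[0::2] = starts
            xs[1::2] = ends
            integral = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
            ys = np.empty(2 * len(sub))
            ys[0::2] = integral[:-1]
            ys[1::2] = integral[1:]
            # assumes non-overlapping intervals; gaps contribute zero coverage
            self._knots[chrom] = (xs, ys)

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "CoverageTrack":
        return cls(read_bedgraph(path))

    def window_mean(self, chrom: str, start: np.ndarray | float, end: np.ndarray | float):
        """Mean coverage over [start, end); zero outside covered intervals."""
        start = np.asarray(start, dtype=float)
        end = np.asarray(end, dtype=float)
        if chrom not in self._knots:
            return np.zeros_like(start)
        xs, ys = self._knots[chrom]
        total = np.interp(end, xs, ys) - np.interp(start, xs, ys)
        with np.errstate(invalid="ignore"):
            return total / np.maximum(end - start, 1.0)


@dataclass
class Transcript:
    name: str
    gene: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int  # thickStart
    cds_end: int    # thickEnd
    exons: list[tuple[int, int]]


class Annotation:
    """Gene annotation: transcripts plus per-gene extreme TSS / start codon.

    ``genes`` is a DataFrame with columns ``gene, chrom, strand, tss0``
    (most-5' annotated TSS), ``start_codon0`` (first base of the most-3'
    annotated start codon) and ``orf_length`` (nt, including the stop codon).
    """

    def __init__(self, transcripts: list[Transcript], genes: pd.DataFrame):
        self.transcripts = transcripts
        self.genes = genes.set_index("gene", drop=False)
        self._by_gene: dict[str, list[Transcript]] = {}
        for tx in transcripts:
            self._by_gene.setdefault(tx.gene, []).append(tx)

    def gene_transcripts(self, gene: str) -> list[Transcript]:
        return self._by_gene.get(gene, [])

    def gene_records(self, chrom: str, strand: str) -> list[dict]:
        """Plain-dict gene rows on one chrom/strand (cached for speed)."""
        if not hasattr(self, "_records"):
            self._records: dict[tuple[str, str], list[dict]] = {}
            for row in self.genes.to_dict("records"):
                key = (row["chrom"], row["strand"])
                self._records.setdefault(key, []).append(row)
        return self._records.get((chrom, strand), [])

    def to_bed12(self) -> pd.DataFrame:
        rows = []
        for tx in self.transcripts:
            exons = sorted(tx.exons)
            sizes = ",".join(str(e - s) for s, e in exons) + ","
            starts = ",".join(str(s - tx.tx_start) for s, e in exons) + ","
            rows.append(
                (tx.chrom, tx.tx_start, tx.tx_end, f"{tx.gene}|{tx.name}", 0,
                 tx.strand, tx.cds_start, tx.cds_end, "0,0,0", len(exons), sizes, starts)
            )
        return pd.DataFrame(
            rows,
            columns=["chrom", "start", "end", "name", "score", "strand",
                     "thickStart", "thickEnd", "itemRgb", "blockCount",
                     "blockSizes", "blockStarts"],
        )

    def write(self, bed12_path: str | Path, genes_path: str | Path) -> None:
        self.to_bed12().to_csv(bed12_path, sep="\t", index=False, header=False)
        self.genes.to_csv(genes_path, sep="\t", index=False)

    @classmethod
    def read(cls, bed12_path: str | Path, genes_path: str | Path) -> "Annotation":
        bed = pd.read_csv(
            bed12_path, sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score", "strand",
                   "thickStart", "thickEnd", "itemRgb", "blockCount",
                   "blockSizes", "blockStarts"],
        )
        transcripts = []
        for _, row in bed.iterrows():
            gene, _, tx_name = row["name"].partition("|")
            sizes = [int(x) for x in str(row["blockSizes"]).rstrip(",").split(",")]
            offsets = [int(x) for x in str(row["blockStarts"]).rstrip(",").split(",")]
            exons = [
                (row["start"] + off, row["start"] + off + size)
                for off, size in zip(offsets, sizes)
            ]
            transcripts.append(
                Transcript(tx_name or row["name"], gene, row["chrom"], row["strand"],
                           int(row["start"]), int(row["end"]),
                           int(row["thickStart"]), int(row["thickEnd"]), exons)
            )
        return cls(transcripts, pd.read_csv(genes_path, sep="\t"))


def clusters_to_bed(clusters) -> pd.DataFrame:
    """TSS clusters as a BED6+ table (score = pooled tag count)."""
    rows = []
    for i, c in enumerate(clusters):
        name = f"{c.gene or 'NA'}:{i}"
        rows.append(
            (c.chrom, c.start0, c.end0, name, c.pooled_count, c.strand,
             c.summit, c.region, c.idr, c.flagged)
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start0", "end0", "name", "score", "strand",
                 "summit", "region", "idr", "flagged"],
    )
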