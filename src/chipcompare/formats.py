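"""Readers and writers for the interval, coverage, sequence and table formats.

BED and narrowPeak records are stored 0-based half-open on disk, matching the
in-memory convention, so no coordinate shifting is needed for them. bedGraph
is likewise half-open. Gene tables are TSV with a header.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GenomicInterval, Peak

GENE_COLUMNS = ["gene_id", "chrom", "tss", "strand", "expression"]


class ParseError(ValueError):
    pass


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_intervals(path, format: str = "bed"):
    """Read a BED or narrowPeak file.

    Returns a list of ``(GenomicInterval, attrs)`` pairs; ``attrs`` carries
    any extra columns (name/score, and for narrowPeak the signal value,
    -log10 p/q and summit offset).
    """
    if format not in ("bed", "narrowpeak"):
        raise ValueError(f"unknown interval format {format!r}")
    out = []
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 columns")
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
        if start >= end:
            raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
        strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
        attrs = {}
        if len(f) > 3:
            attrs["name"] = f[3]
        if len(f) > 4:
            attrs["score"] = f[4]
        if format == "narrowpeak":
            if len(f) < 10:
                raise ParseError(f"{path}:{lineno}: narrowPeak needs 10 columns")
            attrs["signal"] = float(f[6])
            attrs["pvalue_log10"] = float(f[7])
            attrs["qvalue_log10"] = float(f[8])
            attrs["summit_offset"] = int(f[9])
        out.append((GenomicInterval(f[0], start, end, strand), attrs))
    return out


def write_intervals(path, intervals, format: str = "bed") -> None:
    """Write intervals (GenomicInterval, or (interval, attrs) pairs) as BED."""
    if format != "bed":
        raise ValueError("write_intervals only emits BED; use write_peaks for narrowPeak")
    with open(path, "w") as fh:
        for i, item in enumerate(intervals):
            iv, attrs = item if isinstance(item, tuple) else (item, {})
            name = attrs.get("name", f"iv{i}")
            score = attrs.get("score", "0")
            if iv.strand == "." and not attrs:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )


def write_peaks(path, peaks) -> None:
    """Write peaks in narrowPeak layout (-log10 p in column 8, summit offset in 10)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak{i + 1}\t0\t.\t"
                f"{p.fold_enrichment:.5g}\t{p.neg_log10_pvalue:.5g}\t-1\t"
                f"{p.summit - p.start}\n"
            )


def read_peaks(path):
    """Read a narrowPeak file back into Peak objects."""
    peaks = []
    for iv, attrs in read_intervals(path, format="narrowpeak"):
        peaks.append(
            Peak(
                chrom=iv.chrom,
                start=iv.start,
                end=iv.end,
                summit=iv.start + attrs["summit_offset"],
                tag_count=1,  # narrowPeak does not carry tag counts
                fold_enrichment=attrs["signal"],
                neg_log10_pvalue=attrs["pvalue_log10"],
            )
        )
    return peaks


@dataclass
class StepTrack:
    """Piecewise-constant coverage over one or more chromosomes.

    Stored per chromosome as sorted, non-overlapping (start, end, value)
    triples; positions not covered by any record have value 0.
    """

    segments: dict  # chrom -> (starts, ends, values) numpy arrays

    def value_at(self, chrom: str, pos: int) -> float:
        if chrom not in self.segments:
            return 0.0
        starts, ends, values = self.segments[chrom]
        i = np.searchsorted(starts, pos, side="right") - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return 0.0

    def total_signal(self) -> float:
        """Sum over bp of the track value (= sum of value * width)."""
        return float(
            sum(((e - s) * v).sum() for s, e, v in self.segments.values())
        )


def read_coverage(path) -> StepTrack:
    """Read a bedGraph file; records must be sorted and non-overlapping."""
    per_chrom = {}
    for lineno, line in _data_lines(path):
        f = line.split()
        if len(f) != 4:
            raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
        chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
        if start >= end:
            raise ParseError(f"{path}:{lineno}: start >= end")
        rows = per_chrom.setdefault(chrom, [])
        if rows and start < rows[-1][1]:
            raise ParseError(
                f"{path}:{lineno}: overlapping or unsorted records on {chrom}"
            )
        rows.append((start, end, value))
    segments = {
        c: (
            np.array([r[0] for r in rows]),
            np.array([r[1] for r in rows]),
            np.array([r[2] for r in rows]),
        )
        for c, rows in per_chrom.items()
    }
    return StepTrack(segments)


def write_coverage(path, track: StepTrack) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.segments):
            starts, ends, values = track.segments[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:g}\n")


def read_fasta(path) -> dict:
    """Read a FASTA file into {chrom: upper-cased sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(path, sequences: dict) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_gene_table(path, genome: dict | None = None) -> pd.DataFrame:
    """Read a gene TSV (gene_id, chrom, tss, strand, expression).

    If a genome is supplied, TSS positions are validated against chromosome
    lengths.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: gene table missing column(s) {missing}")
    df = df[GENE_COLUMNS].copy()
    df["tss"] = df["tss"].astype(int)
    df["expression"] = df["expression"].astype(float)
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ParseError(f"{path}: duplicate gene_id {dup!r}")
    if genome is not None:
        for _, row in df.iterrows():
            if row.chrom not in genome:
                raise ParseError(f"{path}: unknown chrom {row.chrom!r}")
            if not (0 <= row.tss < len(genome[row.chrom])):
                raise ParseError(
                    f"{path}: gene {row.gene_id} TSS {row.tss} outside {row.chrom}"
                )
    return df


def write_gene_table(path, genes: pd.DataFrame) -> None:
    genes[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_reads(path) -> pd.DataFrame:
    """Read mapped reads from BED6 into a DataFrame."""
    rows = read_intervals(path, format="bed")
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv, _ in rows],
            "start": np.array([iv.start for iv, _ in rows], dtype=np.int64),
            "end": np.array([iv.end for iv, _ in rows], dtype=np.int64),
            "name": [a.get("name", ".") for _, a in rows],
            "score": [a.get("score", "0") for _, a in rows],
            "strand": [iv.strand for iv, _ in rows],
        }
    )


def write_reads(path, reads: pd.DataFrame) -> None:
    reads.to_csv(
        path,
        sep="\t",
        header=False,
        index=False,
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
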