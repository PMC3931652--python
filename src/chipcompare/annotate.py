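"""Promoter/enhancer annotation: peak-to-promoter assignment, chromatin-mark
promoter classes (H3K4me3-only vs bivalent), enhancer classes (active vs
poised), and CpG-content promoter classes (HCP/ICP/LCP).

Promoter windows are strand-aware intervals around the TSS. The default
binding window is TSS -1 kb / +1 kb; the wider -3 kb / +2 kb variant used for
factors that bind further from the TSS is available as the ``"s5a"`` preset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GenomicInterval, GeneRecord, Peak


@dataclass(frozen=True)
class WindowParams:
    upstream: int = 1000
    downstream: int = 1000

    def __post_init__(self):
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("window extents must be >= 0")
        if self.upstream == 0 and self.downstream == 0:
            raise ValueError("window cannot be empty")


WINDOW_PRESETS = {
    "default": WindowParams(1000, 1000),
    "s5a": WindowParams(3000, 2000),
}


def promoter_window(
    gene, window: WindowParams = WINDOW_PRESETS["default"], chrom_length: int | None = None
) -> GenomicInterval:
    """Strand-aware promoter window around a gene's TSS, clipped at chrom ends.

    For a + gene the window is [tss - upstream, tss + downstream); for a -
    gene [tss - downstream, tss + upstream).
    """
    tss, strand = int(gene.tss), gene.strand
    if strand == "+":
        start, end = tss - window.upstream, tss + window.downstream
    else:
        start, end = tss - window.downstream, tss + window.upstream
    start = max(start, 0)
    if chrom_length is not None:
        end = min(end, chrom_length)
    if start >= end:
        raise ValueError(
            f"promoter window of gene {getattr(gene, 'gene_id', '?')} lies "
            "entirely off-chromosome"
        )
    return GenomicInterval(gene.chrom, start, end, strand)


def promoter_windows(
    genes: pd.DataFrame, window: WindowParams, chrom_lengths: dict | None = None
) -> pd.DataFrame:
    """Vectorised promoter windows for a gene table; adds start/end columns."""
    tss = genes["tss"].to_numpy()
    plus = genes["strand"].to_numpy() == "+"
    start = np.where(plus, tss - window.upstream, tss - window.downstream)
    end = np.where(plus, tss + window.downstream, tss + window.upstream)
    start = np.maximum(start, 0)
    if chrom_lengths is not None:
        lengths = genes["chrom"].map(chrom_lengths).to_numpy()
        end = np.minimum(end, lengths)
    out = genes[["gene_id", "chrom", "strand"]].copy()
    out["start"] = start
    out["end"] = end
    if (out["start"] >= out["end"]).any():
        bad = out.loc[out["start"] >= out["end"], "gene_id"].iloc[0]
        raise ValueError(f"promoter window of gene {bad} lies entirely off-chromosome")
    return out


def _interval_trees(intervals) -> dict:
    """Build one IntervalTree per chromosome from intervals or Peaks."""
    trees: dict[str, IntervalTree] = {}
    for idx, item in enumerate(intervals):
        trees.setdefault(item.chrom, IntervalTree()).addi(item.start, item.end, idx)
    return trees


def assign_peaks_to_promoters(
    peaks,
    genes: pd.DataFrame,
    window: WindowParams = WINDOW_PRESETS["default"],
    chrom_lengths: dict | None = None,
):
    """Genes whose promoter window intersects at least one peak.

    Returns ``(bound, best_peak)`` where ``bound`` is the set of bound
    gene_ids and ``best_peak`` maps each bound gene to its most significant
    intersecting peak (lowest p-value; for plain intervals, the first hit).
    """
    trees = _interval_trees(peaks)
    wins = promoter_windows(genes, window, chrom_lengths)
    bound: set[str] = set()
    best_peak: dict[str, object] = {}
    for gene_id, chrom, start, end in zip(
        wins["gene_id"], wins["chrom"], wins["start"], wins["end"]
    ):
        tree = trees.get(chrom)
        if tree is None:
            continue
        hits = tree.overlap(int(start), int(end))
        if not hits:
            continue
        bound.add(gene_id)
        candidates = [peaks[h.data] for h in hits]
        if isinstance(candidates[0], Peak):
            best_peak[gene_id] = max(
                candidates, key=lambda p: (p.neg_log10_pvalue, -p.start)
            )
        else:
            best_peak[gene_id] = min(candidates, key=lambda iv: iv.start)
    return bound, best_peak


def classify_promoter_marks(
    genes: pd.DataFrame,
    k4me3_intervals,
    k27me3_intervals,
    window: WindowParams = WINDOW_PRESETS["default"],
) -> dict:
    """Mark class per gene: H3K4me3_only, bivalent (K4me3+K27me3), or none."""
    k4, _ = assign_peaks_to_promoters(list(k4me3_intervals), genes, window)
    k27, _ = assign_peaks_to_promoters(list(k27me3_intervals), genes, window)
    out = {}
    for gene_id in genes["gene_id"]:
        if gene_id in k4:
            out[gene_id] = "bivalent" if gene_id in k27 else "H3K4me3_only"
        else:
            out[gene_id] = "none"
    return out


def classify_enhancers(
    k4me1_intervals, k27ac_intervals, genes: pd.DataFrame, distal_min: int = 5000
) -> dict:
    """Classify distal H3K4me1 elements as active (with H3K27ac) or poised.

    Candidates are H3K4me1 intervals at least ``distal_min`` bp away from
    every TSS; anything closer is dropped (it is promoter-proximal).
    """
    tss_by_chrom = {
        c: np.sort(g["tss"].to_numpy()) for c, g in genes.groupby("chrom")
    }
    k27_trees = _interval_trees(list(k27ac_intervals))
    out = {}
    for iv in k4me1_intervals:
        tss = tss_by_chrom.get(iv.chrom)
        if tss is not None and tss.size:
            i = np.searchsorted(tss, iv.start)
            nearby = tss[max(i - 1, 0) : i + 1]
            if min(iv.distance_to_point(int(t)) for t in nearby) < distal_min:
                continue
        tree = k27_trees.get(iv.chrom)
        active = tree is not None and bool(tree.overlap(iv.start, iv.end))
        out[iv] = "active" if active else "poised"
    return out


def cpg_window_stats(seq: str, win: int = 500, step: int = 5):
    """GC fraction and CpG observed/expected for sliding windows over seq.

    O/E follows the classic definition (#CpG * window_length) / (#C * #G),
    taken as 0 when the window contains no C or no G. Sequences shorter than
    the window are evaluated as a single window (with a warning upstream).
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    n = arr.size
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_cg = np.zeros(n, dtype=np.int64)
    if n > 1:
        is_cg[:-1] = ((arr[:-1] == ord("C")) & (arr[1:] == ord("G"))).astype(np.int64)
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cg = np.concatenate([[0], np.cumsum(is_cg)])
    if n < win:
        starts = np.array([0])
        win_eff = n
    else:
        starts = np.arange(0, n - win + 1, step)
        win_eff = win
    ends = starts + win_eff
    c = cum_c[ends] - cum_c[starts]
    g = cum_g[ends] - cum_g[starts]
    # CpG dinucleotides fully inside the window start at [start, end-1)
    cg = cum_cg[ends - 1] - cum_cg[starts]
    gc_frac = (c + g) / win_eff
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(c * g > 0, cg * win_eff / np.maximum(c * g, 1), 0.0)
    return gc_frac, oe


def classify_cpg_sequence(
    seq: str,
    win: int = 500,
    step: int = 5,
    oe_high: float = 0.75,
    gc_high: float = 0.55,
    oe_low: float = 0.48,
) -> str:
    """HCP/ICP/LCP class of one promoter sequence.

    HCP: some window has CpG O/E > oe_high and GC fraction > gc_high.
    LCP: no window reaches O/E >= oe_low. ICP: everything else.
    """
    if len(seq) < win:
        warnings.warn(
            f"promoter sequence shorter than {win} bp; evaluating single window",
            stacklevel=2,
        )
    gc, oe = cpg_window_stats(seq, win=win, step=step)
    if np.any((oe > oe_high) & (gc > gc_high)):
        return "HCP"
    if not np.any(oe >= oe_low):
        return "LCP"
    return "ICP"


def classify_cpg(
    genome: dict,
    genes: pd.DataFrame,
    window: WindowParams = WINDOW_PRESETS["default"],
    **kwargs,
) -> dict:
    """CpG-content class (HCP/ICP/LCP) of every gene's promoter window."""
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    wins = promoter_windows(genes, window, chrom_lengths)
    out = {}
    for gene_id, chrom, start, end in zip(
        wins["gene_id"], wins["chrom"], wins["start"], wins["end"]
    ):
        seq = genome[chrom][int(start) : int(end)]
        out[gene_id] = classify_cpg_sequence(seq, **kwargs)
    return out


def class_table(
    genes: pd.DataFrame, mark_classes: dict, cpg_classes: dict
) -> pd.DataFrame:
    """Tidy per-gene class table (gene_id, mark_class, cpg_class)."""
    return pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "mark_class": genes["gene_id"].map(mark_classes),
            "cpg_class": genes["gene_id"].map(cpg_classes),
        }
    )


def genes_from_frame(genes: pd.DataFrame):
    """Gene table rows as GeneRecord objects (convenience for scalar APIs)."""
    return [
        GeneRecord(r.gene_id, r.chrom, int(r.tss), r.strand, float(r.expression))
        for r in genes.itertuples(index=False)
    ]
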