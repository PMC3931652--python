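"""Co-binding analytics: promoter Venn decomposition, peak colocalization
versus significance cutoff, TSS-centered signal matrices ordered by
expression, and between-dataset correlation clustering."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .peaks import BinnedCoverage, threshold_peaks


@dataclass
class VennDecomposition:
    """Exact counts for every non-empty membership pattern over named sets.

    ``counts`` maps a frozenset of set names (the membership pattern) to the
    number of elements belonging to exactly those sets; patterns sum to the
    union size. ``pairwise_fraction[(a, b)]`` is |a ∩ b| / |a|.
    """

    set_names: list
    counts: dict
    pairwise_fraction: dict
    union_size: int


def promoter_venn(bound_sets: dict) -> VennDecomposition:
    """Decompose 2-4 named gene sets into exclusive membership patterns."""
    if not bound_sets:
        raise ValueError("bound_sets must not be empty")
    if not (2 <= len(bound_sets) <= 4):
        raise ValueError(f"promoter_venn supports 2-4 sets, got {len(bound_sets)}")
    names = sorted(bound_sets)
    union = set().union(*bound_sets.values())
    counts: dict[frozenset, int] = {}
    for g in union:
        pattern = frozenset(n for n in names if g in bound_sets[n])
        counts[pattern] = counts.get(pattern, 0) + 1
    pairwise = {}
    for a in names:
        for b in names:
            if a == b:
                continue
            na = len(bound_sets[a])
            pairwise[(a, b)] = (
                len(bound_sets[a] & bound_sets[b]) / na if na else float("nan")
            )
    return VennDecomposition(
        set_names=names,
        counts=counts,
        pairwise_fraction=pairwise,
        union_size=len(union),
    )


def venn_table(venn: VennDecomposition) -> pd.DataFrame:
    rows = []
    for pattern, n in sorted(venn.counts.items(), key=lambda kv: sorted(kv[0])):
        rows.append({"pattern": "&".join(sorted(pattern)), "count": n})
    return pd.DataFrame(rows)


def peak_colocalization_curve(peaks, feature_sets: dict, p_grid) -> pd.DataFrame:
    """Fraction of peaks overlapping each feature set at each p-value cutoff.

    ``p_grid`` must be sorted loosest-first (descending p). Output is a tidy
    long-format table (p_cutoff, n_peaks, feature, fraction); the fraction is
    NaN when no peak survives a cutoff.
    """
    p_grid = list(p_grid)
    if not p_grid:
        raise ValueError("p_grid must not be empty")
    if any(a < b for a, b in zip(p_grid, p_grid[1:])):
        raise ValueError("p_grid must be sorted descending (loosest cutoff first)")
    trees = {}
    for name, intervals in feature_sets.items():
        tree = IntervalTree()
        for iv in intervals:
            tree.addi(iv.start, iv.end, iv.chrom)
        trees[name] = tree
    rows = []
    for cutoff in p_grid:
        surviving = threshold_peaks(peaks, cutoff)
        for name, tree in trees.items():
            if surviving:
                n_hit = sum(
                    1
                    for p in surviving
                    if any(h.data == p.chrom for h in tree.overlap(p.start, p.end))
                )
                frac = n_hit / len(surviving)
            else:
                frac = float("nan")
            rows.append(
                {
                    "p_cutoff": cutoff,
                    "n_peaks": len(surviving),
                    "feature": name,
                    "fraction": frac,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SignalMatrix:
    """Per-gene binned read density around the TSS, ordered by expression.

    Rows are genes sorted by ascending expression (ties broken by gene_id);
    columns span TSS +/- halfwidth at ``bin_size`` resolution, oriented so
    upstream is always on the left; values are summed per-bp fragment
    coverage per bin, scaled to reads per million.
    """

    values: np.ndarray  # (n_genes, n_bins)
    gene_ids: list
    expression: np.ndarray
    halfwidth: int
    bin_size: int

    def to_frame(self) -> pd.DataFrame:
        cols = [
            f"{-self.halfwidth + i * self.bin_size}"
            for i in range(self.values.shape[1])
        ]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "gene_id", self.gene_ids)
        return df

    def row_sums(self) -> pd.Series:
        return pd.Series(self.values.sum(axis=1), index=self.gene_ids)


def tss_signal_matrix(
    coverage: BinnedCoverage,
    genes: pd.DataFrame,
    halfwidth: int = 5000,
    bin_size: int = 50,
) -> SignalMatrix:
    """TSS-centered signal heatmap matrix from binned fragment coverage.

    The matrix bin size must be a multiple of the coverage bin size; each
    matrix cell is the per-bp coverage summed over the cell, scaled to RPM.
    Windows that run off the chromosome produce a zero row with a warning.
    """
    if bin_size % coverage.bin_size != 0:
        raise ValueError(
            f"matrix bin_size {bin_size} must be a multiple of the coverage "
            f"bin size {coverage.bin_size}"
        )
    if (2 * halfwidth) % bin_size != 0:
        raise ValueError("2*halfwidth must be divisible by bin_size")
    order = genes.sort_values(["expression", "gene_id"], kind="mergesort")
    n_bins = 2 * halfwidth // bin_size
    fine_per_cell = bin_size // coverage.bin_size
    n_fine = n_bins * fine_per_cell
    scale = coverage.rpm_scale() * coverage.bin_size
    values = np.zeros((len(order), n_bins))
    for row_i, rec in enumerate(order.itertuples(index=False)):
        cv = coverage.counts.get(rec.chrom)
        if cv is None:
            continue
        L = coverage.chrom_lengths[rec.chrom]
        w_start = rec.tss - halfwidth
        w_end = rec.tss + halfwidth
        if w_start < 0 or w_end > L:
            warnings.warn(
                f"TSS window of gene {rec.gene_id} off chromosome; row zeroed",
                stacklevel=2,
            )
            continue
        f0 = w_start // coverage.bin_size
        fine = cv[f0 : f0 + n_fine]
        row = fine.reshape(n_bins, fine_per_cell).sum(axis=1) * scale
        if rec.strand == "-":
            row = row[::-1]
        values[row_i] = row
    return SignalMatrix(
        values=values,
        gene_ids=list(order["gene_id"]),
        expression=order["expression"].to_numpy(),
        halfwidth=halfwidth,
        bin_size=bin_size,
    )


def genome_bin_vector(coverage: BinnedCoverage, bin_size: int = 1000) -> np.ndarray:
    """Genome-wide coverage vector at a coarse bin size (for correlations)."""
    if bin_size % coverage.bin_size != 0:
        raise ValueError("bin_size must be a multiple of the coverage bin size")
    k = bin_size // coverage.bin_size
    parts = []
    for chrom in sorted(coverage.counts):
        cv = coverage.counts[chrom]
        n = (len(cv) // k) * k
        parts.append(cv[:n].reshape(-1, k).sum(axis=1).astype(float))
    return np.concatenate(parts)


def dataset_correlation_clustering(signals: dict):
    """Pairwise Pearson correlation and average-linkage clustering on 1 - r.

    ``signals`` maps dataset name -> equal-length genome-binned vector.
    Returns ``(corr, linkage, merge_order)`` where ``corr`` is a DataFrame
    indexed by sorted dataset names, ``linkage`` the scipy linkage matrix,
    and ``merge_order`` the successive merges as tuples of name-frozensets.
    """
    if len(signals) < 2:
        raise ValueError("need at least two datasets")
    names = sorted(signals)
    lengths = {len(np.asarray(signals[n])) for n in names}
    if len(lengths) != 1:
        raise ValueError("all signal vectors must have the same length")
    mat = np.vstack([np.asarray(signals[n], dtype=float) for n in names])
    stds = mat.std(axis=1)
    for n, s in zip(names, stds):
        if s == 0:
            raise ValueError(f"dataset {n!r} has zero variance; correlation undefined")
    corr = np.corrcoef(mat)
    dist = squareform(np.clip(1.0 - corr, 0.0, None), checks=False)
    linkage = hierarchy.average(dist)
    clusters = {i: frozenset([names[i]]) for i in range(len(names))}
    merge_order = []
    for i, (a, b, _, _) in enumerate(linkage):
        ca, cb = clusters[int(a)], clusters[int(b)]
        merge_order.append((ca, cb))
        clusters[len(names) + i] = ca | cb
    corr_df = pd.DataFrame(corr, index=names, columns=names)
    return corr_df, linkage, merge_order
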