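"""Benchmarking of peak sets against reference gene sets.

Two complementary views of sensitivity/specificity are implemented:

* ROC/AUC — genes are labelled foreground (top 50% of expressed genes that
  carry the reference feature) or background (bottom 50% of expressed genes
  that do not), and the peak set is swept over a grid of p-value cutoffs to
  trace sensitivity vs specificity of promoter binding.
* Cumulative-signal distance d — the empirical cumulative distributions of
  raw promoter signal (RPM) in the foreground and background sets are
  compared by their maximum vertical gap, i.e. the two-sample
  Kolmogorov-Smirnov statistic. A cleaner separation of bound from unbound
  promoters yields a larger d.

The module also carries the small ChIP-qPCR arithmetic used for wet-lab
validation: fold difference over mock, and the pooled background average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import WINDOW_PRESETS, WindowParams, assign_peaks_to_promoters, promoter_windows
from .peaks import BinnedCoverage

DEFAULT_P_GRID = tuple(np.logspace(-2, -15, 14))


@dataclass
class LabeledGeneSets:
    foreground: set
    background: set
    mode: str = "max_binding"

    def __post_init__(self):
        if self.foreground & self.background:
            raise ValueError("foreground and background must be disjoint")


def build_reference_sets(
    genes: pd.DataFrame, reference_positive: set, mode: str = "max_binding"
) -> LabeledGeneSets:
    """Split expressed genes at their median expression and intersect with a
    reference gene set.

    Foreground: top-half expressed genes that are reference-positive.
    Background: bottom-half expressed genes that are reference-negative.
    Genes with expression 0 are excluded ("expressed genes" only); genes
    exactly at the median are dropped from both halves so the split is
    symmetric and deterministic.
    """
    expressed = genes[genes["expression"] > 0]
    if expressed.empty:
        raise ValueError("no expressed genes (expression > 0)")
    med = expressed["expression"].median()
    top = set(expressed.loc[expressed["expression"] > med, "gene_id"])
    bottom = set(expressed.loc[expressed["expression"] < med, "gene_id"])
    fg = top & reference_positive
    bg = bottom - reference_positive
    if not fg:
        raise ValueError(
            "foreground is empty: no top-half expressed gene is reference-positive"
        )
    if not bg:
        raise ValueError(
            "background is empty: every bottom-half expressed gene is reference-positive"
        )
    return LabeledGeneSets(foreground=fg, background=bg, mode=mode)


@dataclass
class ROCCurve:
    """Sensitivity/specificity points over p-value cutoffs, with trapezoidal AUC."""

    points: pd.DataFrame  # columns: p_cutoff, sensitivity, specificity, x, y
    auc: float

    def __post_init__(self):
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")


def _trapezoid_auc(x: np.ndarray, y: np.ndarray) -> float:
    order = np.lexsort((y, x))
    return float(np.trapezoid(y[order], x[order]))


def roc_from_peaks(
    peaks,
    genes: pd.DataFrame,
    reference_sets: LabeledGeneSets,
    window: WindowParams = WINDOW_PRESETS["default"],
    p_grid=DEFAULT_P_GRID,
    chrom_lengths: dict | None = None,
) -> ROCCurve:
    """ROC of promoter binding over a grid of peak p-value cutoffs.

    At each cutoff: sensitivity = bound foreground fraction, specificity =
    unbound background fraction. The curve is anchored at (0,0) and (1,1)
    and the AUC is the trapezoidal area under the sorted points.
    """
    fg, bg = reference_sets.foreground, reference_sets.background
    if not fg or not bg:
        raise ValueError("foreground and background must both be non-empty")
    eval_genes = genes[genes["gene_id"].isin(fg | bg)]
    _, best = assign_peaks_to_promoters(peaks, eval_genes, window, chrom_lengths)
    best_nlp = {g: p.neg_log10_pvalue for g, p in best.items()}
    rows = []
    for cutoff in p_grid:
        min_nlp = -np.log10(cutoff)
        bound = {g for g, nlp in best_nlp.items() if nlp >= min_nlp}
        sens = len(bound & fg) / len(fg)
        spec = len(bg - bound) / len(bg)
        rows.append(
            {
                "p_cutoff": cutoff,
                "sensitivity": sens,
                "specificity": spec,
                "x": 1.0 - spec,
                "y": sens,
            }
        )
    pts = pd.DataFrame(rows)
    x = np.concatenate([[0.0], pts["x"].to_numpy(), [1.0]])
    y = np.concatenate([[0.0], pts["y"].to_numpy(), [1.0]])
    auc = _trapezoid_auc(x, y)
    return ROCCurve(points=pts, auc=auc)


@dataclass
class ECDFComparison:
    """Paired empirical CDFs of promoter signal and their maximum gap d."""

    support: np.ndarray
    fg_cdf: np.ndarray
    bg_cdf: np.ndarray
    d: float
    d_location: float = field(default=float("nan"))

    def __post_init__(self):
        if not (0.0 <= self.d <= 1.0):
            raise ValueError("d must lie in [0, 1]")


def ecdf_distance(signal_fg, signal_bg) -> ECDFComparison:
    """Maximum vertical distance between the foreground and background
    empirical CDFs (the two-sample Kolmogorov-Smirnov statistic)."""
    fg = np.sort(np.asarray(signal_fg, dtype=float))
    bg = np.sort(np.asarray(signal_bg, dtype=float))
    if fg.size == 0 or bg.size == 0:
        raise ValueError("both signal samples must be non-empty")
    support = np.unique(np.concatenate([fg, bg]))
    fg_cdf = np.searchsorted(fg, support, side="right") / fg.size
    bg_cdf = np.searchsorted(bg, support, side="right") / bg.size
    gaps = np.abs(fg_cdf - bg_cdf)
    i = int(np.argmax(gaps))
    return ECDFComparison(
        support=support,
        fg_cdf=fg_cdf,
        bg_cdf=bg_cdf,
        d=float(gaps[i]),
        d_location=float(support[i]),
    )


def promoter_signal(
    coverage: BinnedCoverage,
    genes: pd.DataFrame,
    window: WindowParams = WINDOW_PRESETS["default"],
) -> pd.Series:
    """Raw promoter signal per gene: per-bp fragment coverage summed over the
    promoter window, scaled to reads per million."""
    wins = promoter_windows(genes, window, coverage.chrom_lengths)
    scale = coverage.rpm_scale() * coverage.bin_size
    out = np.zeros(len(wins))
    for i, rec in enumerate(wins.itertuples(index=False)):
        cv = coverage.counts.get(rec.chrom)
        if cv is None:
            continue
        b0 = rec.start // coverage.bin_size
        b1 = (rec.end - 1) // coverage.bin_size
        out[i] = cv[b0 : b1 + 1].sum() * scale
    return pd.Series(out, index=wins["gene_id"].to_numpy())


def ecdf_from_reference(
    coverage: BinnedCoverage,
    genes: pd.DataFrame,
    reference_sets: LabeledGeneSets,
    window: WindowParams = WINDOW_PRESETS["default"],
) -> ECDFComparison:
    """ECDF comparison of promoter signal between FG and BG gene sets."""
    signal = promoter_signal(coverage, genes, window)
    fg = signal[signal.index.isin(reference_sets.foreground)]
    bg = signal[signal.index.isin(reference_sets.background)]
    return ecdf_distance(fg.to_numpy(), bg.to_numpy())


def qpcr_fold_difference(chip_percent_input, mock_percent_input):
    """Fold difference of ChIP recovery over the parental mock cells.

    Vectorized over loci; the mock value must be positive everywhere.
    """
    chip = np.asarray(chip_percent_input, dtype=float)
    mock = np.asarray(mock_percent_input, dtype=float)
    if np.any(mock <= 0):
        raise ValueError("mock recovery must be > 0 (fold difference undefined)")
    fold = chip / mock
    if np.isscalar(chip_percent_input) and np.isscalar(mock_percent_input):
        return float(fold)
    return fold


def background_average(mock_pos, mock_neg, chip_neg) -> float:
    """Pooled ChIP background level.

    Arithmetic mean of the mock/IgG recovery at the positive and negative
    control regions plus the specific ChIP recovery at the negative regions
    (canonically 2 + 2 + 2 values).
    """
    pools = [np.atleast_1d(np.asarray(x, dtype=float)) for x in (mock_pos, mock_neg, chip_neg)]
    values = np.concatenate(pools)
    if values.size == 0:
        raise ValueError("no values supplied")
    if tuple(p.size for p in pools) != (2, 2, 2):
        warnings.warn(
            "background_average canonically pools 2+2+2 values; averaging what was given",
            stacklevel=2,
        )
    return float(values.mean())
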