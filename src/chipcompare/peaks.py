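"""Simplified Poisson peak caller with mock/IgG control normalisation.

The decision structure mirrors the classic local-background caller: collapse
duplicate reads, extend each read to the sequencing fragment length, find
candidate regions where fragment coverage exceeds a fold of the genome-wide
rate, then score each candidate with a Poisson upper-tail p-value against a
local expectation estimated from the depth-scaled control (the most
conservative of 1 kb / 5 kb / 10 kb windows and the genome-wide rate).
P-values are carried in -log10 form so deeply significant peaks stay
rankable, and peaks are reported at a caller-level cutoff (1e-8 by default
downstream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import Peak

LOCAL_LAMBDA_WINDOWS = (1_000, 5_000, 10_000)
LN10 = math.log(10.0)


@dataclass(frozen=True)
class PeakCallParams:
    fragment_length: int = 200
    bin_size: int = 10
    seed_fold: float = 5.0
    merge_gap: int = 100
    min_width: int = 20

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.fragment_length <= 0:
            raise ValueError("fragment_length must be positive")
        if self.seed_fold <= 0:
            raise ValueError("seed_fold must be positive")


def collapse_duplicates(reads: pd.DataFrame) -> pd.DataFrame:
    """Keep at most one read per (chrom, 5' position, strand).

    The 5' position of a - strand read is its end - 1. Output is canonically
    sorted so the result does not depend on input order.
    """
    if reads.empty:
        return reads.copy()
    pos5 = np.where(reads["strand"] == "+", reads["start"], reads["end"] - 1)
    df = reads.assign(_pos5=pos5)
    df = df.drop_duplicates(subset=["chrom", "_pos5", "strand"], keep="first")
    df = df.sort_values(["chrom", "start", "end", "strand"], kind="mergesort")
    return df.drop(columns="_pos5").reset_index(drop=True)


@dataclass
class BinnedCoverage:
    """Fragment coverage in fixed-size bins: counts[chrom][b] is the number
    of (extended) fragments overlapping bin b."""

    bin_size: int
    counts: dict  # chrom -> int64 array
    chrom_lengths: dict
    n_reads: int
    fragment_length: int

    def mean_bin_count(self) -> float:
        total = sum(int(c.sum()) for c in self.counts.values())
        nbins = sum(len(c) for c in self.counts.values())
        return total / nbins if nbins else 0.0

    def rpm_scale(self) -> float:
        return 1e6 / self.n_reads if self.n_reads else 0.0


def fragment_spans(reads: pd.DataFrame, fragment_length: int, chrom_length: int):
    """Per-read fragment [start, end) after extension from the 5' end in the
    strand direction, clipped at chromosome bounds."""
    pos5 = np.where(reads["strand"] == "+", reads["start"], reads["end"] - 1)
    start = np.where(reads["strand"] == "+", pos5, pos5 - fragment_length + 1)
    start = np.clip(start, 0, None)
    end = np.minimum(start + fragment_length, chrom_length)
    start = np.minimum(start, end - 1)
    return start.astype(np.int64), end.astype(np.int64)


def build_coverage(
    reads: pd.DataFrame,
    fragment_length: int,
    bin_size: int,
    chrom_lengths: dict,
) -> BinnedCoverage:
    """Binned fragment coverage: each read extended to fragment_length from
    its 5' end; counts are fragments overlapping each bin."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if not reads.empty:
        max_read = int((reads["end"] - reads["start"]).max())
        if fragment_length < max_read:
            raise ValueError(
                f"fragment_length {fragment_length} shorter than longest read {max_read}"
            )
    counts = {}
    for chrom, L in chrom_lengths.items():
        nbins = (L + bin_size - 1) // bin_size
        diff = np.zeros(nbins + 1, dtype=np.int64)
        sub = reads[reads["chrom"] == chrom]
        if not sub.empty:
            start, end = fragment_spans(sub, fragment_length, L)
            b0 = start // bin_size
            b1 = (end - 1) // bin_size
            np.add.at(diff, b0, 1)
            np.add.at(diff, b1 + 1, -1)
        counts[chrom] = np.cumsum(diff[:-1])
    return BinnedCoverage(
        bin_size=bin_size,
        counts=counts,
        chrom_lengths=dict(chrom_lengths),
        n_reads=len(reads),
        fragment_length=fragment_length,
    )


def _log_poisson_tail_series(k: int, lam: float) -> float:
    """log P(X >= k) by log-space summation of the pmf series; accurate far
    beyond the double-precision underflow point of the linear sf."""
    from scipy.special import gammaln, logsumexp

    j = np.arange(k, k + 2_000)
    terms = -lam + j * math.log(lam) - gammaln(j + 1)
    return float(logsumexp(terms))


def poisson_tail(count, lam, log10: bool = False):
    """Upper-tail Poisson probability P(X >= count) for X ~ Poisson(lam).

    Computed in log space (via the regularised gamma survival function) so
    very small tails do not underflow before -log10 conversion. Scalar in,
    scalar out; arrays broadcast.
    """
    count_arr = np.asarray(count)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(count_arr < 0):
        raise ValueError("count must be >= 0")
    if np.any(lam_arr <= 0):
        raise ValueError("lam must be > 0")
    # P(X >= k) = sf(k - 1)
    logp = np.asarray(stats.poisson.logsf(count_arr - 1, lam_arr), dtype=float)
    # logsf underflows to -inf once sf drops below the smallest normal float;
    # recover those entries by summing the pmf series directly in log space
    if np.any(np.isneginf(logp)):
        flat = np.broadcast_arrays(count_arr, lam_arr)
        k_flat = np.ravel(flat[0])
        l_flat = np.ravel(flat[1]).astype(float)
        fixed = np.ravel(logp.copy())
        for i in np.flatnonzero(np.isneginf(fixed)):
            fixed[i] = _log_poisson_tail_series(int(k_flat[i]), float(l_flat[i]))
        logp = fixed.reshape(np.shape(logp))
    log10p = logp / LN10
    result = log10p if log10 else np.exp(logp)
    if np.isscalar(count) and np.isscalar(lam):
        return float(result)
    return result


def _candidate_regions(cov_counts: np.ndarray, threshold: float, merge_gap_bins: int):
    """Maximal runs of bins with count >= threshold, merged across gaps of at
    most merge_gap_bins bins. Returns (first_bin, last_bin) inclusive pairs."""
    above = cov_counts >= threshold
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > merge_gap_bins + 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def shifted_tag_positions(reads: pd.DataFrame, fragment_length: int) -> dict:
    """Fragment-midpoint ("shifted tag") positions per chromosome, sorted."""
    out = {}
    shift = fragment_length // 2
    for chrom, sub in reads.groupby("chrom"):
        pos5 = np.where(sub["strand"] == "+", sub["start"], sub["end"] - 1)
        pos = np.where(sub["strand"] == "+", pos5 + shift, pos5 - shift)
        out[chrom] = np.sort(pos)
    return out


def call_peaks(
    treatment: pd.DataFrame,
    control: pd.DataFrame,
    chrom_lengths: dict,
    params: PeakCallParams = PeakCallParams(),
    p_cutoff: float | None = None,
) -> list[Peak]:
    """Call enriched regions in treatment over a mock/IgG control.

    Both read sets are expected to be duplicate-collapsed. The control is
    scaled to treatment depth by the ratio of collapsed read counts; the
    local expectation for each candidate is the maximum control rate over
    1 kb / 5 kb / 10 kb windows centred on the candidate and the genome-wide
    rate, times the candidate width. Peaks are sorted by significance.
    """
    if treatment.empty:
        return []
    if control.empty:
        raise ValueError("peak calling requires a non-empty control read set")
    genome_size = sum(chrom_lengths.values())
    if genome_size <= 0:
        raise ValueError("zero-length genome")

    cov = build_coverage(treatment, params.fragment_length, params.bin_size, chrom_lengths)
    mean_bin = cov.mean_bin_count()
    if mean_bin <= 0:
        return []
    threshold = params.seed_fold * mean_bin
    merge_gap_bins = max(params.merge_gap // params.bin_size, 0)

    treat_tags = shifted_tag_positions(treatment, params.fragment_length)
    ctrl_tags = shifted_tag_positions(control, params.fragment_length)
    scale = len(treatment) / len(control)
    genome_rate = len(control) * scale / genome_size

    peaks: list[Peak] = []
    for chrom, L in chrom_lengths.items():
        counts = cov.counts[chrom]
        regions = _candidate_regions(counts, threshold, merge_gap_bins)
        if not regions:
            continue
        t_pos = treat_tags.get(chrom, np.empty(0, dtype=np.int64))
        c_pos = ctrl_tags.get(chrom, np.empty(0, dtype=np.int64))
        for b0, b1 in regions:
            start = b0 * params.bin_size
            end = min((b1 + 1) * params.bin_size, L)
            width = end - start
            if width < params.min_width:
                continue
            tag_count = int(
                np.searchsorted(t_pos, end) - np.searchsorted(t_pos, start)
            )
            if tag_count < 1:
                continue
            center = (start + end) // 2
            rate = genome_rate
            for w in LOCAL_LAMBDA_WINDOWS:
                lo, hi = center - w // 2, center + w // 2
                c_count = np.searchsorted(c_pos, hi) - np.searchsorted(c_pos, lo)
                rate = max(rate, c_count * scale / w)
            lam = rate * width
            nlp = -poisson_tail(tag_count, lam, log10=True)
            summit_bin = b0 + int(np.argmax(counts[b0 : b1 + 1]))
            summit = min(summit_bin * params.bin_size + params.bin_size // 2, end - 1)
            summit = max(summit, start)
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    summit=int(summit),
                    tag_count=tag_count,
                    fold_enrichment=tag_count / lam,
                    neg_log10_pvalue=float(nlp),
                )
            )
    peaks.sort(key=lambda p: (-p.neg_log10_pvalue, p.chrom, p.start))
    if p_cutoff is not None:
        peaks = threshold_peaks(peaks, p_cutoff)
    return peaks


def threshold_peaks(peaks, p_cutoff: float):
    """Retain peaks with p-value <= p_cutoff (stable order)."""
    if not (0.0 < p_cutoff <= 1.0):
        raise ValueError(f"p_cutoff must be in (0, 1], got {p_cutoff}")
    min_nlp = -math.log10(p_cutoff)
    return [p for p in peaks if p.neg_log10_pvalue >= min_nlp]


def peak_counts_by_cutoff(peaks, p_grid) -> pd.DataFrame:
    """Number of surviving peaks at each p-value cutoff (loosest first)."""
    rows = [
        {"p_cutoff": p, "n_peaks": len(threshold_peaks(peaks, p))} for p in p_grid
    ]
    return pd.DataFrame(rows)
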