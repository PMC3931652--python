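"""Known-motif scanning and enrichment for peak sets.

The motif of interest is the E-box CACGTG bound by Myc/Max dimers. It is its
own reverse complement, so a double-strand scan must guard against counting
each genomic occurrence twice; non-palindromic motifs are scanned on both
strands. Enrichment of hit-bearing peaks over a background model (dinucleotide
shuffles of the peak sequences, or length-matched random genomic intervals) is
scored with an upper-tail binomial test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import GenomicInterval

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    strand: str
    matched: str


def _find_all(seq: str, pattern: str):
    """Overlapping occurrences of pattern in seq (N never matches)."""
    start = 0
    while True:
        i = seq.find(pattern, start)
        if i < 0:
            return
        yield i
        start = i + 1


def scan_motif(sequence: str, motif: str = "CACGTG", chrom: str = "seq", offset: int = 0):
    """All occurrences of motif on both strands of sequence.

    For palindromic motifs (motif == its reverse complement) each genomic
    position is reported exactly once, on the + strand. ``offset`` shifts
    reported coordinates (e.g. the genomic start of the scanned window).
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    motif = motif.upper()
    if any(b not in "ACGT" for b in motif):
        raise ValueError("motif must be non-degenerate over ACGT")
    seq = sequence.upper()
    hits = []
    for i in _find_all(seq, motif):
        hits.append(
            MotifHit(
                GenomicInterval(chrom, offset + i, offset + i + len(motif), "+"),
                "+",
                seq[i : i + len(motif)],
            )
        )
    rc = reverse_complement(motif)
    if rc != motif:
        for i in _find_all(seq, rc):
            hits.append(
                MotifHit(
                    GenomicInterval(chrom, offset + i, offset + i + len(motif), "-"),
                    "-",
                    seq[i : i + len(motif)],
                )
            )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide (and hence
    mononucleotide) counts, via a random Eulerian path on the dinucleotide
    multigraph (Altschul-Erickson)."""
    if len(seq) <= 2:
        return seq
    s = seq.upper()
    last = s[-1]
    # adjacency: successor lists per vertex (character)
    adj: dict[str, list] = {}
    for a, b in zip(s[:-1], s[1:]):
        adj.setdefault(a, []).append(b)
    vertices = sorted(adj.keys() | {last})
    for _ in range(1000):
        # pick a random terminal edge per non-terminal vertex, check that the
        # chosen edges form a tree oriented toward the terminal vertex
        last_edge = {}
        for v in vertices:
            if v == last or v not in adj:
                continue
            last_edge[v] = adj[v][rng.integers(len(adj[v]))]
        ok = True
        for v in last_edge:
            seen = {v}
            cur = v
            while cur != last:
                nxt = last_edge.get(cur)
                if nxt is None or nxt in seen:
                    ok = False
                    break
                seen.add(nxt)
                cur = nxt
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - connected input always succeeds quickly
        raise RuntimeError("dinucleotide shuffle failed to find an Eulerian order")
    out = [s[0]]
    remaining = {}
    for v, succ in adj.items():
        succ = list(succ)
        if v in last_edge:
            succ.remove(last_edge[v])
        rng.shuffle(succ)
        if v in last_edge:
            succ.append(last_edge[v])
        remaining[v] = succ[::-1]  # pop() from the end
    cur = s[0]
    for _ in range(len(s) - 1):
        nxt = remaining[cur].pop()
        out.append(nxt)
        cur = nxt
    result = "".join(out)
    assert _dinuc_counts(result) == _dinuc_counts(s), "shuffle broke dinucleotide counts"
    return result


def _dinuc_counts(seq: str) -> dict:
    counts: dict[str, int] = {}
    for a, b in zip(seq[:-1], seq[1:]):
        counts[a + b] = counts.get(a + b, 0) + 1
    return counts


@dataclass
class EnrichmentResult:
    motif: str
    n_peaks: int
    n_with_hit: int
    fraction_with_hit: float
    background_rate: float
    fold_vs_background: float
    pvalue: float
    pvalue_is_bound: bool = False  # True when background rate was 0


def motif_enrichment(
    peak_sequences,
    motif: str = "CACGTG",
    background: str = "shuffle",
    background_sequences=None,
    n_shuffles: int = 2,
    rng: np.random.Generator | None = None,
) -> EnrichmentResult:
    """Binomial enrichment of motif-bearing peaks over a background model.

    background='shuffle' estimates the null per-peak hit rate from
    ``n_shuffles`` dinucleotide shuffles of every peak sequence;
    background='sampled' uses caller-provided ``background_sequences``
    (e.g. length-matched random genomic intervals). The p-value is the
    upper-tail binomial probability of observing at least the seen number of
    hit-bearing peaks at the background rate.
    """
    peak_sequences = list(peak_sequences)
    if not peak_sequences:
        raise ValueError("need at least one peak sequence")
    if background == "shuffle":
        if rng is None:
            rng = np.random.default_rng(0)
        bg_seqs = [
            dinucleotide_shuffle(s, rng) for s in peak_sequences for _ in range(n_shuffles)
        ]
    elif background == "sampled":
        if not background_sequences:
            raise ValueError("background='sampled' requires background_sequences")
        bg_seqs = list(background_sequences)
    else:
        raise ValueError(f"unknown background model {background!r}")

    def has_hit(s):
        return bool(scan_motif(s, motif))

    n = len(peak_sequences)
    k = sum(has_hit(s) for s in peak_sequences)
    bg_hits = sum(has_hit(s) for s in bg_seqs)
    p0 = bg_hits / len(bg_seqs)
    bound = False
    if p0 == 0.0:
        if k > 0:
            warnings.warn(
                "background rate is 0 with observed hits; reporting an upper "
                "bound on the p-value",
                stacklevel=2,
            )
            bound = True
            p0_eff = 1.0 / (len(bg_seqs) + 1)
        else:
            p0_eff = 1.0 / (len(bg_seqs) + 1)
    else:
        p0_eff = p0
    pvalue = float(stats.binom.sf(k - 1, n, p0_eff)) if k > 0 else 1.0
    frac = k / n
    fold = frac / p0 if p0 > 0 else math.inf if k else float("nan")
    return EnrichmentResult(
        motif=motif.upper(),
        n_peaks=n,
        n_with_hit=k,
        fraction_with_hit=frac,
        background_rate=p0,
        fold_vs_background=fold,
        pvalue=pvalue,
        pvalue_is_bound=bound,
    )


def peak_sequences(genome: dict, peaks, flank: int = 100):
    """Summit-centered sequences (+/- flank bp) for a list of peaks."""
    out = []
    for p in peaks:
        seq = genome[p.chrom]
        lo = max(p.summit - flank, 0)
        hi = min(p.summit + flank, len(seq))
        out.append(seq[lo:hi])
    return out
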