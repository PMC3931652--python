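# Methods note

## Purpose

`chipcompare` quantifies how the non-specific background level of a ChIP
experiment limits what a standard peak-calling analysis can recover. Because
every dataset is simulated, recovery can be scored against the exact planted
truth instead of a proxy. The package contrasts two read profiles of the same
ground truth — *tagged* (5% uniform background, emulating a stringent
streptavidin pull-down of a biotin-tagged factor) and *antibody* (40%
background, a conventional IP) — plus a background-only *mock* control.

## Generator

**Genome.** One chromosome of i.i.d. bases at a configurable GC content
(default 0.5, length 20 Mb). This is deliberately the simplest sequence model
that supports motif planting and CpG statistics; see Limitations.

**Genes.** 2,000 TSSs are placed uniformly subject to a minimum spacing of
8 kb and a 5 kb margin at each chromosome end (sorted uniform offsets plus a
deterministic gap; exact, no rejection). Strands are uniform. Expression is
log-normal(μ=1, σ=1) with a 20% zero-inflated silenced fraction.

The 8 kb spacing is a deliberate design point: it keeps all supported
promoter windows (up to −3 kb/+2 kb) non-overlapping while leaving roughly a
fifth of the genome more than 5 kb from any TSS, so the distal-site
constraint below remains satisfiable at the default gene density. A 10 kb
spacing would saturate a 20 Mb / 2,000-gene genome exactly and leave
essentially no legal distal positions.

**Binding sites.** 300 sites, 80% promoter / 20% distal. Promoter sites are
assigned to distinct genes with probability proportional to
expression^2 (weighted sampling without replacement via the Gumbel-max
trick), at a uniform strand-aware offset in [−800, +200] bp from the TSS.
The quadratic coupling encodes the empirical pattern that strong activator
binding concentrates at highly expressed promoters; it also makes the
H3K4me3-positive reference set (top 20% of genes by expression, below)
informative about binding. Distal sites are rejection-sampled at least 5 kb
from every TSS and 1 kb from each other. 90% of sites get a literal CACGTG
written at their center; per-site read-emission strength is
log-normal(0, 2.5), so site intensities span several orders of magnitude and
the weakest sites sit near the detection limit — exactly the regime where
background level matters.

**Reads.** Single-end 36 bp reads. A signal read selects a site proportional
to strength, then a 200 bp fragment positioned uniformly so the site center
lies inside it; the read is the fragment's 5′ end on a random strand. This
reproduces the canonical strand asymmetry (mean 5′ separation ≈ fragment
length) that fragment-midpoint shifting exploits. Background reads are
uniform fragments. The mock control is 100% background at the same depth.

**Histone marks.** H3K4me3 intervals cover the promoter windows of the top
20% of genes by expression; a further 10% random low-expression subset is
bivalent (H3K4me3 + H3K27me3). Distal true sites get H3K4me1 (±500 bp), 60%
of them also H3K27ac (active enhancers). The planted labels are returned
alongside the intervals so classification can be round-trip-tested.

## Pipeline

**Peak calling.** Reads are duplicate-collapsed per (chromosome, 5′
position, strand), extended to the fragment length, and binned at 10 bp
(difference-array / cumulative-sum). Candidate regions are runs of bins at
≥5× the genome-wide mean bin count, merged over gaps ≤100 bp, minimum width
20 bp. Each candidate is scored with a Poisson upper tail P(X ≥ tags) whose
expectation is the most conservative of the depth-scaled control rate in
1 kb / 5 kb / 10 kb windows around the candidate and the genome-wide rate,
times the candidate width. The tail is computed in log space
(`poisson.logsf`), with a log-sum-exp series fallback where the linear
survival function underflows double precision, so −log10(p) stays finite and
rankable for arbitrarily strong peaks. The reporting cutoff is p ≤ 1e-8.

**Promoter assignment.** Strand-aware TSS windows (default −1 kb/+1 kb; a
−3 kb/+2 kb preset exists for factors binding further upstream), half-open
coordinates, interval-tree overlap.

**Evaluation.** Reference-positive gene sets are either the planted truth
(genes whose promoter window contains a site) or the H3K4me3-marked genes.
Foreground = top-half expressed genes that are positive; background =
bottom-half expressed genes that are not; zero-expression genes are excluded
and genes exactly at the median are dropped from both halves. The ROC sweeps
peak p-value cutoffs over a 14-point grid (1e-2 … 1e-15), anchors at (0,0)
and (1,1), and integrates by the trapezoid rule; with per-gene scores on the
grid this equals the pair-ordering (Mann-Whitney) probability, which the
acceptance suite asserts. The cumulative-signal distance *d* is the maximum
vertical gap between the foreground and background empirical CDFs of raw
promoter signal — the two-sample Kolmogorov-Smirnov statistic. Promoter
signal and heatmap matrices are reported in reads-per-million (RPM) summed
per-bp coverage, so values are comparable across datasets of different
depth.

**Motif.** CACGTG is its own reverse complement, so scanning counts each
genomic occurrence once (plus strand only); non-palindromic motifs are
scanned on both strands. Enrichment compares the fraction of hit-bearing
peak sequences (summit ±100 bp) against dinucleotide-preserving shuffles
(Altschul–Erickson Euler-walk shuffle, two per sequence) with an upper-tail
binomial test; a zero estimated background rate is replaced by the
1/(N+1) upper bound and flagged.

**Determinism.** Every stage draws from `SeedSequence(seed, spawn_key=...)`
streams keyed by stage name, so outputs are bit-reproducible per (config,
seed) and independent of execution order. Reports round floats to six
digits and serialize with sorted keys; two runs at the same seed produce
byte-identical `summary.yaml` files (asserted in the acceptance suite).

## Problem sizes and budgets

Unit tests run at 4 Mb / 300 genes / 60 sites / 200k reads (seconds). The
acceptance suite and `scripts/acceptance.py` run the full study scale
(20 Mb / 2,000 genes / 300 sites / 1e6 reads per dataset); one replicate
takes ~5–7 s on one CPU, the 20-replicate headline test ~2.5 minutes, and
the acceptance script ~1–2 minutes.

## Generator realism and limitations

* The i.i.d. genome has no CpG depletion, isochores, or repeats, so CpG
  promoter classes are driven almost entirely by sampling noise: at GC 0.5
  nearly all windows have CpG observed/expected near 1, and most simulated
  promoters classify as high-CpG. The HCP/ICP/LCP classifier is therefore
  validated against sequence oracles, not against a realistic class mix.
* Background reads are uniform; real non-specific pull-down is biased by
  chromatin accessibility and mappability. Uniform background makes the
  local-lambda control conservative relative to real data.
* One chromosome, single-end reads, no read errors or mappability gaps.
* Site strengths are independent of the motif flag and of expression given
  the site's gene; real occupancy correlates with motif quality.
* The mixture structure means the measured *d* scales with the fraction of
  foreground promoters that are genuinely bound: with foreground sets much
  larger than the bound set, *d* is diluted for both profiles equally. The
  default H3K4me3 fraction (top 20%) keeps the H3K4me3 reference mode
  informative at the default site count.

No empirical claims are made in this note beyond quantities computed by the
test suite or `scripts/acceptance.py`.
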