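# chipcompare

Comparative benchmarking of ChIP-Seq experimental designs on fully synthetic
experiments with known ground truth.

## Scientific problem

Chromatin immunoprecipitation followed by sequencing (ChIP-Seq) maps where a
DNA-binding protein sits on the genome. How well it works depends heavily on
the pull-down chemistry: a stringent streptavidin capture of an in-vivo
biotinylated (Bio-tagged) factor recovers very little non-specific DNA, while
a conventional antibody IP of the same factor can carry a large uniform
background. With real data the true binding sites are unknown, so the two
designs can only be compared indirectly. `chipcompare` makes the comparison
direct: it simulates a complete toy experiment — genome, genes with
expression levels, true E-box (CACGTG) binding sites, sequencing reads at a
tunable signal-to-background ratio, histone-mark tracks — and then runs a
full analysis pipeline against the known truth.

## Model

* **Genome & genes.** A single i.i.d. chromosome (default 20 Mb, GC 0.5)
  carries 2,000 genes whose TSSs are uniform given an 8 kb minimum spacing;
  expression is log-normal with a 20% silenced fraction.
* **True sites.** 300 sites, 80% at promoters (chosen with probability
  proportional to expression², offset −800..+200 bp from the TSS,
  strand-aware) and 20% distal (≥5 kb from every TSS). 90% of sites carry a
  planted CACGTG; per-site strength is log-normal(0, 2.5).
* **Reads.** Each signal read picks a site proportional to its strength, a
  200 bp fragment containing it, and reports the fragment's 5′ end on a
  random strand (the classic strand asymmetry). Background reads are uniform.
  The *tagged* profile uses 5% background, the *antibody* profile 40%; a
  *mock* control is 100% background.
* **Pipeline.** Duplicate collapse → fragment-extended binned coverage →
  candidate regions ≥5× the genome-wide rate → Poisson upper-tail p-value
  against a local lambda from the depth-scaled control (1/5/10 kb windows) →
  promoter assignment in strand-aware TSS windows → Venn decomposition,
  dataset correlation clustering, TSS heatmap matrices → ROC/AUC and the
  cumulative-signal distance *d* (two-sample KS statistic) against
  ground-truth and H3K4me3-based reference gene sets → E-box enrichment over
  dinucleotide-shuffled backgrounds.

## Worked example

A small experiment (4 Mb, 300 genes, 60 sites, 200k reads per dataset):

```bash
cat > config.yaml <<'YAML'
seed: 5
simulation:
  genome_length: 4000000
  n_genes: 300
  n_true_sites: 60
  n_reads: 200000
YAML
chipcompare run --config config.yaml --out-dir out
```

This writes `out/summary.yaml`, per-stage TSV tables, narrowPeak files, and
prints:

```
# ChIP-Seq profile comparison

Seed: 5

## Per-profile summary

| metric | antibody | tagged |
|---|---|---|
| background_fraction | 0.4 | 0.05 |
| n_peaks | 36 | 47 |
| n_bound_promoters | 31 | 40 |
| auc_max_binding | 0.826087 | 0.913043 |
| auc_k4me3 | 0.664349 | 0.713314 |
| d_max_binding | 0.797826 | 0.891304 |
| d_k4me3 | 0.396154 | 0.492308 |

## Motif enrichment

- antibody: CACGTG in 0.972 of peaks (17.50x background, p = 0)
- tagged: CACGTG in 0.979 of peaks (15.33x background, p = 0)

## Bound-promoter Venn patterns

- antibody&tagged&truth: 31
- tagged&truth: 9
- truth: 8
```

Reading it: the low-background tagged profile finds more peaks (47 vs 36),
binds more true promoters (40 vs 31, with the antibody set fully nested
inside it), and separates bound from unbound promoters better on every
metric (e.g. AUC 0.913 vs 0.826 against the ground truth). Both peak sets
are saturated with the planted E-box. The genome-wide correlation clustering
in `out/summary.yaml` groups the two ChIP datasets first (Pearson r = 0.977)
and leaves the mock control outside (r ≈ 0.02).

Each stage is also available as its own subcommand (`chipcompare simulate`,
`callpeaks`, `annotate`, `compare`, `evaluate`, `motif`, `report`); see
`chipcompare --help`.

## Reproduction

The study-scale benchmark (20 Mb, 2,000 genes, 300 sites, 1e6 reads,
tagged 5% vs antibody 40% background) is reproduced by:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which runs 10 seeded replicates plus recovery/false-positive/motif checks
(about 1–2 minutes) and writes every quantity as
`{"name": {"value": ..., "n": ...}}`. With `--seed 1` it reports, among
others:

```
auc_max_binding_tagged:   0.916882 (n=10)
auc_max_binding_antibody: 0.850994 (n=10)
d_max_binding_tagged:     0.892331 (n=10)
d_max_binding_antibody:   0.788411 (n=10)
tagged_wins_all_metrics_fraction: 1 (n=10)
strong_site_recovery_tagged: 1 (n=150)
background_only_peaks_total: 0 (n=5)
motif_fraction_with_hit_tagged: 0.944649 (n=271)
```

All randomness derives from `--seed`; re-running with the same seed is
bit-reproducible. See `docs/methods.md` for the modelling choices, numerical
details, and limitations.
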