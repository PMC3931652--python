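"""End-to-end orchestration: simulate -> call peaks -> annotate -> compare ->
evaluate -> motif -> report, with a single YAML-configurable entry point.

The default configuration contrasts a low-background ("tagged", 5% uniform
reads) and a high-background ("antibody", 40%) ChIP of the same ground-truth
binding sites, and reports promoter Venn counts, ROC/AUC and cumulative
signal distance d under both reference modes, motif enrichment, and peak
counts per p-value cutoff. Everything is deterministic under (config, seed).
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import annotate, cooccupancy, evaluate, formats, motif, peaks, simulate
from .annotate import WINDOW_PRESETS, WindowParams
from .core import SimulationConfig, stage_rng

log = logging.getLogger("chipcompare")

DEFAULT_PROFILES = {"tagged": 0.05, "antibody": 0.40}


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "chipcompare_out"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    profiles: dict = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    peak_params: peaks.PeakCallParams = field(default_factory=peaks.PeakCallParams)
    p_cutoff: float = 1e-8
    window: WindowParams = field(default_factory=lambda: WINDOW_PRESETS["default"])
    p_grid: tuple = evaluate.DEFAULT_P_GRID
    marks: dict = field(default_factory=dict)
    motif: str = "CACGTG"
    motif_flank: int = 100
    motif_shuffles: int = 2
    save_fixture: bool = False

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "simulation" in data:
            sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
            sim_unknown = set(data["simulation"]) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown simulation key(s): {sorted(sim_unknown)}")
            data["simulation"] = SimulationConfig(**data["simulation"])
        if "peak_params" in data:
            data["peak_params"] = peaks.PeakCallParams(**data["peak_params"])
        if "window" in data:
            w = data["window"]
            if isinstance(w, str):
                data["window"] = WINDOW_PRESETS[w]
            else:
                data["window"] = WindowParams(**w)
        if "p_grid" in data:
            data["p_grid"] = tuple(float(p) for p in data["p_grid"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def validate(self) -> None:
        sim = self.simulation.replace(seed=self.seed)
        sim.validate()
        if not self.profiles:
            raise ValueError("at least one profile is required")
        for name, bg in self.profiles.items():
            if not (0.0 <= bg <= 1.0):
                raise ValueError(f"profile {name!r}: background fraction {bg} not in [0,1]")
        if not (0.0 < self.p_cutoff <= 1.0):
            raise ValueError("p_cutoff must be in (0, 1]")
        if not self.p_grid:
            raise ValueError("p_grid must not be empty")


def _round_floats(obj, ndigits: int = 6):
    """Round all floats in a nested structure so serialized reports are
    byte-stable across runs."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the summary report bundle (also written to
    out_dir/summary.yaml along with per-stage tables)."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    sim_cfg = config.simulation.replace(seed=config.seed)

    log.info("stage=simulate profiles=%s", sorted(config.profiles))
    bundle = simulate.simulate_experiment(sim_cfg, config.profiles, config.marks)
    chrom_lengths = {c: len(s) for c, s in bundle.genome.items()}
    if config.save_fixture:
        simulate.write_fixture(bundle, os.path.join(config.out_dir, "fixture"))

    control = peaks.collapse_duplicates(bundle.reads["mock"])
    report: dict = {
        "seed": config.seed,
        "config_hash": simulate.config_hash(sim_cfg),
        "profiles": {},
        "venn": {},
        "correlation": {},
        "peak_counts": {},
    }

    peak_sets: dict[str, list] = {}
    bound_sets: dict[str, set] = {}
    coverages: dict[str, peaks.BinnedCoverage] = {}
    for label in sorted(config.profiles):
        log.info("stage=callpeaks profile=%s", label)
        treat = peaks.collapse_duplicates(bundle.reads[label])
        called = peaks.call_peaks(
            treat, control, chrom_lengths, config.peak_params, p_cutoff=None
        )
        kept = peaks.threshold_peaks(called, config.p_cutoff)
        peak_sets[label] = kept
        formats.write_peaks(
            os.path.join(config.out_dir, f"peaks_{label}.narrowPeak"), kept
        )
        bound, _ = annotate.assign_peaks_to_promoters(
            kept, bundle.genes, config.window, chrom_lengths
        )
        bound_sets[label] = bound
        coverages[label] = peaks.build_coverage(
            treat,
            config.peak_params.fragment_length,
            config.peak_params.bin_size,
            chrom_lengths,
        )
        report["peak_counts"][label] = {
            f"{p:.0e}": int(n)
            for p, n in peaks.peak_counts_by_cutoff(called, config.p_grid)
            .itertuples(index=False)
        }
        report["profiles"][label] = {
            "background_fraction": config.profiles[label],
            "n_peaks": len(kept),
            "n_bound_promoters": len(bound),
        }

    log.info("stage=annotate")
    mark_classes = annotate.classify_promoter_marks(
        bundle.genes, bundle.marks["H3K4me3"], bundle.marks["H3K27me3"], config.window
    )
    enhancer_classes = annotate.classify_enhancers(
        bundle.marks["H3K4me1"], bundle.marks["H3K27ac"], bundle.genes
    )
    k4me3_positive = {g for g, c in mark_classes.items() if c != "none"}
    cpg_classes = annotate.classify_cpg(bundle.genome, bundle.genes, config.window)
    annotate.class_table(bundle.genes, mark_classes, cpg_classes).to_csv(
        os.path.join(config.out_dir, "promoter_classes.tsv"), sep="\t", index=False
    )

    log.info("stage=compare")
    venn_sets = dict(bound_sets)
    venn_sets["truth"] = set(bundle.truth.bound_genes)
    venn = cooccupancy.promoter_venn(venn_sets)
    cooccupancy.venn_table(venn).to_csv(
        os.path.join(config.out_dir, "venn.tsv"), sep="\t", index=False
    )
    report["venn"]["patterns"] = {
        "&".join(sorted(k)): v for k, v in venn.counts.items()
    }
    report["venn"]["pairwise_fraction"] = {
        f"{a}|{b}": v for (a, b), v in venn.pairwise_fraction.items()
    }

    feature_sets = {
        "truth_sites": bundle.truth.sites,
        "H3K4me3_only_promoters": [
            annotate.promoter_window(g, config.window, chrom_lengths.get(g.chrom))
            for g in annotate.genes_from_frame(bundle.genes)
            if mark_classes[g.gene_id] == "H3K4me3_only"
        ],
        "active_enhancers": [iv for iv, c in enhancer_classes.items() if c == "active"],
    }
    for label in sorted(config.profiles):
        coloc = cooccupancy.peak_colocalization_curve(
            peak_sets[label], feature_sets, sorted(config.p_grid, reverse=True)
        )
        coloc.to_csv(
            os.path.join(config.out_dir, f"colocalization_{label}.tsv"),
            sep="\t",
            index=False,
        )

    corr_signals = {
        label: cooccupancy.genome_bin_vector(cov) for label, cov in coverages.items()
    }
    corr_signals["mock"] = cooccupancy.genome_bin_vector(
        peaks.build_coverage(
            control,
            config.peak_params.fragment_length,
            config.peak_params.bin_size,
            chrom_lengths,
        )
    )
    corr, _, merge_order = cooccupancy.dataset_correlation_clustering(corr_signals)
    report["correlation"]["pearson"] = {
        f"{a}|{b}": float(corr.loc[a, b]) for a in corr.index for b in corr.columns if a < b
    }
    report["correlation"]["merge_order"] = [
        ["+".join(sorted(a)), "+".join(sorted(b))] for a, b in merge_order
    ]

    log.info("stage=evaluate")
    references = {
        "max_binding": set(bundle.truth.bound_genes),
        "k4me3": k4me3_positive,
    }
    for label in sorted(config.profiles):
        for mode, positive in references.items():
            refsets = evaluate.build_reference_sets(bundle.genes, positive, mode)
            roc = evaluate.roc_from_peaks(
                peak_sets[label],
                bundle.genes,
                refsets,
                config.window,
                config.p_grid,
                chrom_lengths,
            )
            ecdf = evaluate.ecdf_from_reference(
                coverages[label], bundle.genes, refsets, config.window
            )
            report["profiles"][label][f"auc_{mode}"] = roc.auc
            report["profiles"][label][f"d_{mode}"] = ecdf.d
            roc.points.to_csv(
                os.path.join(config.out_dir, f"roc_{label}_{mode}.tsv"),
                sep="\t",
                index=False,
            )

    log.info("stage=motif")
    rng = stage_rng(config.seed, "motif-shuffle")
    for label in sorted(config.profiles):
        seqs = motif.peak_sequences(
            bundle.genome, peak_sets[label], flank=config.motif_flank
        )
        if seqs:
            enr = motif.motif_enrichment(
                seqs, config.motif, n_shuffles=config.motif_shuffles, rng=rng
            )
            report["profiles"][label]["motif"] = {
                "motif": enr.motif,
                "fraction_with_hit": enr.fraction_with_hit,
                "fold_vs_background": enr.fold_vs_background,
                "pvalue": enr.pvalue,
            }
        else:
            report["profiles"][label]["motif"] = None

    report = _round_floats(report)
    with open(os.path.join(config.out_dir, "summary.yaml"), "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=True)
    report_md = render_report(report)
    with open(os.path.join(config.out_dir, "report.md"), "w") as fh:
        fh.write(report_md)
    return report


REPORT_SECTIONS = ("seed", "profiles", "venn", "correlation", "peak_counts")


def render_report(report: dict) -> str:
    """Human-readable markdown summary of a pipeline report bundle."""
    missing = [s for s in REPORT_SECTIONS if s not in report]
    if missing:
        raise ValueError(f"report bundle incomplete; missing section(s): {missing}")
    lines = ["# ChIP-Seq profile comparison", ""]
    lines.append(f"Seed: {report['seed']}")
    lines.append("")
    lines.append("## Per-profile summary")
    lines.append("")
    labels = sorted(report["profiles"])
    metrics = [
        "background_fraction",
        "n_peaks",
        "n_bound_promoters",
        "auc_max_binding",
        "auc_k4me3",
        "d_max_binding",
        "d_k4me3",
    ]
    lines.append("| metric | " + " | ".join(labels) + " |")
    lines.append("|---|" + "---|" * len(labels))
    for m in metrics:
        row = [str(report["profiles"][l].get(m, "")) for l in labels]
        lines.append(f"| {m} | " + " | ".join(row) + " |")
    lines.append("")
    lines.append("## Motif enrichment")
    lines.append("")
    for l in labels:
        mo = report["profiles"][l].get("motif")
        if mo:
            lines.append(
                f"- {l}: {mo['motif']} in {mo['fraction_with_hit']:.3f} of peaks "
                f"({mo['fold_vs_background']:.2f}x background, p = {mo['pvalue']:.3g})"
            )
    lines.append("")
    lines.append("## Bound-promoter Venn patterns")
    lines.append("")
    for pattern, n in sorted(report["venn"]["patterns"].items()):
        lines.append(f"- {pattern}: {n}")
    lines.append("")
    return "\n".join(lines)


def profile_benchmark(
    sim_config: SimulationConfig,
    profiles: dict | None = None,
    peak_params: peaks.PeakCallParams = peaks.PeakCallParams(),
    p_cutoff: float = 1e-8,
    window: WindowParams = WINDOW_PRESETS["default"],
    p_grid=evaluate.DEFAULT_P_GRID,
    mark_params: dict | None = None,
) -> dict:
    """One replicate of the headline benchmark: same TruthSet, two read
    profiles, AUC and d under both reference modes.

    Returns {profile: {auc_max_binding, auc_k4me3, d_max_binding, d_k4me3,
    n_peaks, recovery stats...}} without touching the filesystem.
    """
    if profiles is None:
        profiles = dict(DEFAULT_PROFILES)
    bundle = simulate.simulate_experiment(sim_config, profiles, mark_params)
    chrom_lengths = {c: len(s) for c, s in bundle.genome.items()}
    control = peaks.collapse_duplicates(bundle.reads["mock"])
    mark_classes = annotate.classify_promoter_marks(
        bundle.genes, bundle.marks["H3K4me3"], bundle.marks["H3K27me3"], window
    )
    references = {
        "max_binding": set(bundle.truth.bound_genes),
        "k4me3": {g for g, c in mark_classes.items() if c != "none"},
    }
    out: dict = {}
    for label in sorted(profiles):
        treat = peaks.collapse_duplicates(bundle.reads[label])
        called = peaks.call_peaks(treat, control, chrom_lengths, peak_params)
        kept = peaks.threshold_peaks(called, p_cutoff)
        cov = peaks.build_coverage(
            treat, peak_params.fragment_length, peak_params.bin_size, chrom_lengths
        )
        res = {"n_peaks": len(kept)}
        for mode, positive in references.items():
            refsets = evaluate.build_reference_sets(bundle.genes, positive, mode)
            roc = evaluate.roc_from_peaks(
                kept, bundle.genes, refsets, window, p_grid, chrom_lengths
            )
            ecdf = evaluate.ecdf_from_reference(cov, bundle.genes, refsets, window)
            res[f"auc_{mode}"] = roc.auc
            res[f"d_{mode}"] = ecdf.d
        out[label] = res
    out["_truth"] = {"n_sites": bundle.truth.n_sites, "n_bound_genes": len(bundle.truth.bound_genes)}
    return out
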