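"""Synthetic ChIP-Seq experiment generator.

Produces a self-contained toy experiment: a single-chromosome genome, genes
with log-normal expression (a configurable fraction silenced), true
transcription-factor binding sites placed preferentially at promoters of
expressed genes with the E-box motif CACGTG planted at the site center,
ChIP read sets at a tunable signal-to-background ratio, a background-only
mock control, and histone-mark interval sets consistent with the expression
classes. Everything is deterministic under (config, seed).

The ``background_fraction`` of the read simulator is the experimental
contrast of interest: 0.05 emulates a stringent streptavidin pull-down of a
biotin-tagged factor, 0.40 a conventional antibody IP with substantial
non-specific recovery.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import formats
from .annotate import WINDOW_PRESETS, WindowParams, assign_peaks_to_promoters
from .core import CapacityError, GenomicInterval, SimulationConfig, TruthSet, stage_rng

EBOX = "CACGTG"
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: promoter sites are dropped in this strand-aware window relative to the TSS
SITE_OFFSET_MIN, SITE_OFFSET_MAX = -800, 200
#: distal sites keep this distance from every TSS
DISTAL_MIN_TSS_DIST = 5_000
#: and from each other / promoter sites
SITE_MIN_SPACING = 1_000


def simulate_reference(config: SimulationConfig):
    """Generate the genome sequence and the gene table.

    The sequence is i.i.d. with GC content ``config.gc_content``; TSSs are
    uniform given a minimum spacing of 8 kb (so promoter windows never
    overlap and intergenic space remains for distal sites) and a 5 kb margin
    at each chromosome end; expression is log-normal with a zero-inflated
    "not expressed" fraction.
    """
    config.validate()
    rng = stage_rng(config.seed, "reference")
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=config.genome_length, p=probs)
    genome = _BASES[idx].tobytes().decode("ascii")

    n = config.n_genes
    if n == 0:
        genes = pd.DataFrame(columns=formats.GENE_COLUMNS)
        return genome, genes
    margin, gap = SimulationConfig.GENE_MARGIN, SimulationConfig.MIN_TSS_GAP
    slack = config.genome_length - 2 * margin - (n - 1) * gap
    if slack < 0:
        raise CapacityError(
            f"cannot place {n} genes on {config.genome_length} bp; "
            f"need >= {config.required_genome_length()} bp"
        )
    offsets = np.sort(rng.integers(0, slack + 1, size=n))
    tss = margin + offsets + np.arange(n) * gap
    strands = rng.choice(np.array(["+", "-"]), size=n)
    expression = rng.lognormal(config.expression_mu, config.expression_sigma, size=n)
    silenced = rng.random(n) < config.zero_expression_fraction
    expression[silenced] = 0.0
    width = len(str(n))
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i + 1:0{width}d}" for i in range(n)],
            "chrom": config.chrom,
            "tss": tss.astype(np.int64),
            "strand": strands,
            "expression": expression,
        }
    )
    return genome, genes


def _weighted_sample_without_replacement(rng, weights: np.ndarray, k: int) -> np.ndarray:
    """Indices of k items sampled w/o replacement with prob proportional to
    weights (Gumbel-max trick; zero-weight items are never selected)."""
    eligible = np.flatnonzero(weights > 0)
    if k > eligible.size:
        raise CapacityError(
            f"cannot place {k} promoter sites: only {eligible.size} genes have "
            "positive sampling weight"
        )
    with np.errstate(divide="ignore"):
        keys = np.log(weights[eligible]) + rng.gumbel(size=eligible.size)
    order = np.argsort(keys)[::-1]
    return eligible[order[:k]]


def plant_binding_sites(genome: str, genes: pd.DataFrame, config: SimulationConfig):
    """Choose true binding sites and plant the CACGTG motif at their centers.

    Promoter sites are assigned to genes with probability proportional to
    expression ** coupling (without replacement); distal sites fall at least
    5 kb from every TSS. Returns the edited genome and the TruthSet.
    """
    config.validate()
    rng = stage_rng(config.seed, "sites")
    n_prom = int(round(config.n_true_sites * config.promoter_site_fraction))
    n_distal = config.n_true_sites - n_prom
    if config.n_true_sites == 0:
        return genome, TruthSet()
    if n_prom > 0 and genes.empty:
        raise CapacityError("promoter sites requested but the gene table is empty")

    seq = bytearray(genome.encode("ascii"))
    L = len(seq)
    centers: list[int] = []
    kinds: list[str] = []
    site_gene: list = []

    if n_prom > 0:
        weights = np.power(
            genes["expression"].to_numpy(), config.binding_expression_coupling
        )
        chosen = _weighted_sample_without_replacement(rng, weights, n_prom)
        offsets = rng.integers(SITE_OFFSET_MIN, SITE_OFFSET_MAX + 1, size=n_prom)
        for gi, off in zip(chosen, offsets):
            tss = int(genes["tss"].iloc[gi])
            c = tss + int(off) if genes["strand"].iloc[gi] == "+" else tss - int(off)
            centers.append(int(np.clip(c, 3, L - 3)))
            kinds.append("promoter")
            site_gene.append(genes["gene_id"].iloc[gi])

    if n_distal > 0:
        tss_sorted = np.sort(genes["tss"].to_numpy()) if not genes.empty else np.empty(0)
        placed = 0
        attempts = 0
        max_attempts = max(1000, n_distal * 1000)
        while placed < n_distal:
            attempts += 1
            if attempts > max_attempts:
                raise CapacityError(
                    f"could not place {n_distal} distal sites >= "
                    f"{DISTAL_MIN_TSS_DIST} bp from TSSs on a "
                    f"{config.genome_length} bp genome"
                )
            c = int(rng.integers(3, L - 3))
            if tss_sorted.size:
                i = np.searchsorted(tss_sorted, c)
                near = tss_sorted[max(i - 1, 0) : i + 1]
                if np.min(np.abs(near - c)) < DISTAL_MIN_TSS_DIST:
                    continue
            if centers and min(abs(c - x) for x in centers) < SITE_MIN_SPACING:
                continue
            centers.append(c)
            kinds.append("distal")
            site_gene.append(None)
            placed += 1

    n_sites = len(centers)
    has_motif = rng.random(n_sites) < config.motif_fraction
    motif = EBOX.encode("ascii")
    for c, m in zip(centers, has_motif):
        if m:
            seq[c - 3 : c + 3] = motif
    strength = rng.lognormal(0.0, config.site_strength_sigma, size=n_sites)

    sites = [GenomicInterval(config.chrom, c - 3, c + 3) for c in centers]
    truth = TruthSet(
        sites=sites,
        site_strength=strength,
        site_kind=kinds,
        site_gene=site_gene,
        has_motif=list(map(bool, has_motif)),
        bound_genes=set(),
    )
    truth.bound_genes = bound_genes_from_sites(truth, genes)
    return seq.decode("ascii"), truth


def bound_genes_from_sites(
    truth: TruthSet,
    genes: pd.DataFrame,
    window: WindowParams = WINDOW_PRESETS["default"],
) -> set:
    """Genes whose promoter window intersects a true site (interval overlap)."""
    if genes.empty or truth.n_sites == 0:
        return set()
    bound, _ = assign_peaks_to_promoters(truth.sites, genes, window)
    return bound


def simulate_chip_reads(
    truth: TruthSet,
    config: SimulationConfig,
    profile: str = "signal",
    label: str = "",
) -> pd.DataFrame:
    """Simulate single-end mapped reads (BED6-style DataFrame).

    Signal reads pick a site proportional to its strength, then a sequencing
    fragment positioned so the site lies inside it; the read is the 5' end of
    the fragment on a random strand, giving the characteristic strand
    asymmetry (+ reads upstream of the site, - reads downstream, mean 5'
    separation ~ fragment_length). Background reads are fragments placed
    uniformly on the genome. A ``control`` profile (mock/IgG) is 100%
    background regardless of ``background_fraction``.
    """
    if profile not in ("signal", "control"):
        raise ValueError(f"profile must be 'signal' or 'control', got {profile!r}")
    config.validate()
    rng = stage_rng(config.seed, "reads", profile, label)
    n = config.n_reads
    L = config.genome_length
    frag, rl = config.fragment_length, config.read_length

    if profile == "control" or truth.n_sites == 0:
        n_bg = n
    else:
        n_bg = int(rng.binomial(n, config.background_fraction))
    n_sig = n - n_bg

    frag_starts = np.empty(n, dtype=np.int64)
    frag_starts[:n_bg] = rng.integers(0, L - frag + 1, size=n_bg)
    if n_sig > 0:
        p = truth.site_strength / truth.site_strength.sum()
        site_idx = rng.choice(truth.n_sites, size=n_sig, p=p)
        site_centers = np.array([s.center for s in truth.sites], dtype=np.int64)
        c = site_centers[site_idx]
        # fragment start so that the site center falls inside [start, start+frag)
        starts = c - rng.integers(0, frag, size=n_sig)
        frag_starts[n_bg:] = np.clip(starts, 0, L - frag)

    plus = rng.random(n) < 0.5
    read_start = np.where(plus, frag_starts, frag_starts + frag - rl)
    read_end = read_start + rl
    strand = np.where(plus, "+", "-")
    return pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": read_start,
            "end": read_end,
            "name": [f"r{i}" for i in range(n)],
            "score": 0,
            "strand": strand,
        }
    )


def simulate_marks(
    genes: pd.DataFrame,
    truth: TruthSet,
    config: SimulationConfig,
    k4me3_top_fraction: float = 0.2,
    bivalent_fraction: float = 0.1,
    active_enhancer_fraction: float = 0.6,
    promoter_window: WindowParams = WINDOW_PRESETS["default"],
):
    """Histone-mark interval sets consistent with the expression classes.

    Top-expressed genes get H3K4me3 at their promoter; a low-expression
    subset gets H3K4me3 + H3K27me3 (bivalent); distal true sites get H3K4me1,
    a fraction of them also H3K27ac (active enhancers). Returns
    ``(marks, labels)`` where marks maps mark name -> interval list and
    labels records the planted promoter and enhancer classes for round-trip
    checks.
    """
    for name, v in (
        ("k4me3_top_fraction", k4me3_top_fraction),
        ("bivalent_fraction", bivalent_fraction),
        ("active_enhancer_fraction", active_enhancer_fraction),
    ):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if genes.empty:
        raise ValueError("simulate_marks requires a non-empty gene table")
    rng = stage_rng(config.seed, "marks")
    n = len(genes)
    order = genes.sort_values(
        ["expression", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)
    n_k4 = int(round(k4me3_top_fraction * n))
    k4_genes = set(order["gene_id"].iloc[:n_k4])
    rest = order["gene_id"].iloc[n_k4:].to_numpy()
    n_biv = min(int(round(bivalent_fraction * n)), rest.size)
    biv_genes = set(rng.choice(rest, size=n_biv, replace=False)) if n_biv else set()

    marks = {"H3K4me3": [], "H3K27me3": [], "H3K4me1": [], "H3K27ac": []}
    promoter_labels = {}
    by_id = genes.set_index("gene_id")
    for gene_id in genes["gene_id"]:
        row = by_id.loc[gene_id]
        tss, strand = int(row["tss"]), row["strand"]
        if strand == "+":
            win = GenomicInterval(
                row["chrom"],
                max(tss - promoter_window.upstream, 0),
                tss + promoter_window.downstream,
            )
        else:
            win = GenomicInterval(
                row["chrom"],
                max(tss - promoter_window.downstream, 0),
                tss + promoter_window.upstream,
            )
        if gene_id in k4_genes or gene_id in biv_genes:
            marks["H3K4me3"].append(win)
        if gene_id in biv_genes:
            marks["H3K27me3"].append(win)
        promoter_labels[gene_id] = (
            "bivalent"
            if gene_id in biv_genes
            else ("H3K4me3_only" if gene_id in k4_genes else "none")
        )

    enhancer_labels = {}
    for site in truth.distal_sites():
        c = site.center
        k4me1 = GenomicInterval(site.chrom, max(c - 500, 0), c + 500)
        marks["H3K4me1"].append(k4me1)
        if rng.random() < active_enhancer_fraction:
            marks["H3K27ac"].append(GenomicInterval(site.chrom, max(c - 300, 0), c + 300))
            enhancer_labels[k4me1] = "active"
        else:
            enhancer_labels[k4me1] = "poised"
    labels = {"promoters": promoter_labels, "enhancers": enhancer_labels}
    return marks, labels


@dataclass
class FixtureBundle:
    """One full simulated experiment ready to be written to disk."""

    config: SimulationConfig
    genome: dict  # chrom -> sequence
    genes: pd.DataFrame
    truth: TruthSet
    reads: dict = field(default_factory=dict)  # label -> reads DataFrame
    marks: dict = field(default_factory=dict)  # mark name -> interval list


def simulate_experiment(
    config: SimulationConfig,
    profiles: dict | None = None,
    mark_params: dict | None = None,
) -> FixtureBundle:
    """Run the whole generator: reference, sites, reads per profile, marks.

    ``profiles`` maps dataset label -> background fraction (default the
    tagged/antibody contrast); a background-only ``mock`` control is always
    included.
    """
    if profiles is None:
        profiles = {"tagged": 0.05, "antibody": 0.40}
    genome, genes = simulate_reference(config)
    genome, truth = plant_binding_sites(genome, genes, config)
    reads = {}
    for label, bg in profiles.items():
        cfg = config.replace(background_fraction=bg)
        reads[label] = simulate_chip_reads(truth, cfg, profile="signal", label=label)
    reads["mock"] = simulate_chip_reads(truth, config, profile="control", label="mock")
    marks, labels = simulate_marks(genes, truth, config, **(mark_params or {}))
    bundle = FixtureBundle(
        config=config,
        genome={config.chrom: genome},
        genes=genes,
        truth=truth,
        reads=reads,
        marks=marks,
    )
    bundle.mark_labels = labels
    return bundle


def config_hash(config: SimulationConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def truth_table(truth: TruthSet) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in truth.sites],
            "start": [s.start for s in truth.sites],
            "end": [s.end for s in truth.sites],
            "kind": truth.site_kind,
            "gene_id": ["" if g is None else g for g in truth.site_gene],
            "strength": truth.site_strength,
            "has_motif": [int(m) for m in truth.has_motif],
        }
    )


def truth_from_table(df: pd.DataFrame, genes: pd.DataFrame) -> TruthSet:
    truth = TruthSet(
        sites=[
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in df.itertuples(index=False)
        ],
        site_strength=df["strength"].to_numpy(dtype=float),
        site_kind=list(df["kind"]),
        site_gene=[None if g in ("", None) or pd.isna(g) else str(g) for g in df["gene_id"]],
        has_motif=[bool(int(m)) for m in df["has_motif"]],
    )
    truth.bound_genes = bound_genes_from_sites(truth, genes)
    return truth


def write_fixture(bundle: FixtureBundle, out_dir: str) -> dict:
    """Write the fixture bundle to out_dir; returns the manifest.

    Emits genome FASTA, gene TSV, one reads BED6 per dataset, one BED3 per
    mark, a truth TSV, and a YAML manifest listing the files plus the seed
    and a hash of the configuration.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest = {
        "seed": bundle.config.seed,
        "config_hash": config_hash(bundle.config),
        "files": {},
    }

    def _path(name):
        manifest["files"][name] = name
        return os.path.join(out_dir, name)

    formats.write_fasta(_path("genome.fa"), bundle.genome)
    formats.write_gene_table(_path("genes.tsv"), bundle.genes)
    truth_table(bundle.truth).to_csv(_path("truth.tsv"), sep="\t", index=False)
    for label, df in bundle.reads.items():
        formats.write_reads(_path(f"reads_{label}.bed"), df)
    for mark, intervals in bundle.marks.items():
        formats.write_intervals(_path(f"marks_{mark}.bed"), intervals, format="bed")
    with open(os.path.join(out_dir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def read_fixture(out_dir: str) -> FixtureBundle:
    """Round-trip reader for a written fixture (config is not reconstructed)."""
    genome = formats.read_fasta(os.path.join(out_dir, "genome.fa"))
    genes = formats.read_gene_table(os.path.join(out_dir, "genes.tsv"), genome=genome)
    tdf = pd.read_csv(
        os.path.join(out_dir, "truth.tsv"), sep="\t", dtype={"gene_id": str}
    )
    truth = truth_from_table(tdf, genes)
    with open(os.path.join(out_dir, "manifest.yaml")) as fh:
        manifest = yaml.safe_load(fh)
    reads = {}
    marks = {}
    for name in manifest["files"]:
        if name.startswith("reads_"):
            label = name[len("reads_") : -len(".bed")]
            reads[label] = formats.read_reads(os.path.join(out_dir, name))
        elif name.startswith("marks_"):
            mark = name[len("marks_") : -len(".bed")]
            marks[mark] = [
                iv for iv, _ in formats.read_intervals(os.path.join(out_dir, name))
            ]
    chrom = next(iter(genome))
    cfg = SimulationConfig(genome_length=len(genome[chrom]), chrom=chrom)
    bundle = FixtureBundle(
        config=cfg, genome=genome, genes=genes, truth=truth, reads=reads, marks=marks
    )
    return bundle
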