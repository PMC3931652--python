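"""Core domain types shared by every stage of the pipeline.

All genomic coordinates are 0-based, half-open ``[start, end)``. Conversion
to/from 1-based conventions happens only inside the format readers/writers.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields

import numpy as np

STRANDS = ("+", "-", ".")


class CapacityError(ValueError):
    """Raised when a simulation request cannot be placed on the genome."""


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic span: chrom, [start, end), optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to_point(self, pos: int) -> int:
        """bp distance from a point to this interval (0 if inside)."""
        if self.start <= pos < self.end:
            return 0
        return max(self.start - pos, pos - (self.end - 1))


@dataclass(frozen=True)
class GeneRecord:
    """A gene reduced to what promoter analysis needs: TSS, strand, expression."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    expression: float

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if self.expression < 0:
            raise ValueError("expression must be >= 0")


@dataclass(frozen=True)
class Peak:
    """A called enrichment peak with its Poisson upper-tail p-value.

    The p-value is stored as -log10(p) so that extremely significant peaks
    (p far below float underflow) remain rankable.
    """

    chrom: str
    start: int
    end: int
    summit: int
    tag_count: int
    fold_enrichment: float
    neg_log10_pvalue: float

    def __post_init__(self):
        if not (self.start <= self.summit < self.end):
            raise ValueError("summit must lie in [start, end)")
        if self.tag_count < 1:
            raise ValueError("peak must contain at least one tag")
        if self.neg_log10_pvalue < 0:
            raise ValueError("-log10(p) must be >= 0")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def pvalue(self) -> float:
        """Linear-scale p-value; underflows to 0.0 below ~1e-308."""
        return float(10.0 ** (-self.neg_log10_pvalue))


def stage_rng(seed: int, *key) -> np.random.Generator:
    """Derive an independent, reproducible RNG stream for a named stage.

    Stage names are folded into the SeedSequence spawn key via CRC32 so the
    same (seed, stage) pair always yields the same stream, and stages can be
    re-run standalone with identical randomness.
    """
    spawn = tuple(
        zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in key
    )
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=spawn))


@dataclass
class SimulationConfig:
    """Parameters of the toy ChIP-Seq experiment.

    ``background_fraction`` is the knob that distinguishes the stringent
    streptavidin-style pull-down (low, default 0.05) from a conventional
    antibody IP (high, 0.40): it is the fraction of reads drawn uniformly
    from the genome instead of from true binding sites.
    """

    genome_length: int = 20_000_000
    gc_content: float = 0.5
    n_genes: int = 2_000
    n_true_sites: int = 300
    promoter_site_fraction: float = 0.8
    expression_mu: float = 1.0
    expression_sigma: float = 1.0
    zero_expression_fraction: float = 0.2
    binding_expression_coupling: float = 2.0
    site_strength_sigma: float = 2.5
    motif_fraction: float = 0.9
    n_reads: int = 1_000_000
    background_fraction: float = 0.05
    fragment_length: int = 200
    read_length: int = 36
    seed: int = 0
    chrom: str = "chrS"

    #: bp kept free of genes at each chromosome end; minimum spacing between
    #: adjacent TSSs (non-overlapping +/-4 kb windows, so even the widest
    #: promoter preset never overlaps, while leaving intergenic space for
    #: distal enhancer sites >= 5 kb from every TSS)
    GENE_MARGIN = 5_000
    MIN_TSS_GAP = 8_000

    def validate(self) -> None:
        fracs = {
            "gc_content": self.gc_content,
            "promoter_site_fraction": self.promoter_site_fraction,
            "zero_expression_fraction": self.zero_expression_fraction,
            "motif_fraction": self.motif_fraction,
            "background_fraction": self.background_fraction,
        }
        for name, v in fracs.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("genome_length", "n_reads", "fragment_length", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 0 or self.n_true_sites < 0:
            raise ValueError("counts must be non-negative")
        if self.fragment_length < self.read_length:
            raise ValueError("fragment_length must be >= read_length")
        required = self.required_genome_length()
        if self.genome_length < required:
            raise CapacityError(
                f"genome_length={self.genome_length} too short for "
                f"{self.n_genes} genes with non-overlapping promoter windows; "
                f"need at least {required} bp"
            )

    def required_genome_length(self) -> int:
        if self.n_genes == 0:
            return 1
        return 2 * self.GENE_MARGIN + (self.n_genes - 1) * self.MIN_TSS_GAP

    def replace(self, **kw) -> "SimulationConfig":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(kw)
        return SimulationConfig(**d)


@dataclass
class TruthSet:
    """Ground-truth binding sites planted by the simulator.

    ``sites`` are the 6-bp site footprints; ``site_strength`` are relative
    read-emission weights; ``bound_genes`` are the genes whose promoter
    window contains a site (derivable by interval intersection, and asserted
    to be so in tests).
    """

    sites: list = field(default_factory=list)  # list[GenomicInterval]
    site_strength: np.ndarray = field(default_factory=lambda: np.empty(0))
    site_kind: list = field(default_factory=list)  # "promoter" | "distal"
    site_gene: list = field(default_factory=list)  # gene_id or None
    has_motif: list = field(default_factory=list)  # bool per site
    bound_genes: set = field(default_factory=set)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def promoter_sites(self):
        return [s for s, k in zip(self.sites, self.site_kind) if k == "promoter"]

    def distal_sites(self):
        return [s for s, k in zip(self.sites, self.site_kind) if k == "distal"]
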