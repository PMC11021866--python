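"""Configuration objects for the simulator and the end-to-end pipeline.

Validation lives here so every stage can assume well-formed parameters.
Coordinates are 1-based inclusive (VCF/GFF3 native) everywhere except BED
output, which is converted in :mod:`qtlbsa.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

SEG_MODELS = ("1:1", "1:2:1")

#: Mean marker dosage and dosage variance per segregation model
#: (dosage = number of alternate alleles carried by a progeny line).
_SEG_DOSAGE = {"1:1": (0.5, 0.25), "1:2:1": (1.0, 0.5)}


@dataclass(frozen=True)
class QtlSpec:
    """A single additive QTL planted by the simulator.

    ``effect`` is the additive allele-substitution effect expressed in
    phenotypic standard deviations (difference between adjacent dosage
    classes).
    """

    chrom: str
    pos: int
    effect: float


@dataclass
class SimConfig:
    """Study design for the synthetic F1 cross.

    Defaults mirror the design of the jujube fruit-size cross this package
    models: 284 F1 lines, extreme pools of 30 lines each, pooled sequencing
    at ~40x mean depth with parents around 14x, and a mostly-SNP marker set
    (SNPs are ~81% of called variants in that study).
    """

    n_progeny: int = 284
    chromosomes: Sequence[tuple[str, int]] = (
        ("chr1", 30_000_000),
        ("chr2", 30_000_000),
        ("chr3", 30_000_000),
    )
    marker_density: float = 200.0  # markers per Mb
    snp_fraction: float = 0.81
    qtl: Optional[QtlSpec] = QtlSpec("chr1", 15_000_000, 1.0)
    h2: float = 0.6
    pool_size: int = 30
    depth_mean: float = 40.0
    parent_depth_mean: float = 14.0
    seg_model: str = "1:1"
    cm_per_mb: float = 3.0
    error_rate: float = 0.0  # symmetric per-read sequencing error
    genes_per_mb: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.qtl, (tuple, list)):
            self.qtl = QtlSpec(*self.qtl)
        self.chromosomes = [(str(n), int(l)) for n, l in self.chromosomes]
        if not self.chromosomes:
            raise ValueError("at least one chromosome is required")
        if any(l <= 0 for _, l in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if self.seg_model not in SEG_MODELS:
            raise ValueError(f"seg_model must be one of {SEG_MODELS}")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if self.n_progeny < 2:
            raise ValueError("need at least two progeny lines")
        if self.pool_size < 1 or 2 * self.pool_size > self.n_progeny:
            raise ValueError("pool_size must satisfy 2 * pool_size <= n_progeny")
        if self.depth_mean <= 0 or self.parent_depth_mean <= 0:
            raise ValueError("read depths must be positive")
        if not 0.0 <= self.snp_fraction <= 1.0:
            raise ValueError("snp_fraction must lie in [0, 1]")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.n_markers() < 1:
            raise ValueError("configuration yields zero markers")
        if self.qtl is not None:
            sizes = dict(self.chromosomes)
            if self.qtl.chrom not in sizes:
                raise ValueError(f"QTL chromosome {self.qtl.chrom!r} not in genome")
            if not 1 <= self.qtl.pos < sizes[self.qtl.chrom]:
                raise ValueError("QTL position must lie within its chromosome")
            _, var_g = _SEG_DOSAGE[self.seg_model]
            if self.qtl.effect**2 * var_g > self.h2 + 1e-12:
                raise ValueError(
                    "QTL variance effect^2 * Var(dosage) exceeds h2; "
                    "lower the effect or raise h2"
                )

    def n_markers(self) -> int:
        return sum(
            round(self.marker_density * length / 1e6) for _, length in self.chromosomes
        )

    def dosage_moments(self) -> tuple[float, float]:
        """(mean, variance) of marker dosage under the segregation model."""
        return _SEG_DOSAGE[self.seg_model]


#: The four sample roles every multi-sample VCF must provide.
ROLES = ("parent_female", "parent_male", "pool_large", "pool_small")


@dataclass
class SampleRoles:
    parent_female: str = "parent_female"
    parent_male: str = "parent_male"
    pool_large: str = "pool_large"
    pool_small: str = "pool_small"

    def __post_init__(self) -> None:
        names = [self.parent_female, self.parent_male, self.pool_large, self.pool_small]
        if len(set(names)) != 4:
            raise ValueError("the four sample roles must map to distinct sample names")

    def as_dict(self) -> dict[str, str]:
        return {r: getattr(self, r) for r in ROLES}


@dataclass
class PipelineConfig:
    """Everything needed for a full pipeline run (``run-all``)."""

    vcf: Path
    gff3: Path
    fasta: Optional[Path]
    phenotypes: Path
    out_dir: Path
    samples: SampleRoles = field(default_factory=SampleRoles)
    window: int = 1_000_000
    step: int = 1_000
    min_index: float = 0.3
    min_depth: int = 7
    flank: int = 1_000
    splice_window: int = 2
    ci_level: float = 0.95
    n_sims: int = 10_000
    pool_size: int = 30
    seg_model: str = "1:1"
    min_abs_delta: float = 0.0
    candidate_mode: str = "genome-wide"
    include_updown: bool = True
    make_plots: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for attr in ("vcf", "gff3", "phenotypes", "out_dir"):
            setattr(self, attr, Path(getattr(self, attr)))
        if self.fasta is not None:
            self.fasta = Path(self.fasta)
        if isinstance(self.samples, dict):
            self.samples = SampleRoles(**self.samples)
        if self.window < self.step or self.step <= 0:
            raise ValueError("require window >= step > 0")
        if self.seg_model not in SEG_MODELS:
            raise ValueError(f"seg_model must be one of {SEG_MODELS}")
        if not 0.5 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0.5, 1)")
        if self.candidate_mode not in ("genome-wide", "interval-restricted"):
            raise ValueError("candidate_mode must be genome-wide or interval-restricted")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)
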