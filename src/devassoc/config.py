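"""Configuration objects for simulation and the analysis pipeline.

The default stage list has 13 ordered developmental stages (early fetal
through adulthood) and the default region vocabulary covers three groups of
brain regions — prefrontal cortex, non-prefrontal cortex and subcortical —
plus a whole-brain tier that pools all of them. Stage labels are plain
config data; no ages are hard-coded anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ConfigError",
    "CovariateModel",
    "PlantedEffect",
    "SimulationConfig",
    "DEFAULT_STAGES",
    "DEFAULT_REGION_GROUPS",
    "WHOLE_BRAIN",
    "all_regions",
]


class ConfigError(ValueError):
    """Raised when a configuration fails validation."""


#: Ordered developmental stages, earliest first.
DEFAULT_STAGES: tuple[str, ...] = (
    "Early Fetal",
    "Early Midfetal 1",
    "Early Midfetal 2",
    "Late Midfetal",
    "Late Fetal",
    "Neonatal",
    "Early Infancy",
    "Late Infancy",
    "Early Childhood",
    "Late Childhood",
    "Adolescence",
    "Young Adulthood",
    "Adulthood",
)

#: Region-group tiers: prefrontal cortex, non-prefrontal cortex, subcortical.
DEFAULT_REGION_GROUPS: dict[str, tuple[str, ...]] = {
    "prefrontal cortex": ("MFC", "DFC", "VFC", "OFC"),
    "non-prefrontal cortex": ("STC", "ITC", "A1C", "V1C", "M1C", "IPC", "S1C"),
    "subcortical": ("AMY", "THA", "STR", "HIP"),
}

#: Label for the tier-1 pooled analysis across every region.
WHOLE_BRAIN = "whole brain"


def all_regions(region_groups: Mapping[str, Sequence[str]]) -> tuple[str, ...]:
    """All member regions across groups, in group order."""
    out: list[str] = []
    for members in region_groups.values():
        out.extend(members)
    return tuple(out)


@dataclass(frozen=True)
class CovariateModel:
    """Per-sample technical/demographic covariates drawn by the simulator.

    RIN is uniform over ``rin_range``; the default range straddles the RIN=7
    quality cutoff so the sample filter is exercised. Ethnicity and sex are
    categorical draws.
    """

    rin_range: tuple[float, float] = (6.0, 9.5)
    ethnicities: tuple[str, ...] = ("EUR", "AFR", "EAS")
    sexes: tuple[str, ...] = ("F", "M")
    rin_effect: float = 0.15
    ethnicity_effect_sd: float = 0.2
    sex_effect_sd: float = 0.2


@dataclass(frozen=True)
class PlantedEffect:
    """A planted association–expression correlation at one (stage, group).

    ``rho`` is the planting strength tying the gene-level association Z to
    the gene's relative expression at ``stage`` within ``region_group``; its
    sign sets the direction (negative rho plants a depletion-type signal:
    associated genes relatively *under*-expressed at the stage). Effects that
    share a ``latent`` key are driven by the same per-gene latent vector, so
    the same genes carry both signals (used for conditional-analysis
    scenarios); ``loadings`` optionally fixes the latent explicitly.
    """

    stage: str
    region_group: str = WHOLE_BRAIN
    rho: float = 0.3
    latent: str | None = None
    loadings: tuple[float, ...] | None = None

    @property
    def latent_key(self) -> str:
        return self.latent if self.latent is not None else f"{self.stage}|{self.region_group}"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic generators.

    Defaults emulate the scale of the real study: 13 ordered stages,
    3 donors per stage (39 ≈ the atlas's 38 individuals), 15 brain regions
    in three groups, and GWAS summary statistics with block LD.
    """

    n_genes: int = 2000
    subjects_per_stage: int = 3
    stages: tuple[str, ...] = DEFAULT_STAGES
    region_groups: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_GROUPS)
    )
    covariates: CovariateModel = field(default_factory=CovariateModel)
    planted_effects: tuple[PlantedEffect, ...] = ()
    #: expression shift per unit latent at the planted stage (adjusted-RPKM units)
    planted_amplitude: float = 1.5
    #: ceiling of the planted per-gene association strength (probit units)
    planted_z_scale: float = 10.0
    noise_sd: float = 1.0
    baseline_range: tuple[float, float] = (3.0, 10.0)
    region_effect_sd: float = 0.3
    stage_effect_sd: float = 0.6
    zero_gene_fraction: float = 0.02
    # GWAS side
    ld_block_size: int = 5
    ld_r: float = 0.5
    snps_per_gene: tuple[int, int] = (5, 12)
    #: fraction of genes given an extra SNP just outside the mapping window
    outside_snp_fraction: float = 0.2
    low_maf_fraction: float = 0.05
    low_info_fraction: float = 0.05
    # gene annotation layout
    n_chromosomes: int = 6
    gene_length_range: tuple[int, int] = (5_000, 100_000)
    gene_gap_range: tuple[int, int] = (60_000, 200_000)
    noncoding_fraction: float = 0.05
    x_gene_fraction: float = 0.02
    xmhc_gene_fraction: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.subjects_per_stage <= 0:
            raise ConfigError("subjects_per_stage must be positive")
        if len(self.stages) < 2:
            raise ConfigError("need at least two developmental stages")
        if len(set(self.stages)) != len(self.stages):
            raise ConfigError("stage labels must be unique")
        if not self.region_groups or not any(self.region_groups.values()):
            raise ConfigError("need at least one region in one region group")
        regions = all_regions(self.region_groups)
        if len(set(regions)) != len(regions):
            raise ConfigError("region labels must be disjoint across groups")
        for eff in self.planted_effects:
            if not -1.0 <= eff.rho <= 1.0:
                raise ConfigError(f"planted rho {eff.rho} outside [-1, 1]")
            if eff.stage not in self.stages:
                raise ConfigError(f"planted stage {eff.stage!r} not in stage list")
            if eff.region_group != WHOLE_BRAIN and eff.region_group not in self.region_groups:
                raise ConfigError(f"unknown region group {eff.region_group!r}")
            if eff.loadings is not None and len(eff.loadings) != self.n_genes:
                raise ConfigError("explicit loadings must have length n_genes")
        if self.ld_block_size < 1:
            raise ConfigError("ld_block_size must be >= 1")
        if not -1.0 < self.ld_r < 1.0:
            raise ConfigError("ld_r must be in (-1, 1)")
        lo, hi = self.snps_per_gene
        if lo < 1 or hi < lo:
            raise ConfigError("snps_per_gene must be a nondecreasing positive range")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible stream for one generator component."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))

    def group_regions(self, group: str) -> tuple[str, ...]:
        if group == WHOLE_BRAIN:
            return all_regions(self.region_groups)
        return tuple(self.region_groups[group])
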