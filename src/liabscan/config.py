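"""Configuration objects for simulation, model fitting and the pipeline.

The :class:`SimConfig` defaults define the package's reference synthetic
study: a scaled-down Holstein-like design with a multi-generation pedigree,
a genotyped subset, a handful of large-effect QTL windows, and a binary
outcome with low incidence generated from a probit liability model with
additive animal and service-sire random effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

__all__ = ["SimConfig", "ParitySpec", "GibbsConfig", "PipelineConfig"]


@dataclass
class ParitySpec:
    """One parity's phenotype layer: nulliparous records carry no DIM or
    uterine-disease factor; lactating parities carry both."""

    name: str
    incidence: float
    n_records: int
    factors: tuple[str, ...] = (
        "year_season",
        "breed_type",
        "dim_class",
        "uterine_disease",
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.incidence < 1.0:
            raise ValueError("incidence must be in (0, 1)")
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")


@dataclass
class SimConfig:
    """Generating parameters of the synthetic study.

    Residual liability variance is fixed at 1 (probit identification), so
    ``sigma2_a`` and ``sigma2_ss`` are on the liability scale directly.
    """

    n_founders: int = 500
    n_generations: int = 3
    matings_per_generation: int = 1250
    offspring_per_mating: int = 2
    n_sires_per_generation: int = 25
    n_chromosomes: int = 5
    snps_per_chromosome: int = 400
    chrom_length_bp: int = 100_000_000
    n_qtl: int = 5
    qtl_var_fraction: float = 0.30
    sigma2_a: float = 0.20
    sigma2_ss: float = 0.05
    incidence_target: float = 0.135
    fixed_effect_levels: dict[str, int] = field(
        default_factory=lambda: {
            "year_season": 39,
            "breed_type": 2,
            "dim_class": 3,
            "uterine_disease": 2,
        }
    )
    fixed_effect_sd: float = 0.2
    n_service_sires: int = 100
    prop_genotyped: float = 0.12
    missing_rate: float = 0.01
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    pheno_generations: int = 2
    n_records: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_founders,
            self.offspring_per_mating,
            self.matings_per_generation,
            self.n_sires_per_generation,
            self.n_chromosomes,
            self.snps_per_chromosome,
            self.chrom_length_bp,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all structural counts must be >= 1")
        if self.n_generations < 0 or self.n_qtl < 0:
            raise ValueError("n_generations and n_qtl must be >= 0")
        if self.n_generations == 0 and self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if self.sigma2_a < 0 or self.sigma2_ss < 0:
            raise ValueError("variances must be >= 0")
        for name, frac in (
            ("qtl_var_fraction", self.qtl_var_fraction),
            ("prop_genotyped", self.prop_genotyped),
            ("missing_rate", self.missing_rate),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.incidence_target < 1.0:
            raise ValueError("incidence_target must be in (0, 1)")
        lo, hi = self.founder_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("founder_maf_range must lie within (0, 0.5]")

    @property
    def n_snps(self) -> int:
        return self.n_chromosomes * self.snps_per_chromosome


@dataclass
class GibbsConfig:
    """Chain lengths default to the full-scale analysis protocol
    (500,000 post-burn-in samples after 100,000 burn-in, thinning 100);
    scaled-down chains are passed explicitly where runtime matters.

    Variance priors are scaled inverse chi-square with df 4 and scale set so
    the prior mode equals the start value; ``prior_df_* = 0`` gives the flat
    limit.
    """

    n_iter: int = 600_000
    burn_in: int = 100_000
    thin: int = 100
    seed: int = 0
    prior_df_a: float = 4.0
    prior_scale_a: float | None = None
    prior_df_ss: float = 4.0
    prior_scale_ss: float | None = None
    start_sigma2_a: float = 0.10
    start_sigma2_ss: float = 0.05
    h2_includes_service_sire: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.start_sigma2_a <= 0 or self.start_sigma2_ss <= 0:
            raise ValueError("start values must be > 0")

    def resolved_prior(self, which: str) -> tuple[float, float]:
        """(df, scale) with the mode-matching default scale filled in."""
        df = getattr(self, f"prior_df_{which}")
        scale = getattr(self, f"prior_scale_{which}")
        start = getattr(self, f"start_sigma2_{'a' if which == 'a' else 'ss'}")
        if scale is None:
            scale = start * (df + 2.0) / df if df > 0 else 0.0
        return float(df), float(scale)


@dataclass
class PipelineConfig:
    """End-to-end run: simulate -> QC -> H^-1 -> per-parity fits -> scans ->
    cross-parity correlations -> enrichment."""

    sim: SimConfig = field(default_factory=SimConfig)
    parities: tuple[ParitySpec, ...] = (
        ParitySpec("nulliparous", 0.083, 2400, ("year_season", "breed_type")),
        ParitySpec("primiparous", 0.135, 2050),
        ParitySpec("multiparous", 0.137, 1380),
    )
    gibbs: GibbsConfig = field(default_factory=GibbsConfig)
    qc_animal_call_rate: float = 0.95
    qc_snp_call_rate: float = 0.95
    qc_maf: float = 0.01
    qc_hwe_p: float = 1e-6
    blend: float = 0.95
    span_bp: int = 2_000_000
    window_mode: str = "sliding"
    flank_bp: int = 15_000
    top_fraction: float = 0.05
    min_term_size: int = 10
    n_genes: int = 800
    n_terms: int = 40
    genes_per_term: tuple[int, int] = (10, 40)
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["parities"] = [asdict(p) for p in self.parities]
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            sim = dict(d["sim"])
            if "founder_maf_range" in sim:
                sim["founder_maf_range"] = tuple(sim["founder_maf_range"])
            d["sim"] = SimConfig(**sim)
        if "gibbs" in d and isinstance(d["gibbs"], dict):
            d["gibbs"] = GibbsConfig(**d["gibbs"])
        if "parities" in d:
            d["parities"] = tuple(
                ParitySpec(**{**p, "factors": tuple(p.get("factors", ParitySpec.factors))})
                if isinstance(p, dict)
                else p
                for p in d["parities"]
            )
        if "genes_per_term" in d:
            d["genes_per_term"] = tuple(d["genes_per_term"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
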