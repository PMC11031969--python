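"""Configuration objects for the trial simulator and the analysis pipeline.

Defaults encode the design of a 20-practice, 1:1 cluster-randomised primary
care trial with three cohorts (58 children, 315 adults, 671 older adults;
1,044 patients in all), a 12-month intervention, three 12-month observation
periods (baseline, months 0–12, months 12–24), an A$1,000 per-participant
intervention payment, 5% annual discounting, and an A$50,000/QALY
willingness-to-pay threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

COHORTS = ("child", "adult", "older")
OUTCOMES = ("ed", "adm", "nights", "spec", "pharm")
#: cost components assembled per 12-month period
COST_COMPONENTS = ("hospital", "specialist", "pharma")


def _default_cohort_sizes() -> dict[str, int]:
    return {"child": 58, "adult": 315, "older": 671}


def _default_true_irr() -> dict[str, float]:
    # observed two-year intervention rate ratios used as the simulated truth
    return {"ed": 0.90, "adm": 0.95, "nights": 0.80, "spec": 0.99, "pharm": 1.00}


def _default_dispersion() -> dict[str, float]:
    # NB2 alpha: Var = mu + alpha * mu^2, conditional on the random effects
    return {"ed": 2.5, "adm": 2.5, "nights": 12.0, "spec": 0.7, "pharm": 0.25}


def _default_baseline_rates() -> dict[str, dict[str, float]]:
    # mean counts per patient per 12 months, by cohort
    return {
        "child": {"ed": 0.40, "adm": 0.15, "nights": 0.30, "spec": 8.0, "pharm": 6.0},
        "adult": {"ed": 0.60, "adm": 0.40, "nights": 1.20, "spec": 30.0, "pharm": 45.0},
        "older": {"ed": 0.75, "adm": 0.55, "nights": 2.00, "spec": 40.0, "pharm": 60.0},
    }


def _default_unit_prices() -> dict[str, float]:
    # A$ unit prices linking service counts to component costs
    return {"night": 2000.0, "admission": 1500.0, "ed": 600.0, "specialist": 90.0, "pharm": 43.0}


def _default_cost_noise() -> dict[str, dict[str, float]]:
    # gamma noise (shape, scale) added to each component cost, per period
    return {
        "hospital": {"shape": 2.0, "scale": 150.0},
        "specialist": {"shape": 2.0, "scale": 100.0},
        "pharma": {"shape": 2.0, "scale": 50.0},
    }


def _default_death_prob() -> dict[str, float]:
    return {"child": 0.002, "adult": 0.02, "older": 0.08}


def _default_utility_means() -> dict[str, float]:
    return {"child": 0.88, "adult": 0.57, "older": 0.64}


def _default_time_effects() -> dict[str, float]:
    # secular log-rate shifts for the two follow-up periods, common to both arms
    return {"p1": 0.0, "p2": -0.05}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic clustered-trial generator.

    The same seed and config always produce the identical dataset.
    """

    n_practices: int = 20
    allocation_ratio: float = 0.5
    cohort_sizes: dict[str, int] = field(default_factory=_default_cohort_sizes)
    practice_sd_utility: float = 0.05
    practice_sd_lograte: float = 0.15
    patient_sd_lograte: float = 0.50
    #: sd of the latent patient health factor shared by baseline/12m utility
    utility_patient_sd: float = 0.25
    #: sd of the occasion-level utility noise
    utility_noise_sd: float = 0.12
    utility_means: dict[str, float] = field(default_factory=_default_utility_means)
    #: additive 12-month utility effect of the intervention (latent scale)
    true_effect_utility: float = 0.05
    true_irr: dict[str, float] = field(default_factory=_default_true_irr)
    count_dispersion: dict[str, float] = field(default_factory=_default_dispersion)
    baseline_rates: dict[str, dict[str, float]] = field(default_factory=_default_baseline_rates)
    time_effects: dict[str, float] = field(default_factory=_default_time_effects)
    #: correlation between low latent health and high service use
    health_count_coupling: float = 0.5
    unit_prices: dict[str, float] = field(default_factory=_default_unit_prices)
    cost_noise: dict[str, dict[str, float]] = field(default_factory=_default_cost_noise)
    death_prob: dict[str, float] = field(default_factory=_default_death_prob)
    #: logistic intercept/slope for MAR missingness of the 12m state on u0
    missing_prob_coefs: tuple[float, float] = (-1.2, -1.5)
    value_set: str = "synthetic-au-range"
    seed: int = 0

    def validate(self) -> None:
        if not isinstance(self.seed, (int,)) or isinstance(self.seed, bool):
            raise TypeError(f"seed must be an integer, got {type(self.seed).__name__}")
        if self.n_practices < 2:
            raise ValueError("need at least 2 practices")
        if not 0.0 < self.allocation_ratio < 1.0:
            raise ValueError("allocation_ratio must be in (0, 1)")
        total = sum(self.cohort_sizes.values())
        if total <= 0:
            raise ValueError("total cohort size must be positive")
        if self.n_practices > total:
            raise ValueError("more practices than patients")
        for c, n in self.cohort_sizes.items():
            if n < 0:
                raise ValueError(f"cohort {c!r}: size must be >= 0")
        for c, p in self.death_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"death_prob[{c!r}] outside [0, 1]")
        for k, a in self.count_dispersion.items():
            if a <= 0:
                raise ValueError(f"count_dispersion[{k!r}] must be > 0")
        for sd in (
            self.practice_sd_utility,
            self.practice_sd_lograte,
            self.patient_sd_lograte,
            self.utility_patient_sd,
            self.utility_noise_sd,
        ):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= abs(self.health_count_coupling) <= 1.0:
            raise ValueError("health_count_coupling must lie in [-1, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "missing_prob_coefs" in d:
            d["missing_prob_coefs"] = tuple(d["missing_prob_coefs"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunConfig:
    """End-to-end pipeline run: simulate (or load) → score → cost → CEA → counts."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    dataset_path: str | None = None
    value_set: str = "synthetic-au-range"
    discount_rate: float = 0.05
    payment: float = 1000.0
    #: converts the nominal payment to analysis-year prices (1.026 → A$1,026)
    index_factor: float = 1.026
    n_bootstrap: int = 1000
    wtp_threshold: float = 50_000.0
    wtp_grid: tuple[float, float, float] = (0.0, 100_000.0, 1_000.0)  # start, stop, step
    scenarios: tuple[float, ...] = (0.0, 0.05, 0.15)
    subgroups: tuple[str, ...] = ("combined", "adult", "older")
    seed: int = 0
    out_dir: str = "ceatrial_run"

    def validate(self) -> None:
        self.generator.validate()
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        if self.payment < 0 or self.index_factor < 0:
            raise ValueError("payment and index_factor must be >= 0")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        for d in self.scenarios:
            if not 0.0 <= d <= 1.0:
                raise ValueError("decay scenarios must lie in [0, 1]")
        for g in self.subgroups:
            if g not in ("combined", "adult", "older"):
                raise ValueError(f"unknown subgroup {g!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = GeneratorConfig.from_dict(raw.pop("generator", {}))
        for key in ("wtp_grid", "scenarios", "subgroups"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(generator=gen, **raw)
        cfg.validate()
        return cfg
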