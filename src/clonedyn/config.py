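"""Cohort-generator configuration.

A :class:`CohortConfig` is the full statement of the simulated world: cohort
size and ages, the longitudinal sampling schedule with its missingness, the
sequencing-noise model (replicate coverage), the clone growth-rate
distribution, and the clinical panel including the targeted rank correlation
between true clone growth rate and HDL-cholesterol.

Defaults describe an SOS-style obesity cohort: baseline ages 37-60 y,
examinations at 0/2/10/15/20 y with retention 40/38/40/38/24 of 40
individuals, two technical sequencing replicates at ~3891x mean coverage,
clone VAFs log-normal around 1% growing log-linearly at a mean of 7% per
year, and a metabolic panel with obesity-typical means/SDs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import yaml

from .errors import ConfigError

__all__ = ["CohortConfig", "ClinicalVariable", "DEFAULT_CLINICAL_PANEL", "load_config"]


@dataclass(frozen=True)
class ClinicalVariable:
    """Marginal distribution of one clinical panel variable.

    ``dist`` is "normal" or "lognormal" (moment-matched to mean/sd).
    ``visit_cv_frac`` scales within-person visit-to-visit noise as a fraction
    of the between-person SD. ``floor`` clips physiologically impossible
    values from the Gaussian tail.
    """

    mean: float
    sd: float
    dist: str = "normal"
    visit_cv_frac: float = 0.10
    floor: float | None = None


# Means/SDs of the usual-care obesity group; insulin, triglycerides and CRP
# are right-skewed and drawn log-normal.
DEFAULT_CLINICAL_PANEL: Mapping[str, ClinicalVariable] = {
    "bmi": ClinicalVariable(40.4, 5.26, floor=18.0),
    "glucose_mmol_l": ClinicalVariable(5.94, 2.38, floor=2.5),
    "insulin_mu_l": ClinicalVariable(17.3, 12.4, dist="lognormal"),
    "total_chol_mmol_l": ClinicalVariable(5.48, 1.05, floor=2.0),
    "hdl_c_mmol_l": ClinicalVariable(1.38, 0.33, floor=0.3),
    "triglycerides_mmol_l": ClinicalVariable(1.95, 1.37, dist="lognormal"),
    "sbp_mmhg": ClinicalVariable(142.0, 18.7, floor=80.0),
    "dbp_mmhg": ClinicalVariable(82.9, 9.76, floor=40.0),
    "crp_mg_l": ClinicalVariable(7.89, 8.18, dist="lognormal"),
}

# Bernoulli probabilities for the binary panel entries.
DEFAULT_BINARY_PANEL: Mapping[str, float] = {
    "male": 0.299,
    "smoker": 0.25,
    "diabetes_med": 0.10,
    "bp_med": 0.35,
}


@dataclass(frozen=True)
class CohortConfig:
    n_individuals: int = 40
    baseline_age_range: tuple[float, float] = (37.0, 60.0)
    timepoints: tuple[float, ...] = (0.0, 2.0, 10.0, 15.0, 20.0)
    #: per-timepoint retention; integers are absolute counts subsampled
    #: without replacement, floats in [0, 1] are Bernoulli probabilities
    dropout_pattern: tuple[float, ...] = (40, 38, 40, 38, 24)
    coverage_mean: float = 3891.0
    n_replicates: int = 2
    carrier_prevalence_at_mean_age: float = 0.206
    prevalence_age_log_odds: float = 0.05
    growth_log_mean: float = math.log(1.07)
    growth_log_sd: float = 0.06
    #: natural log of baseline VAF in percent (median 1%)
    baseline_vaf_log_mean: float = 0.0
    baseline_vaf_log_sd: float = 1.2
    #: per-year effect of age on ln(VAF) in the cross-sectional design
    #: (0 = clone size independent of age at sampling)
    vaf_age_log_slope: float = 0.0
    multi_clone_prob: float = 0.20
    hdl_growth_spearman_target: float = -0.68
    clinical_panel_params: Mapping[str, ClinicalVariable] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_PANEL)
    )
    binary_panel_params: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BINARY_PANEL)
    )
    #: disable read-count noise: totals fixed at coverage_mean, alt = round
    noiseless: bool = False
    vaf_ceiling_pct: float = 50.0  # heterozygous bound
    vaf_floor_pct: float = 0.01
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.baseline_age_range
        if not lo < hi:
            raise ConfigError(f"baseline_age_range inverted: ({lo}, {hi})")
        tps = tuple(float(t) for t in self.timepoints)
        if len(tps) == 0 or tps[0] != 0.0:
            raise ConfigError("timepoints must start at 0")
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ConfigError(f"timepoints must be strictly increasing: {tps}")
        if len(self.dropout_pattern) != len(tps):
            raise ConfigError(
                f"dropout_pattern has {len(self.dropout_pattern)} entries "
                f"for {len(tps)} timepoints"
            )
        for r in self.dropout_pattern:
            if isinstance(r, float) and not r.is_integer():
                if not 0.0 <= r <= 1.0:
                    raise ConfigError(f"retention probability {r} outside [0, 1]")
            elif not 0 <= int(r) <= self.n_individuals:
                raise ConfigError(
                    f"retention count {r} outside [0, {self.n_individuals}]"
                )
        if self.coverage_mean <= 0:
            raise ConfigError("coverage_mean must be positive")
        if self.n_replicates != 2:
            raise ConfigError("the assay model is defined for exactly 2 replicates")
        if not 0.0 <= self.carrier_prevalence_at_mean_age <= 1.0:
            raise ConfigError("carrier_prevalence_at_mean_age outside [0, 1]")
        if not 0.0 <= self.multi_clone_prob <= 1.0:
            raise ConfigError("multi_clone_prob outside [0, 1]")
        if self.growth_log_sd < 0:
            raise ConfigError("growth_log_sd must be non-negative")
        if not -1.0 <= self.hdl_growth_spearman_target <= 1.0:
            raise ConfigError("hdl_growth_spearman_target outside [-1, 1]")

    def with_(self, **kwargs) -> "CohortConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def retention_counts(self) -> list[int] | None:
        """Absolute retention counts, or None if probabilities were given.

        Entries all <= 1.0 are read as per-individual retention
        probabilities; otherwise as absolute counts.
        """
        if all(float(r) <= 1.0 for r in self.dropout_pattern):
            return None
        return [int(r) for r in self.dropout_pattern]


def load_config(path: str) -> CohortConfig:
    """Load a CohortConfig from a YAML file; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} is not a mapping")
    known = CohortConfig.__dataclass_fields__.keys()
    unknown = set(raw) - set(known)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "clinical_panel_params" in raw:
        raw["clinical_panel_params"] = {
            k: ClinicalVariable(**v) for k, v in raw["clinical_panel_params"].items()
        }
    for key in ("timepoints", "dropout_pattern", "baseline_age_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return CohortConfig(**raw)
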