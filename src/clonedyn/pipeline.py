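"""End-to-end orchestration of the two study designs.

``run_single_timepoint`` reproduces the cross-sectional analysis: replicate
calling, cohort summary, logistic prevalence-vs-age fit, and the OLS fit of
log clone size on age (largest clone per carrier).

``run_longitudinal`` reproduces the longitudinal analysis: replicate
calling, trajectory assembly and classification, dominant-trajectory
selection with exclusion of shrinking-dominant individuals, the
random-intercept/random-slope growth model, and Spearman associations of
per-individual growth rates with clinical covariates averaged over the first
three follow-up visits (plus the sensitivity analysis retaining shrinking
individuals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from . import association, cohort_stats, detection, growthmodel, trajectories

__all__ = ["run_single_timepoint", "run_longitudinal",
           "SingleTimepointReport", "LongitudinalReport", "dominant_long_table"]


@dataclass
class SingleTimepointReport:
    summary: cohort_stats.CohortSummary
    logvaf_fit: growthmodel.LogVafAgeFit
    carrier_fit: growthmodel.CarrierAgeFit
    calls: pd.DataFrame


@dataclass
class LongitudinalReport:
    calls: pd.DataFrame
    trajectories: list
    dominant: list  # DominantSelection per individual
    n_excluded_shrinking: int
    n_no_traceable: int
    growth: growthmodel.MixedGrowthFit
    associations: list  # primary + secondary AssociationResult
    sensitivity: list  # AssociationResult, shrinking retained
    covariate_means: pd.DataFrame


def _largest_clone_per_carrier(calls: pd.DataFrame) -> pd.DataFrame:
    det = calls[calls["detected"]]
    idx = det.groupby("individual_id")["vaf_pct"].idxmax()
    return det.loc[idx, ["individual_id", "age_years", "vaf_pct"]]


def run_single_timepoint(
    observations: pd.DataFrame,
    clinical: pd.DataFrame,
    min_alt_reads: int = 3,
    vaf_floor_pct: float = 0.01,
) -> SingleTimepointReport:
    if observations.empty or clinical.empty:
        from .errors import InputError

        raise InputError("empty input tables")
    calls = detection.call_table(observations, min_alt_reads, vaf_floor_pct)
    summary = cohort_stats.summarize_cohort(clinical, calls)
    carriers = _largest_clone_per_carrier(calls)
    logvaf_fit = growthmodel.fit_logvaf_vs_age(carriers)
    carrier_ids = set(carriers["individual_id"])
    cohort = clinical[["individual_id", "age_years"]].copy()
    cohort["carrier"] = cohort["individual_id"].isin(carrier_ids).astype(int)
    carrier_fit = growthmodel.fit_carrier_vs_age(cohort)
    return SingleTimepointReport(summary, logvaf_fit, carrier_fit, calls)


def dominant_long_table(selections) -> pd.DataFrame:
    """Long (individual, age, vaf) table of dominant trajectories."""
    rows = []
    for sel in selections:
        if sel.status != "dominant":
            continue
        for p in sel.trajectory.points:
            rows.append({"individual_id": sel.individual_id,
                         "age_years": p.age_years, "vaf_pct": p.vaf_pct})
    return pd.DataFrame(rows, columns=["individual_id", "age_years", "vaf_pct"])


def run_longitudinal(
    observations: pd.DataFrame,
    clinical: pd.DataFrame,
    min_alt_reads: int = 3,
    vaf_floor_pct: float = 0.01,
    response_scale: str = "log",
    run_sensitivity: bool = True,
) -> LongitudinalReport:
    if observations.empty or clinical.empty:
        from .errors import InputError

        raise InputError("empty input tables")
    calls = detection.call_table(observations, min_alt_reads, vaf_floor_pct)
    trajs = trajectories.build_trajectories(calls)
    by_ind: dict[str, list] = {}
    for t in trajs:
        by_ind.setdefault(t.individual_id, []).append(t)
    selections = [trajectories.select_dominant(ts) for ts in by_ind.values()]
    n_shrink = sum(1 for s in selections if s.status == "excluded_shrinking")
    n_none = sum(1 for s in selections if s.status == "no_traceable")

    long = dominant_long_table(selections)
    growth = growthmodel.fit_mixed_growth(long, response_scale=response_scale)

    derived = association.derive_clinical(clinical)
    means = association.average_first_three(derived)
    assoc = association.correlate_growth(growth.estimates_frame(), means)
    sens = (association.sensitivity_including_shrinking(
        trajs, clinical, response_scale=response_scale)
        if run_sensitivity else [])
    return LongitudinalReport(
        calls=calls, trajectories=trajs, dominant=selections,
        n_excluded_shrinking=n_shrink, n_no_traceable=n_none,
        growth=growth, associations=assoc, sensitivity=sens,
        covariate_means=means,
    )
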