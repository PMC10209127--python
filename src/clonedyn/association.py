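"""Clinical derivations and growth-rate / metabolic-covariate associations.

Derived clinical quantities follow standard clinical formulae:

* HOMA-IR = insulin (mU/L) x glucose (mmol/L) / 22.5
* Friedewald LDL-C = total cholesterol - triglycerides/2.2 - HDL-C (mmol/L;
  invalid and left missing when triglycerides exceed 4.5 mmol/L)
* non-HDL-C = total cholesterol - HDL-C
* hypertension: SBP >= 140 or DBP >= 90 or antihypertensive medication
* diabetes: glucose >= 7.0 mmol/L or anti-diabetes medication

Per-individual growth rates are correlated (Spearman, average ranks) with
covariates averaged over the first three follow-up visits. The primary
covariate family is Bonferroni-corrected; triglycerides and non-HDL
cholesterol are secondary, reported unadjusted. For n <= 8 pairs the
two-sided p-value is computed by exact permutation over all n! pairings
(the asymptotic t approximation is unusable at such n).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = [
    "AssociationResult", "derive_clinical", "average_first_three",
    "correlate_growth", "PRIMARY_FAMILY", "SECONDARY_FAMILY",
    "FRIEDEWALD_TG_LIMIT", "spearman_with_p",
]

FRIEDEWALD_TG_LIMIT = 4.5  # mmol/L; Friedewald LDL invalid above this
_EXACT_PERM_MAX_N = 8

#: covariates in the Bonferroni-corrected primary family (m = 10)
PRIMARY_FAMILY: tuple[str, ...] = (
    "bmi", "glucose_mmol_l", "insulin_mu_l", "homa_ir", "total_chol_mmol_l",
    "hdl_c_mmol_l", "ldl_c_mmol_l", "crp_mg_l", "sbp_mmhg", "dbp_mmhg",
)
#: secondary explorative covariates, reported without correction
SECONDARY_FAMILY: tuple[str, ...] = ("triglycerides_mmol_l", "non_hdl_c_mmol_l")


@dataclass(frozen=True)
class AssociationResult:
    covariate: str
    spearman_r: float
    p_raw: float
    p_bonferroni: float  # NaN for secondary/sensitivity covariates
    n: int
    family: str  # primary | secondary | sensitivity


def derive_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Complete a clinical table with derived indices and diagnosis flags."""
    df = clinical.copy()
    df["homa_ir"] = df["insulin_mu_l"] * df["glucose_mmol_l"] / 22.5
    ldl = (df["total_chol_mmol_l"] - df["triglycerides_mmol_l"] / 2.2
           - df["hdl_c_mmol_l"])
    df["ldl_c_mmol_l"] = ldl.where(df["triglycerides_mmol_l"] <= FRIEDEWALD_TG_LIMIT)
    df["non_hdl_c_mmol_l"] = df["total_chol_mmol_l"] - df["hdl_c_mmol_l"]
    bp_med = df.get("bp_med", pd.Series(0, index=df.index)).fillna(0).astype(bool)
    dm_med = df.get("diabetes_med", pd.Series(0, index=df.index)).fillna(0).astype(bool)
    df["hypertension"] = ((df["sbp_mmhg"] >= 140) | (df["dbp_mmhg"] >= 90) | bp_med)
    df["diabetes"] = (df["glucose_mmol_l"] >= 7.0) | dm_med
    return df


def average_first_three(
    clinical: pd.DataFrame,
    follow_up_timepoints: list[float] | None = None,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Per-individual covariate means over the first three follow-up visits.

    Follow-up visits are the scheduled post-baseline timepoints; by default
    the first three distinct positive timepoints present anywhere in the
    table. Individuals missing some of those visits contribute the mean of
    the visits they attended; individuals with none of them are dropped.
    """
    if follow_up_timepoints is None:
        post = sorted(t for t in clinical["timepoint_years"].unique() if t > 0)
        follow_up_timepoints = post[:3]
    if not follow_up_timepoints:
        raise InputError("no follow-up timepoints available to average over")
    sub = clinical[clinical["timepoint_years"].isin(follow_up_timepoints)]
    if covariates is None:
        covariates = [c for c in sub.columns
                      if c not in ("individual_id", "timepoint_years", "sex")
                      and pd.api.types.is_numeric_dtype(sub[c])]
    out = sub.groupby("individual_id")[covariates].mean()
    return out.reset_index()


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    if np.std(rx) == 0 or np.std(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def _exact_perm_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided p over all pairings of y against x (n <= 8)."""
    n = len(x)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = _spearman_rho(x, y[list(perm)])
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def spearman_with_p(x, y) -> tuple[float, float, int]:
    """Spearman rho with a two-sided p-value; exact permutation for n <= 8.

    Returns (rho, p, n) after dropping pairs with missing values; rho is NaN
    (p = NaN) when either margin has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 2:
        return float("nan"), float("nan"), n
    rho = _spearman_rho(x, y)
    if math.isnan(rho):
        return rho, float("nan"), n
    if n <= _EXACT_PERM_MAX_N:
        p = _exact_perm_p(x, y, rho)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, float(p), n


def correlate_growth(
    rates: pd.DataFrame,
    covariate_means: pd.DataFrame,
    primary: tuple[str, ...] = PRIMARY_FAMILY,
    secondary: tuple[str, ...] = SECONDARY_FAMILY,
    rate_col: str = "rate_pct_per_year",
    family_label: str = "primary",
    min_pairs: int = 5,
) -> list[AssociationResult]:
    """Correlate per-individual growth rates with averaged covariates.

    ``rates`` has one row per individual (``individual_id``, ``rate_col``);
    ``covariate_means`` is the output of :func:`average_first_three`.
    Primary-family p-values are Bonferroni-corrected with m = len(primary);
    secondary covariates are reported raw. Covariates with fewer than
    ``min_pairs`` complete pairs are skipped.
    """
    merged = rates[["individual_id", rate_col]].merge(
        covariate_means, on="individual_id", how="inner"
    )
    m = len(primary)
    results: list[AssociationResult] = []
    for cov, fam in [(c, family_label) for c in primary] + \
                    [(c, "secondary" if family_label == "primary" else family_label)
                     for c in secondary]:
        if cov not in merged.columns:
            continue
        rho, p, n = spearman_with_p(merged[rate_col], merged[cov])
        if n < min_pairs:
            continue
        if fam == family_label and cov in primary:
            p_bonf = min(1.0, m * p) if np.isfinite(p) else float("nan")
        else:
            p_bonf = float("nan")
        results.append(AssociationResult(
            covariate=cov, spearman_r=rho, p_raw=p, p_bonferroni=p_bonf,
            n=n, family=fam,
        ))
    return results


def sensitivity_including_shrinking(
    trajectories,
    clinical: pd.DataFrame,
    primary: tuple[str, ...] = PRIMARY_FAMILY,
    secondary: tuple[str, ...] = SECONDARY_FAMILY,
    response_scale: str = "log",
) -> list[AssociationResult]:
    """Primary correlation analysis re-run retaining shrinking-dominant individuals.

    Identical to the main analysis except that dominant-trajectory selection
    keeps individuals whose dominant trajectory is shrinking; results are
    labelled ``sensitivity``.
    """
    from .growthmodel import fit_mixed_growth
    from .trajectories import select_dominant

    rows = []
    trajs = list(trajectories)
    by_ind: dict[str, list] = {}
    for t in trajs:
        by_ind.setdefault(t.individual_id, []).append(t)
    for ind, ts in by_ind.items():
        sel = select_dominant(ts, include_shrinking=True)
        if sel.status != "dominant":
            continue
        for p in sel.trajectory.points:
            rows.append({"individual_id": ind, "age_years": p.age_years,
                         "vaf_pct": p.vaf_pct})
    long = pd.DataFrame(rows)
    fit = fit_mixed_growth(long, response_scale=response_scale)
    means = average_first_three(derive_clinical(clinical))
    return correlate_growth(
        fit.estimates_frame(), means, primary=primary, secondary=secondary,
        family_label="sensitivity",
    )


def associations_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"covariate": r.covariate, "n": r.n, "spearman_r": r.spearman_r,
          "p_raw": r.p_raw, "p_bonferroni": r.p_bonferroni, "family": r.family}
         for r in results],
        columns=["covariate", "n", "spearman_r", "p_raw", "p_bonferroni", "family"],
    )
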