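"""Descriptive cohort summaries and between-group comparisons.

Produces baseline-characteristics tables (mean (SD) for continuous
variables, n (%) for categorical) together with CHDM carrier prevalence, the
clones-per-carrier distribution, and the fraction of carriers at CHIP scale,
plus two-group tests: Welch t-test for continuous variables, chi-square for
categorical ones (continuity correction off by default, both variants
available), and Wilcoxon rank-sum for age comparisons.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .detection import CHIP_THRESHOLD_PCT
from .errors import InputError

__all__ = ["CohortSummary", "summarize_cohort", "compare_groups", "render_table"]

CONTINUOUS_VARS = [
    "age_years", "bmi", "glucose_mmol_l", "insulin_mu_l", "total_chol_mmol_l",
    "hdl_c_mmol_l", "triglycerides_mmol_l", "sbp_mmhg", "dbp_mmhg", "crp_mg_l",
]
CATEGORICAL_VARS = ["smoker", "diabetes_med", "bp_med"]


@dataclass(frozen=True)
class CohortSummary:
    n_individuals: int
    n_carriers: int
    prevalence_pct: float
    clones_per_carrier: dict[int, int]
    n_chip_carriers: int
    chip_pct_of_carriers: float
    continuous: dict[str, tuple[float, float]]  # var -> (mean, sd)
    categorical: dict[str, tuple[int, float]]  # var -> (n, pct)


def _pct(num: int, den: int) -> float:
    return 100.0 * num / den if den else 0.0


def summarize_cohort(
    clinical: pd.DataFrame,
    calls: pd.DataFrame,
    chip_threshold_pct: float = CHIP_THRESHOLD_PCT,
) -> CohortSummary:
    """Summarise one cohort at its DNA-sampling timepoint.

    ``clinical`` has one row per individual; ``calls`` is the called
    observations table (only detected rows count as clones).
    """
    if clinical.empty:
        raise InputError("empty cohort")
    if clinical["individual_id"].duplicated().any():
        raise InputError("expected one clinical row per individual")
    n = len(clinical)
    det = (calls[calls["detected"].astype(bool)]
           if "detected" in calls.columns else calls)
    clones = det.groupby("individual_id").size()
    carriers = set(clones.index)
    n_car = len(carriers)
    per_carrier = Counter(int(c) for c in clones)
    max_vaf = det.groupby("individual_id")["vaf_pct"].max()
    n_chip = int((max_vaf >= chip_threshold_pct).sum())

    continuous = {}
    for var in CONTINUOUS_VARS:
        if var in clinical.columns:
            vals = clinical[var].dropna()
            continuous[var] = (float(vals.mean()), float(vals.std(ddof=1)))
    categorical = {}
    if "sex" in clinical.columns:
        n_male = int((clinical["sex"] == "M").sum())
        categorical["male"] = (n_male, _pct(n_male, n))
    for var in CATEGORICAL_VARS:
        if var in clinical.columns:
            k = int(clinical[var].astype(bool).sum())
            categorical[var] = (k, _pct(k, n))

    return CohortSummary(
        n_individuals=n, n_carriers=n_car, prevalence_pct=_pct(n_car, n),
        clones_per_carrier=dict(sorted(per_carrier.items())),
        n_chip_carriers=n_chip, chip_pct_of_carriers=_pct(n_chip, n_car),
        continuous=continuous, categorical=categorical,
    )


def compare_groups(
    clinical_a: pd.DataFrame,
    clinical_b: pd.DataFrame,
    summary_a: CohortSummary,
    summary_b: CohortSummary,
    yates: bool = False,
    age_ranksum: bool = True,
) -> dict[str, float]:
    """Between-group p-values for a two-cohort comparison.

    Continuous variables: Welch t-test; categorical and carrier prevalence:
    chi-square on the 2x2 counts (Yates continuity correction optional, off
    by default); age optionally also compared by Wilcoxon rank-sum
    (``age_ranksum_p``). Zero-variance continuous variables yield NaN.
    """
    if clinical_a.empty or clinical_b.empty:
        raise InputError("both groups must be non-empty")
    out: dict[str, float] = {}
    for var in CONTINUOUS_VARS:
        if var not in clinical_a.columns or var not in clinical_b.columns:
            continue
        xa = clinical_a[var].dropna().to_numpy(dtype=float)
        xb = clinical_b[var].dropna().to_numpy(dtype=float)
        if np.std(xa) == 0 and np.std(xb) == 0:
            import warnings

            warnings.warn(f"zero-variance variable {var}; p-value undefined",
                          stacklevel=2)
            out[var] = float("nan")
            continue
        t, p = stats.ttest_ind(xa, xb, equal_var=False)
        out[var] = float(p) if np.isfinite(p) else float("nan")
    if age_ranksum and "age_years" in clinical_a.columns:
        xa = clinical_a["age_years"].dropna()
        xb = clinical_b["age_years"].dropna()
        out["age_ranksum_p"] = float(stats.ranksums(xa, xb).pvalue)

    def chi2_2x2(k1, n1, k2, n2):
        table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            return float("nan")
        if (table == table[0]).all() and n1 == n2:
            return 1.0
        res = stats.chi2_contingency(table, correction=yates)
        return float(res.pvalue)

    out["carrier_prevalence"] = chi2_2x2(
        summary_a.n_carriers, summary_a.n_individuals,
        summary_b.n_carriers, summary_b.n_individuals,
    )
    if summary_a.n_carriers and summary_b.n_carriers:
        out["chip_fraction"] = chi2_2x2(
            summary_a.n_chip_carriers, summary_a.n_carriers,
            summary_b.n_chip_carriers, summary_b.n_carriers,
        )
    for var in ["male"] + CATEGORICAL_VARS:
        if var in summary_a.categorical and var in summary_b.categorical:
            out[var] = chi2_2x2(
                summary_a.categorical[var][0], summary_a.n_individuals,
                summary_b.categorical[var][0], summary_b.n_individuals,
            )
    return out


def render_table(
    summary_a: CohortSummary,
    summary_b: CohortSummary | None = None,
    p_values: dict[str, float] | None = None,
    label_a: str = "group A",
    label_b: str = "group B",
) -> str:
    """Markdown baseline-characteristics table for one or two cohorts."""
    lines = []
    headers = ["Characteristic", label_a] + ([label_b] if summary_b else []) + \
        (["P"] if p_values else [])
    lines.append("| " + " | ".join(headers) + " |")
    lines.append("|" + "---|" * len(headers))

    def row(name, fa, fb=None, p=None):
        cells = [name, fa] + ([fb] if summary_b else []) + \
            ([f"{p:.3g}" if p is not None and np.isfinite(p) else ""]
             if p_values else [])
        lines.append("| " + " | ".join(cells) + " |")

    def prev(s):
        return f"{s.n_carriers} ({s.prevalence_pct:.1f})"

    row("CHDM carriers, n (%)", prev(summary_a),
        prev(summary_b) if summary_b else None,
        (p_values or {}).get("carrier_prevalence"))

    def chip(s):
        return f"{s.n_chip_carriers} ({s.chip_pct_of_carriers:.1f})"

    row("CHIP, n (% of carriers)", chip(summary_a),
        chip(summary_b) if summary_b else None,
        (p_values or {}).get("chip_fraction"))
    for var in CONTINUOUS_VARS:
        if var not in summary_a.continuous:
            continue
        fa = "%.2f (%.2f)" % summary_a.continuous[var]
        fb = ("%.2f (%.2f)" % summary_b.continuous[var]
              if summary_b and var in summary_b.continuous else "")
        row(f"{var}, mean (SD)", fa, fb, (p_values or {}).get(var))
    for var, (k, pct) in summary_a.categorical.items():
        fb = ("%d (%.1f)" % summary_b.categorical[var]
              if summary_b and var in summary_b.categorical else "")
        row(f"{var}, n (%)", f"{k} ({pct:.1f})", fb, (p_values or {}).get(var))
    return "\n".join(lines)
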