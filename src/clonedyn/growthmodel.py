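"""Clone-size and clone-growth models.

Single-timepoint cohorts support two cross-sectional fits: a logistic
regression of carrier status on age (prevalence rises with age) and an OLS
regression of log clone size on age, whose age coefficient b converts to a
proportionate size difference of 100*(exp(b) - 1) percent per year of age.

Longitudinal cohorts support a linear mixed model of ln(VAF) on age with
correlated random intercept and random slope per individual (REML). Because
ln(VAF) is linear in time for a clone growing at a constant proportionate
rate, each individual's slope (fixed effect + predicted random effect) is
that individual's growth rate on the log scale, and
``rate = 100*(exp(slope) - 1)`` is the annual percent growth of the clone.

Age is centred (and expressed in decades) internally for conditioning; all
reported slopes are per year on the original scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLMParams
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationWarning,
)

from .errors import (
    ConvergenceError,
    InputError,
    InsufficientDataError,
    SeparationError,
)

__all__ = [
    "GrowthEstimate", "MixedGrowthFit", "LogVafAgeFit", "CarrierAgeFit",
    "fit_logvaf_vs_age", "fit_carrier_vs_age", "fit_mixed_growth",
    "rate_from_slope", "slope_from_rate",
]

_AGE_SCALE = 10.0  # internal age unit: decades


def rate_from_slope(slope_log_per_year: float) -> float:
    """Per-year log-VAF slope -> proportionate annual growth, percent."""
    return 100.0 * float(np.expm1(slope_log_per_year))


def slope_from_rate(rate_pct_per_year: float) -> float:
    """Inverse of :func:`rate_from_slope`."""
    return float(np.log1p(rate_pct_per_year / 100.0))


@dataclass(frozen=True)
class GrowthEstimate:
    """One individual's estimated clone growth."""

    individual_id: str
    slope_log_per_year: float
    rate_pct_per_year: float
    intercept: float  # ln(VAF) extrapolated to age 0
    n_points: int


@dataclass(frozen=True)
class LogVafAgeFit:
    """OLS of log clone size on age (one row per carrier, largest clone)."""

    logvaf_age_coef: float
    pct_per_year: float
    p_value: float
    std_err: float
    intercept: float
    n: int


@dataclass(frozen=True)
class CarrierAgeFit:
    """Logistic regression of carrier status on age."""

    logistic_age_coef: float
    p_value: float
    std_err: float
    intercept: float
    n: int


@dataclass(frozen=True)
class MixedGrowthFit:
    fixed_slope_log_per_year: float
    fixed_slope_se: float
    fixed_intercept: float
    mean_rate_pct_per_year: float
    estimates: tuple[GrowthEstimate, ...]
    converged: bool
    reml: bool
    diagonal_fallback: bool  # random-effects covariance forced diagonal
    n_individuals: int
    n_observations: int

    def estimates_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"individual_id": e.individual_id,
              "slope_log_per_year": e.slope_log_per_year,
              "rate_pct_per_year": e.rate_pct_per_year,
              "n_points": e.n_points} for e in self.estimates],
            columns=["individual_id", "slope_log_per_year",
                     "rate_pct_per_year", "n_points"],
        )


def fit_logvaf_vs_age(
    carriers: pd.DataFrame,
    vaf_col: str = "vaf_pct",
    age_col: str = "age_years",
) -> LogVafAgeFit:
    """OLS of ln(VAF) on age across carriers (one row per individual).

    Callers supply each carrier's largest clone when individuals have
    several. Requires at least 3 carriers.
    """
    df = carriers.dropna(subset=[vaf_col, age_col])
    if len(df) < 3:
        raise InsufficientDataError(f"need >= 3 carriers, got {len(df)}")
    if (df[vaf_col] <= 0).any():
        raise InputError("non-positive VAF cannot be log-transformed")
    y = np.log(df[vaf_col].to_numpy(dtype=float))
    X = sm.add_constant(df[age_col].to_numpy(dtype=float))
    res = sm.OLS(y, X).fit()
    coef = float(res.params[1])
    return LogVafAgeFit(
        logvaf_age_coef=coef,
        pct_per_year=rate_from_slope(coef),
        p_value=float(res.pvalues[1]),
        std_err=float(res.bse[1]),
        intercept=float(res.params[0]),
        n=len(df),
    )


def fit_carrier_vs_age(
    cohort: pd.DataFrame,
    carrier_col: str = "carrier",
    age_col: str = "age_years",
) -> CarrierAgeFit:
    """Maximum-likelihood logistic fit of carrier status on age.

    Raises :class:`SeparationError` when the outcome is single-class or the
    likelihood is degenerate (perfect separation).
    """
    df = cohort.dropna(subset=[carrier_col, age_col])
    y = df[carrier_col].astype(int).to_numpy()
    if y.min() == y.max():
        raise SeparationError("carrier status is constant; logistic fit undefined")
    X = sm.add_constant(df[age_col].to_numpy(dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (PerfectSeparationWarning, Exception) as exc:  # noqa: BLE001
            if "separation" in str(exc).lower() or isinstance(
                exc, PerfectSeparationWarning
            ):
                raise SeparationError(f"perfect separation: {exc}") from exc
            raise
    coef = float(res.params[1])
    if not np.isfinite(res.bse).all() or abs(coef) > 50:
        raise SeparationError("degenerate logistic fit (runaway coefficient)")
    return CarrierAgeFit(
        logistic_age_coef=coef,
        p_value=float(res.pvalues[1]),
        std_err=float(res.bse[1]),
        intercept=float(res.params[0]),
        n=len(df),
    )


def _ols_slope(age: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(intercept, slope) of y on age by least squares."""
    A = np.column_stack([np.ones_like(age), age])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(coef[0]), float(coef[1])


def fit_mixed_growth(
    data: pd.DataFrame,
    individual_col: str = "individual_id",
    age_col: str = "age_years",
    vaf_col: str = "vaf_pct",
    response_scale: str = "log",
    reml: bool = True,
    force_diagonal: bool = False,
) -> MixedGrowthFit:
    """Random-intercept/random-slope model of clone size on age.

    ``data`` is a long table of the dominant trajectory's detections: one row
    per individual per detected timepoint. Each individual needs >= 2 points.
    With ``response_scale='log'`` (default) the response is ln(VAF) and
    per-individual rates are 100*(exp(slope)-1); with ``'raw'`` the response
    is VAF in percent and rates are reported as the raw slope.

    A single-individual input degenerates to that individual's OLS line (the
    mixed model is unidentifiable with one group). ``force_diagonal``
    constrains the random intercept and slope to be uncorrelated (also the
    automatic fallback when the correlated fit is singular).
    """
    if response_scale not in ("log", "raw"):
        raise InputError(f"response_scale must be 'log' or 'raw': {response_scale}")
    df = data.dropna(subset=[individual_col, age_col, vaf_col]).copy()
    df[individual_col] = df[individual_col].astype(str)
    counts = df.groupby(individual_col).size()
    thin = counts[counts < 2]
    if len(thin):
        raise InsufficientDataError(
            f"individuals with < 2 points: {list(thin.index)}"
        )
    if df.empty:
        raise InsufficientDataError("empty input")
    if response_scale == "log":
        if (df[vaf_col] <= 0).any():
            raise InputError("non-positive VAF cannot be log-transformed")
        df["_y"] = np.log(df[vaf_col].astype(float))
    else:
        df["_y"] = df[vaf_col].astype(float)

    age = df[age_col].to_numpy(dtype=float)
    age_mean = float(age.mean())
    df["_age_c"] = (age - age_mean) / _AGE_SCALE

    groups = df[individual_col].astype(str)
    ids = list(dict.fromkeys(groups))

    def _finish(fixed_int_c, fixed_slope_c, per_ind, converged, diagonal,
                fixed_slope_se_c=float("nan")):
        # back-transform from centred decades to per-year at age 0
        fixed_slope = fixed_slope_c / _AGE_SCALE
        fixed_int = fixed_int_c - fixed_slope * age_mean
        estimates = []
        for ind in ids:
            b0_c, b1_c = per_ind[ind]
            slope = b1_c / _AGE_SCALE
            est_int = b0_c - slope * age_mean
            rate = rate_from_slope(slope) if response_scale == "log" else slope
            estimates.append(GrowthEstimate(
                individual_id=str(ind), slope_log_per_year=slope,
                rate_pct_per_year=rate, intercept=est_int,
                n_points=int(counts.loc[ind]),
            ))
        mean_rate = float(np.mean([e.rate_pct_per_year for e in estimates]))
        return MixedGrowthFit(
            fixed_slope_log_per_year=fixed_slope,
            fixed_slope_se=fixed_slope_se_c / _AGE_SCALE,
            fixed_intercept=fixed_int,
            mean_rate_pct_per_year=mean_rate, estimates=tuple(estimates),
            converged=converged, reml=reml, diagonal_fallback=diagonal,
            n_individuals=len(ids), n_observations=len(df),
        )

    if len(ids) == 1:
        b0, b1 = _ols_slope(df["_age_c"].to_numpy(), df["_y"].to_numpy())
        return _finish(b0, b1, {ids[0]: (b0, b1)}, True, False)

    exog = sm.add_constant(df["_age_c"].to_numpy())
    model = sm.MixedLM(df["_y"].to_numpy(), exog, groups=groups.to_numpy(),
                       exog_re=exog)

    def _try_fit(free=None):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = model.fit(reml=reml, method=["lbfgs", "bfgs", "cg"], free=free,
                            maxiter=500)
        conv_warned = any(issubclass(w.category, ConvergenceWarning)
                          for w in caught)
        return res, conv_warned

    diagonal = False
    if force_diagonal:
        res, singular = None, True
        conv_warned = False
    else:
        try:
            res, conv_warned = _try_fit()
            singular = (np.linalg.matrix_rank(np.asarray(res.cov_re)) < 2
                        or not np.isfinite(np.asarray(res.cov_re)).all())
        except (np.linalg.LinAlgError, ValueError):
            res, conv_warned, singular = None, True, True

    if res is None or singular:
        # fall back to independent random intercept and slope
        diagonal = True
        free = MixedLMParams.from_components(
            fe_params=np.ones(2), cov_re=np.eye(2)
        )
        try:
            res, conv_warned = _try_fit(free=free)
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise ConvergenceError(
                "mixed model failed even with diagonal random effects",
                {"n_individuals": len(ids), "n_observations": len(df),
                 "error": str(exc)},
            ) from exc

    if not np.isfinite(res.fe_params).all():
        raise ConvergenceError(
            "non-finite fixed effects",
            {"fe_params": [float(v) for v in res.fe_params]},
        )

    fixed_int_c, fixed_slope_c = (float(res.fe_params[0]), float(res.fe_params[1]))
    per_ind = {}
    if float(res.scale) < 1e-8 * float(np.var(df["_y"])):
        # residual variance at (numerically) zero: the BLUPs degenerate to
        # per-group OLS exactly; computing them directly avoids noise from
        # the near-singular marginal covariance
        for ind, grp in df.groupby(individual_col):
            per_ind[ind] = _ols_slope(grp["_age_c"].to_numpy(),
                                      grp["_y"].to_numpy())
    else:
        re = res.random_effects
        for ind in ids:
            b = np.asarray(re[ind], dtype=float)
            per_ind[ind] = (fixed_int_c + float(b[0]),
                            fixed_slope_c + float(b[1]))
    return _finish(fixed_int_c, fixed_slope_c, per_ind,
                   converged=bool(res.converged) and not conv_warned,
                   diagonal=diagonal,
                   fixed_slope_se_c=float(res.bse_fe[1]))
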