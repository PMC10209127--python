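"""Synthetic cohort generator.

Emulates the data structure of an obesity cohort assayed for clonal
haematopoiesis driver mutations (CHDMs) with an ultrasensitive dual-replicate
sequencing assay:

* each carrier harbours one or more clones whose true VAF grows
  geometrically, ``vaf(t) = min(ceiling, vaf0 * exp(log_slope * t))``;
* at every sampled timepoint each clone yields two technical replicates with
  ``total ~ Poisson(coverage_mean)`` and ``alt ~ Binomial(total, vaf/100)``;
* longitudinal sampling follows a fixed visit schedule with per-visit
  dropout (retention counts or probabilities);
* the clinical panel is drawn per individual (with small visit-to-visit
  noise); HDL-cholesterol is coupled to the individual's dominant true clone
  growth rate through a Gaussian copula calibrated so the Spearman rank
  correlation matches ``hdl_growth_spearman_target`` in expectation.

Everything is driven by one :class:`~clonedyn.config.CohortConfig` and a
single seed; identical config and seed give byte-identical tables.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
import pandas as pd

from .config import CohortConfig
from .errors import ConfigError

__all__ = [
    "GENE_PANEL",
    "generate_longitudinal_cohort",
    "generate_single_timepoint_cohort",
    "LongitudinalCohort",
    "SingleTimepointCohort",
]

# CH-driver panel: whole-gene DNMT3A plus established hotspots in other
# recurrently mutated genes; weights reflect the usual dominance of
# DNMT3A/TET2/ASXL1 in population CH.
GENE_PANEL: tuple[tuple[str, float], ...] = (
    ("DNMT3A", 0.40),
    ("TET2", 0.18),
    ("ASXL1", 0.10),
    ("JAK2", 0.06),
    ("PPM1D", 0.05),
    ("TP53", 0.04),
    ("SF3B1", 0.04),
    ("SRSF2", 0.04),
    ("GNB1", 0.03),
    ("CBL", 0.03),
    ("KRAS", 0.02),
    ("IDH2", 0.01),
)

_HOTSPOTS = {
    "DNMT3A": ("p.(Arg882His)", "p.(Arg882Cys)", "p.(Trp860Arg)", "p.(Tyr735Cys)"),
    "TET2": ("p.(Gln916Ter)", "p.(Cys1263Tyr)", "p.(His1881Arg)"),
    "ASXL1": ("p.(Gly646TrpfsTer12)", "p.(Glu635ArgfsTer15)"),
    "JAK2": ("p.(Val617Phe)",),
    "SF3B1": ("p.(Lys700Glu)", "p.(Lys666Asn)"),
    "SRSF2": ("p.(Pro95His)", "p.(Pro95Leu)"),
    "PPM1D": ("p.(Arg552Ter)", "p.(Ser468Ter)"),
    "TP53": ("p.(Arg273His)", "p.(Arg175His)"),
    "GNB1": ("p.(Lys57Glu)",),
    "CBL": ("p.(Cys404Tyr)",),
    "KRAS": ("p.(Gly12Asp)",),
    "IDH2": ("p.(Arg140Gln)",),
}

_AA3 = ("Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
        "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val")

OBSERVATION_COLUMNS = [
    "individual_id", "gene", "hgvs_p", "timepoint_years", "age_years",
    "alt_reads_rep1", "total_reads_rep1", "alt_reads_rep2", "total_reads_rep2",
]
CLINICAL_COLUMNS = [
    "individual_id", "timepoint_years", "age_years", "sex", "bmi",
    "glucose_mmol_l", "insulin_mu_l", "total_chol_mmol_l", "hdl_c_mmol_l",
    "triglycerides_mmol_l", "sbp_mmhg", "dbp_mmhg", "crp_mg_l", "smoker",
    "diabetes_med", "bp_med",
]
TRUTH_COLUMNS = ["individual_id", "gene", "hgvs_p", "vaf0_pct", "log_slope_per_year"]


class LongitudinalCohort(NamedTuple):
    observations: pd.DataFrame
    clinical: pd.DataFrame
    truth: pd.DataFrame


class SingleTimepointCohort(NamedTuple):
    observations: pd.DataFrame
    clinical: pd.DataFrame


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a log-normal with the given mean/sd."""
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _draw_mutation_labels(rng: np.random.Generator, n: int) -> list[tuple[str, str]]:
    """Draw n distinct (gene, hgvs_p) labels for one individual."""
    genes = [g for g, _ in GENE_PANEL]
    weights = np.array([w for _, w in GENE_PANEL])
    weights = weights / weights.sum()
    labels: list[tuple[str, str]] = []
    seen = set()
    while len(labels) < n:
        gene = genes[rng.choice(len(genes), p=weights)]
        hotspots = _HOTSPOTS.get(gene, ())
        if hotspots and rng.random() < 0.6:
            hgvs = hotspots[rng.integers(len(hotspots))]
        else:  # novel variant elsewhere in the target region
            pos = int(rng.integers(30, 1800))
            ref, alt = rng.choice(len(_AA3), size=2, replace=False)
            hgvs = f"p.({_AA3[ref]}{pos}{_AA3[alt]})"
        if (gene, hgvs) not in seen:
            seen.add((gene, hgvs))
            labels.append((gene, hgvs))
    return labels


def _draw_n_clones(rng: np.random.Generator, multi_clone_prob: float) -> int:
    if rng.random() >= multi_clone_prob:
        return 1
    # among multi-clone carriers, extra clones thin out geometrically
    return 2 + int(min(rng.geometric(0.7) - 1, 2))


def _true_vaf(vaf0: float, slope: float, t: float, ceiling: float) -> float:
    return min(ceiling, vaf0 * math.exp(slope * t))


def _sample_reads(
    rng: np.random.Generator, vaf_pct: float, coverage_mean: float, noiseless: bool
) -> tuple[int, int]:
    """One replicate: (alt, total) reads for a clone at true VAF (percent)."""
    if noiseless:
        total = int(round(coverage_mean))
        alt = int(round(total * vaf_pct / 100.0))
    else:
        total = max(1, int(rng.poisson(coverage_mean)))
        alt = int(rng.binomial(total, vaf_pct / 100.0))
    return alt, total


def _sampling_schedule(
    rng: np.random.Generator, config: CohortConfig
) -> np.ndarray:
    """Boolean (n_individuals, n_timepoints) attendance matrix."""
    n, k = config.n_individuals, len(config.timepoints)
    present = np.zeros((n, k), dtype=bool)
    counts = config.retention_counts()
    if counts is not None:
        for j, c in enumerate(counts):
            if c > n:
                raise ConfigError(f"retention count {c} exceeds cohort size {n}")
            idx = rng.choice(n, size=c, replace=False)
            present[idx, j] = True
    else:
        for j, p in enumerate(config.dropout_pattern):
            present[:, j] = rng.random(n) < float(p)
    return present


def _spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula Pearson rho achieving a given Spearman rho."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _clinical_latents(
    rng: np.random.Generator, config: CohortConfig, n: int
) -> dict[str, np.ndarray]:
    """Per-individual latent panel values (before HDL copula override)."""
    latents: dict[str, np.ndarray] = {}
    for name, var in config.clinical_panel_params.items():
        z = rng.standard_normal(n)
        latents[f"_z_{name}"] = z
        latents[name] = _transform_z(z, var)
    for name, p in config.binary_panel_params.items():
        latents[name] = (rng.random(n) < p).astype(int)
    return latents


def _transform_z(z: np.ndarray, var) -> np.ndarray:
    if var.dist == "lognormal":
        mu, sigma = _lognormal_params(var.mean, var.sd)
        vals = np.exp(mu + sigma * z)
    else:
        vals = var.mean + var.sd * z
    if var.floor is not None:
        vals = np.maximum(vals, var.floor)
    return vals


def _couple_hdl_to_growth(
    rng: np.random.Generator,
    config: CohortConfig,
    dominant_slope: np.ndarray,
    latents: dict[str, np.ndarray],
) -> None:
    """Replace the HDL latent so rank(HDL) ~ rank(dominant slope) at target.

    The dominant slope is max-selected across clones so its marginal law is
    unknown; working through normal scores of its ranks keeps the copula
    exact in rank terms regardless.
    """
    from scipy import stats

    n = dominant_slope.shape[0]
    target = config.hdl_growth_spearman_target
    rho = _spearman_to_pearson(target)
    ranks = stats.rankdata(dominant_slope, method="average")
    z_slope = stats.norm.ppf((ranks - 0.5) / n)
    eps = rng.standard_normal(n)
    z_hdl = rho * z_slope + math.sqrt(max(0.0, 1.0 - rho * rho)) * eps
    latents["hdl_c_mmol_l"] = _transform_z(
        z_hdl, config.clinical_panel_params["hdl_c_mmol_l"]
    )


def _clinical_rows(
    config: CohortConfig,
    rng: np.random.Generator,
    individual_ids: list[str],
    age0: np.ndarray,
    present: np.ndarray,
    latents: dict[str, np.ndarray],
) -> pd.DataFrame:
    rows = []
    panel = config.clinical_panel_params
    for i, ind in enumerate(individual_ids):
        for j, t in enumerate(config.timepoints):
            if not present[i, j]:
                continue
            row = {
                "individual_id": ind,
                "timepoint_years": float(t),
                "age_years": float(age0[i] + t),
                "sex": "M" if latents["male"][i] else "F",
            }
            for name, var in panel.items():
                visit_noise = rng.standard_normal() * var.sd * var.visit_cv_frac
                val = latents[name][i] + visit_noise
                if var.floor is not None:
                    val = max(val, var.floor)
                row[name] = float(val)
            for b in ("smoker", "diabetes_med", "bp_med"):
                row[b] = int(latents[b][i])
            rows.append(row)
    return pd.DataFrame(rows, columns=CLINICAL_COLUMNS)


def generate_longitudinal_cohort(config: CohortConfig) -> LongitudinalCohort:
    """Simulate a multiple-timepoint carrier cohort.

    Every individual is a CHDM carrier with at least one clone (the
    longitudinal design samples known carriers). Returns ``(observations,
    clinical, truth)``; observations hold raw replicate read counts for every
    clone at every attended visit, truth holds the planted baseline VAFs and
    per-year log-VAF slopes.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    ids = [f"S{i + 1:04d}" for i in range(n)]
    lo, hi = config.baseline_age_range
    age0 = rng.uniform(lo, hi, size=n)
    present = _sampling_schedule(rng, config)

    truth_rows = []
    clones_per_ind: list[list[tuple[str, str, float, float]]] = []
    for i, ind in enumerate(ids):
        n_clones = _draw_n_clones(rng, config.multi_clone_prob)
        labels = _draw_mutation_labels(rng, n_clones)
        clones = []
        for gene, hgvs in labels:
            logv = rng.normal(config.baseline_vaf_log_mean, config.baseline_vaf_log_sd)
            vaf0 = float(np.clip(math.exp(logv), config.vaf_floor_pct,
                                 config.vaf_ceiling_pct))
            slope = float(rng.normal(config.growth_log_mean, config.growth_log_sd))
            clones.append((gene, hgvs, vaf0, slope))
            truth_rows.append(
                {"individual_id": ind, "gene": gene, "hgvs_p": hgvs,
                 "vaf0_pct": vaf0, "log_slope_per_year": slope}
            )
        clones_per_ind.append(clones)

    # dominant true slope: clone attaining the highest true VAF at any
    # attended visit (ties: larger baseline VAF)
    dominant_slope = np.empty(n)
    for i in range(n):
        tps = [t for j, t in enumerate(config.timepoints) if present[i, j]] or [0.0]
        best = max(
            clones_per_ind[i],
            key=lambda c: (max(_true_vaf(c[2], c[3], t, config.vaf_ceiling_pct)
                               for t in tps), c[2]),
        )
        dominant_slope[i] = best[3]

    obs_rows = []
    for i, ind in enumerate(ids):
        for gene, hgvs, vaf0, slope in clones_per_ind[i]:
            for j, t in enumerate(config.timepoints):
                if not present[i, j]:
                    continue
                v = _true_vaf(vaf0, slope, t, config.vaf_ceiling_pct)
                a1, t1 = _sample_reads(rng, v, config.coverage_mean, config.noiseless)
                a2, t2 = _sample_reads(rng, v, config.coverage_mean, config.noiseless)
                obs_rows.append(
                    {"individual_id": ind, "gene": gene, "hgvs_p": hgvs,
                     "timepoint_years": float(t), "age_years": float(age0[i] + t),
                     "alt_reads_rep1": a1, "total_reads_rep1": t1,
                     "alt_reads_rep2": a2, "total_reads_rep2": t2}
                )

    latents = _clinical_latents(rng, config, n)
    _couple_hdl_to_growth(rng, config, dominant_slope, latents)
    clinical = _clinical_rows(config, rng, ids, age0, present, latents)

    observations = pd.DataFrame(obs_rows, columns=OBSERVATION_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return LongitudinalCohort(observations, clinical, truth)


def generate_single_timepoint_cohort(config: CohortConfig) -> SingleTimepointCohort:
    """Simulate a cross-sectional cohort with one DNA sample per individual.

    Carrier status follows a logistic model in age whose intercept is
    calibrated so prevalence at the midpoint of ``baseline_age_range`` equals
    ``carrier_prevalence_at_mean_age``. Carriers receive one or more clones
    with log-normal VAFs in [vaf_floor_pct, vaf_ceiling_pct]; non-carriers
    contribute clinical rows only.
    """
    from scipy.special import expit, logit

    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    ids = [f"P{i + 1:05d}" for i in range(n)]
    lo, hi = config.baseline_age_range
    ages = rng.uniform(lo, hi, size=n)
    mean_age = 0.5 * (lo + hi)
    # calibrate the intercept so the cohort-wide (marginal) prevalence hits
    # the target; with a zero age slope this is exactly the at-mean-age rule
    slope_term = config.prevalence_age_log_odds * (ages - mean_age)
    eta0 = float(logit(config.carrier_prevalence_at_mean_age))
    for _ in range(50):  # Newton on mean(expit(eta0 + s)) = target
        p = expit(eta0 + slope_term)
        grad = float(np.mean(p * (1 - p)))
        if grad < 1e-12:
            break
        step = (float(np.mean(p)) - config.carrier_prevalence_at_mean_age) / grad
        eta0 -= step
        if abs(step) < 1e-12:
            break
    carrier = rng.random(n) < expit(eta0 + slope_term)

    obs_rows = []
    for i, ind in enumerate(ids):
        if not carrier[i]:
            continue
        n_clones = _draw_n_clones(rng, config.multi_clone_prob)
        for gene, hgvs in _draw_mutation_labels(rng, n_clones):
            logv = rng.normal(
                config.baseline_vaf_log_mean
                + config.vaf_age_log_slope * (ages[i] - mean_age),
                config.baseline_vaf_log_sd,
            )
            vaf = float(np.clip(math.exp(logv), config.vaf_floor_pct,
                                config.vaf_ceiling_pct))
            a1, t1 = _sample_reads(rng, vaf, config.coverage_mean, config.noiseless)
            a2, t2 = _sample_reads(rng, vaf, config.coverage_mean, config.noiseless)
            obs_rows.append(
                {"individual_id": ind, "gene": gene, "hgvs_p": hgvs,
                 "timepoint_years": 0.0, "age_years": float(ages[i]),
                 "alt_reads_rep1": a1, "total_reads_rep1": t1,
                 "alt_reads_rep2": a2, "total_reads_rep2": t2}
            )

    latents = _clinical_latents(rng, config, n)
    present = np.ones((n, 1), dtype=bool)
    single_cfg = config  # reuse panel params; only visit 0 emitted
    rows = []
    for i, ind in enumerate(ids):
        row = {
            "individual_id": ind, "timepoint_years": 0.0,
            "age_years": float(ages[i]),
            "sex": "M" if latents["male"][i] else "F",
        }
        for name, var in single_cfg.clinical_panel_params.items():
            row[name] = float(latents[name][i])
        for b in ("smoker", "diabetes_med", "bp_med"):
            row[b] = int(latents[b][i])
        rows.append(row)
    clinical = pd.DataFrame(rows, columns=CLINICAL_COLUMNS)
    observations = pd.DataFrame(obs_rows, columns=OBSERVATION_COLUMNS)
    return SingleTimepointCohort(observations, clinical)
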