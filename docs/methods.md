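# Methods

This note documents the models, defaults, and design decisions behind
clonedyn, in the spirit of a statistical methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Detection model

The assay is modelled at the replicate read-count level: each sample yields
two independent PCR/sequencing replicates, each an `(alt, total)` pair for
every candidate mutation. The upstream consensus pipeline (UMI collapsing,
probe QC) is *not* modelled; its place is taken by a documented,
parameterised proxy:

- **detected** ⇔ `alt ≥ min_alt_reads` in **both** replicates (AND rule)
  **and** mean replicate VAF ≥ `vaf_floor_pct`;
- reported VAF = unweighted arithmetic mean of the two replicate VAFs.

Defaults: `min_alt_reads = 3`, `vaf_floor_pct = 0.01` (%). At ~3900×
coverage the AND rule implies an effective detection floor of roughly
3/3900 ≈ 0.08% per replicate; the 0.01% floor is the assay's nominal
sensitivity and only binds at much higher coverage. The rule is monotone in
read support and symmetric in the replicates (both property-tested). The
unweighted mean was chosen as the simplest symmetric combiner; an
inverse-variance weighting would differ negligibly at the near-equal totals
the assay produces.

CHIP annotation uses the conventional 2% VAF threshold.

## 2. Trajectory classification

One trajectory per (individual, mutation). Classification contract:

- `n_detected ∈ {1, 2}` → **event**; `n_detected ≥ 3` → traceable, then
  **growing** (`Δ ≥ +0.5` pp), **shrinking** (`Δ ≤ −0.5` pp) or **static**
  (`|Δ| < 0.5` pp), where `Δ` = final − first *detected* VAF. The boundary
  is inclusive: `Δ = 0.5` exactly is growing.
- First/final refer to detected timepoints only. The VAF is undefined when
  the clone is below the calling threshold, so undetected visits are gaps,
  not zeros; intermediate points never affect the class.
- **late-appearing**: an event whose latest detection is the individual's
  final sampled visit at VAF ≥ 2%.
- **disappeared**: last detection precedes the individual's own final
  sampled visit (their visit schedule, not the study's).

Dominant selection takes, among the individual's traceable trajectories,
the one with the largest VAF at any timepoint. Ties (possible with rounded
inputs) break by larger final detected VAF, then lexicographic
(gene, protein-change) — making the choice deterministic and stable under
input reordering; the underlying data gives no principled ordering, so the
tie-break is purely a reproducibility device. A shrinking dominant
trajectory excludes the individual from growth analyses (shrinkage is
plausibly driven by competition from undetected clones, so its slope does
not measure intrinsic fitness); the sensitivity analysis retains them.

## 3. Growth model

Response: `ln VAF`. For a clone at constant proportionate growth, `ln VAF`
is exactly linear in time and one per-individual parameter captures the
rate; the proportionate annual rate is `100·(exp(slope) − 1)` %. (A raw-VAF
response is available behind `response_scale="raw"` for comparison; log is
the default because only the log scale makes a constant percentage rate a
single linear coefficient.)

Model: `ln VAF ~ age` with correlated random intercept and random slope per
individual, fitted by REML (statsmodels `MixedLM`). Numerical choices:

- Age is centred and internally expressed in decades so the random-slope
  and random-intercept variances are of comparable magnitude; reported
  slopes are rescaled to per-year.
- Per-individual slopes are fixed effect + predicted random effect (BLUP).
- If the estimated residual variance is numerically zero
  (`scale < 1e-8 · var(y)`), BLUPs are computed as exact per-group OLS —
  the analytic limit — rather than through the near-singular marginal
  covariance.
- A singular or non-convergent correlated fit falls back to uncorrelated
  (diagonal) random effects; `force_diagonal=True` requests that structure
  directly. Persistent failure raises a convergence error with diagnostics.
- A single-individual input is unidentifiable as a mixed model and
  degenerates to that individual's OLS line.

Partial pooling: the slope BLUP is pulled from the individual's OLS slope
toward the fixed slope. Component-wise "betweenness" is exact for scalar
shrinkage (balanced design, uncorrelated random effects) and holds to
~1e-3 on the log-slope scale generally — with correlated random effects the
2-D BLUP borrows intercept information and may overshoot the interval
slightly; the tests encode exactly this distinction.

Cross-sectional fits: OLS of `ln VAF` on age over carriers (largest clone
per carrier), and maximum-likelihood logistic regression of carrier status
on age. Perfect separation and single-class outcomes raise a dedicated
error rather than returning runaway coefficients.

## 4. Clinical derivations and associations

Derived quantities (units mmol/L, mU/L, mmHg):

- HOMA-IR = insulin × glucose / 22.5
- Friedewald LDL-C = total-C − TG/2.2 − HDL-C, set missing when
  TG > 4.5 mmol/L (the equation's standard validity bound)
- non-HDL-C = total-C − HDL-C
- hypertension ⇔ SBP ≥ 140 ∨ DBP ≥ 90 ∨ antihypertensive medication
- diabetes ⇔ glucose ≥ 7.0 ∨ anti-diabetes medication

Covariates are averaged per individual over the **first three follow-up
visits** (the first three scheduled post-baseline timepoints present in the
data; baseline excluded; missed visits skipped, so the mean is over the
visits attended).

Association: Spearman rho with average ranks for ties, two-sided p.
For n ≤ 8 pairs the p-value is an exact permutation p over all n!
pairings (the t approximation is unusable there); larger n uses the
standard asymptotic p. The primary family (BMI, glucose, insulin, HOMA-IR,
total-C, HDL-C, LDL-C, CRP, SBP, DBP; m = 10) is Bonferroni-corrected with
`p_bonf = min(1, m·p)`; triglycerides and non-HDL-C are secondary,
explicitly unadjusted. Zero-variance covariates report NaN rather than a
spurious rho.

## 5. Synthetic cohort generator

The generator states a world with the structure the analysis assumes:

| parameter | default | rationale |
|---|---|---|
| n_individuals | 40 | longitudinal carrier-cohort size |
| timepoints | 0/2/10/15/20 y | examination schedule |
| dropout_pattern | 40/38/40/38/24 | per-visit retention counts (probabilities accepted for other cohort sizes) |
| coverage_mean | 3891 | mean reads per replicate (2840 for cross-sectional runs) |
| growth_log_mean | ln(1.07) | mean per-year log-VAF slope ⇒ ~7%/yr proportionate growth |
| growth_log_sd | 0.06 | spreads rates over roughly −4%…+24%/yr across a ~35-draw cohort; only a mean and range are known, so a Gaussian on the log-slope is a stand-in |
| baseline_vaf_log_mean/sd | ln(1%) / 1.2 | log-normal baseline VAFs spanning ~0.05–20%, clipped to [0.01, 50]% |
| vaf ceiling | 50% | heterozygous bound |
| carrier_prevalence_at_mean_age | 0.206 | cross-sectional carrier fraction |
| prevalence_age_log_odds | 0.05/yr | rising prevalence with age; implies a carrier/non-carrier age gap of ~4 y over a 37–70 age range |
| multi_clone_prob | 0.20 | fraction of carriers with >1 clone; within-carrier clones independent |
| hdl_growth_spearman_target | −0.68 | rank coupling of HDL-C to the dominant true slope |
| clinical panel | obesity-cohort means/SDs | normal marginals; insulin, TG, CRP log-normal (right-skewed); within-person visit noise at 10% of the between-person SD |

Mechanics worth knowing:

- True VAF follows `min(50, vaf0·exp(slope·t))`; reads are
  `total ~ Poisson(coverage)`, `alt ~ Binomial(total, VAF/100)` per
  replicate. `noiseless=True` replaces both with deterministic rounding —
  used by exact-recovery tests.
- **Prevalence calibration**: the logistic intercept is Newton-calibrated
  so the *cohort-wide marginal* prevalence equals the target (a printed
  carrier fraction is a marginal quantity). With a zero age slope this
  reduces exactly to calibration at the mean age.
- **HDL copula**: the dominant true clone slope per individual (the clone
  attaining the highest true VAF at any attended visit) is rank-transformed
  to normal scores; HDL-C's latent normal is drawn with Pearson correlation
  `ρ = 2·sin(π·ρ_s/6)` against those scores, which yields the requested
  Spearman `ρ_s` in expectation regardless of the max-selection-distorted
  slope distribution. Only HDL-C is coupled; the other panel variables are
  mutually independent, which real metabolic panels are not — a green
  association test therefore establishes correct null behaviour and correct
  coupled-signal recovery, not realistic covariate collinearity.
- Determinism: one `numpy` Generator seeded from `CohortConfig.seed` drives
  everything; identical config ⇒ byte-identical TSVs.

What the generator does **not** emulate: sequencing error (alt reads in
non-carriers are zero, so specificity is untestable here), UMI/probe-level
bias, clone competition or non-constant growth, within-individual clone
dependence, and covariate cross-correlations. Conclusions from green tests
are correspondingly about the statistical machinery, not assay chemistry.

## 6. Known limitations and behaviour under selection

The analysis pipeline's own selection steps — dominant-clone choice among
multi-clone carriers and exclusion of shrinking dominants — raise the mean
growth rate of the analysed subset above the clone-level mean of the world
that generated it (by roughly +1 pp/yr at the default settings; the
recovery tests and acceptance script quantify this). The mixed-model
estimate tracks the post-selection truth without additional bias; tests
verify unbiasedness and 90–99% CI coverage in a selection-free design.

Friedewald LDL-C computed from *group mean* lipids differs in the second
decimal from the mean of per-subject LDL-C (nonlinearity of missingness
and rounding), which is visible when reproducing reported summary tables.

Cross-sectional and longitudinal designs share one config type; fields that
are meaningless in a design (e.g. growth parameters in a single-visit
cohort) are simply unused there.
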