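# Methods

`hdpsim` asks a design question rather than a data question: when treatment
choice is driven almost deterministically by a clinical indication that a
disease registry measures well and administrative claims measure badly, how
close do different propensity-score (PS) designs get to a known benchmark
treatment effect? The package answers it by simulation, because only in a
simulation is the true effect known exactly.

## The data-generating model

One scenario describes a two-arm surgical cohort — an analog of carotid
stenting (CAS, "exposed") vs. endarterectomy (CEA, "unexposed") in the era
when stenting was indicated only for high-surgical-risk patients.

**Latent conditions.** Each patient carries independent Bernoulli indicators
`Z_j` for ~11 latent clinical conditions (a high-surgical-risk composite,
symptomatic carotid disease, contralateral occlusion, heart failure, coronary
artery disease, myocardial infarction, diabetes, COPD, cancer, NYHA III/IV
class, hyperlipidemia).

**Treatment.** `T ~ Bernoulli(expit(a0 + Σ b_j Z_j))`. The high-surgical-risk
coefficient (b = 3.76) and intercept (a0 = −4.19) were calibrated once, by
Monte-Carlo root finding, so that at the default n = 5254 the exposed
fraction is ≈ 38% and the high-surgical-risk prevalence is ≈ 96.7% among
exposed vs ≈ 44.5% among unexposed — the signature of confounding by
indication. The true per-patient propensity is stored in the truth record.

**Outcome.** All-cause death from a Weibull proportional-hazards model
(default shape 1, i.e. exponential):
`h_i(t) = shape * t^(shape-1) * λ0 · exp(Σ g_j Z_ij + β_true · T_i + u_hospital)`,
with administrative censoring at 1460 days and a lognormal hospital frailty
(SD 0.2 on the log scale; physicians are nested in hospitals and patients
assigned uniformly to physicians). The exponential default is deliberate: it
is the simplest process whose Cox partial-likelihood HR equals the generating
HR, so `β_true` (default 0, benchmark HR 1.0) is an exact target, not an
approximation. λ0 = 5.49e-5/day was calibrated to put 3-year mortality near
26%/17% by arm; because the true HR is 1, the entire arm contrast — crude
HR ≈ 1.6–1.8 — is confounding.

**Registry.** Each condition maps to one registry dimension (medical history,
symptomatic status, imaging, medications, high surgical risk). The registry
records `Z_j` with a capture probability (1.0 by default — registries are the
gold standard here), then values are set missing, MCAR by default, at
configurable per-variable rates (defaults 17.6% for the NYHA analog, 33.2%
for hyperlipidemia; a MAR-on-exposure option exists for sensitivity runs).

**Claims.** For each condition and each of six claims dimensions (inpatient/
outpatient diagnoses and procedures, carrier, nursing home), a dedicated code
fires with a per-dimension sensitivity when the condition is present, with a
zero-truncated Poisson occurrence count. There are no false positives on
condition codes; instead each dimension carries 40 independent noise codes
with prevalences drawn log-uniform on [0.01, 0.3], which is what makes the
hdPS prevalence filter and ranking non-trivial. The structural choice that
drives everything downstream: the high-surgical-risk composite has claims
sensitivity ≤ 0.3 in every dimension (anatomy-type eligibility criteria are
poorly coded), while ordinary comorbidities (heart failure, CAD, MI, ...)
have sensitivities 0.7–0.9. Claims-only adjustment can therefore remove part
— but only part — of the confounding.

**What the generator does not emulate.** Real linked cohorts have correlated
comorbidities, calendar structure, code semantics, informative censoring
(loss of eligibility), and demographics entangled with risk (age > 80 is
itself a high-risk criterion; here demographics are independent noise used as
the forced covariates). Passing tests therefore demonstrate that the methods
behave correctly under the stated mechanism, not that any particular
real-data estimate is right.

## The hdPS covariate engine

Per data dimension: (1) codes with patient-level prevalence ≥ 1% are
candidates, ordered by deviation from ubiquity min(p, 1−p), top 200 kept;
(2) each code expands into up to three recurrence covariates — count ≥ 1,
count ≥ median of positive counts, count ≥ 75th percentile of positive counts
(linear-interpolation quantiles; duplicate indicators collapse to the lowest
level); (3) every covariate is ranked by the magnitude of confounding it
could induce alone, the Bross bias multiplier

    BM = (PC1·(RR−1) + 1) / (PC0·(RR−1) + 1),

with PC1/PC0 its prevalence among exposed/unexposed and RR its crude risk
ratio for any-death during follow-up; covariates are sorted by |log BM| and
the top k (default 500) enter the PS model. Numerical choices: when any cell
of the covariate × outcome table is zero, +0.1 is added to all four cells so
RR stays finite; RR is clamped to max(RR, 1/RR) so protective proxies rank
symmetrically (switchable); ranking ties break lexicographically on
(dimension, code, level) for determinism. Registry variables enter as their
own dimensions with counts in {0,1} (recurrence collapses to "once");
continuous registry values are binarized at the cohort median.

## Propensity models and discrimination

Seven variants: investigator-specified × {claims, registry, both} and hdPS ×
{claims, registry, both, both-minus-risk}, the last removing the registry
high-surgical-risk dimension before ranking and selection — the sensitivity
model probing what that single dimension is worth. All models force age
group, sex, race and procedure year. The synthetic investigator lists mirror
how real ones are built: all named registry variables, and the standard
comorbidity codes (the generator's condition codes, never the noise codes).

Scores come from logistic regression with a tiny ridge penalty (λ = 1e-6),
escalated through {1e-3, 1e-1} only if the optimizer fails — near-
deterministic indication makes quasi-separation a live concern. Scores are
clipped to (1e-12, 1−1e-12). Discrimination is the exposed-vs-unexposed
concordance probability (c-statistic), computed by an O(n log n) midrank
path; an O(n1·n0) pairwise path is kept as the in-package oracle and the two
are tested to agree.

## Adjustment approaches

* **1:1 matching** — greedy nearest-neighbor on the logit PS without
  replacement, caliper 0.2 × SD(logit PS). The caliper phrase "0.2 times the
  logit of the propensity score" is dimensionally incoherent read literally;
  the SD reading is the standard one, and `caliper_absolute=True` provides
  the literal alternative. Determinism is pinned: exposed processed in
  descending PS order (ties by index), candidate-distance ties to the smaller
  unexposed index. Matched-pair Cox fits cluster on pair id.
* **Quintile adjustment** — cut points at the 20/40/60/80th percentiles of
  the analysis sample's PS (boundary scores go to the lower stratum);
  quintiles enter the Cox model as indicator terms by default
  (`quintiles_as_strata=True` switches to baseline-hazard strata).
* **5% asymmetric trimming** — drop exposed below the 5th percentile of the
  exposed PS distribution and unexposed above the 95th percentile of the
  unexposed distribution; quintiles are recomputed on the retained sample;
  the PS is not re-estimated after trimming by default (flag available).

Balance is reported as standardized mean differences with the pooled-SD
denominator, before and after adjustment.

## Survival estimation

Kaplan–Meier cumulative incidence 1 − S(t) with Greenwood-based log(−log)
confidence limits; Cox proportional hazards with the Efron tie correction and
a cluster-robust sandwich variance aggregated at the hospital level by
default (physician-level and matched-pair clustering are arguments; joint
two-way clustering is out of scope). The Newton stopping rule is tightened
(precision 1e-9) because flat partial likelihoods on tiny samples otherwise
stop several 1e-4 from the maximizer, which matters for oracle tests.

## Missing data

Missing registry values are multiply imputed (m = 5 by default) by drawing
from the observed conditional distribution of each variable within
(exposure × event) cells — adequate for the generator's MCAR mechanism, with
a marginal-distribution fallback (logged) for empty cells and deterministic
`mode_fill` as the single-fill variant. The whole downstream pipeline
(ranking, PS, adjustment, Cox) is re-run within each completed dataset and
log-HRs are pooled by Rubin's rules (T = W + (1 + 1/m)·B, t reference with
Rubin df); averaging the PS across imputations instead is not implemented.
With nothing missing the pooled estimate equals the single-run estimate
exactly, which the tests assert.

## The evaluation grid and replication

`run_grid` shares one imputation set across all cells so that cell
differences reflect the PS design only, isolates per-cell failures as
structured error records, and emits the design-comparison table (one row per
model × adjustment plus crude), per-model c-statistics, top-25 rankings and a
seeds/config-hash manifest. `replicate` repeats the grid on independent
cohorts (seeds base+i) and summarizes per-cell mean log-HR bias, empirical
SE, RMSE and benchmark coverage, flagging cells that fail in > 20% of
replicates.

## Problem sizes used

Single-run analyses use the spec-level defaults: n = 5254, m = 5, hdPS
k = 500. Replication runs (the acceptance tests and
`analysis/05_replicate_grid.py`) use 50 replicates with quintile adjustment,
a single mode-fill imputation and k = 100: missingness touches only two
minor registry variables, so multiple imputation cannot change the bias
ordering; and the synthetic code universe (~330 codes) is an order of
magnitude smaller than the claims universes k = 500 was designed for, so
k = 100 already includes every informative covariate plus a noise margin.
These are the package's own desk-scale choices and are all exposed as
parameters.

## Known limitations

* Conditions are independent; real comorbidity clusters would make claims
  proxies collectively more informative than they are here.
* The ranking outcome is any-death-during-follow-up, ignoring censoring
  time; with near-uniform administrative censoring this is a monotone
  transform of the event rate, but with staggered entry it would not be.
* Two-way (hospital + physician) clustered variance is not implemented;
  choose one level.
* The conditional-draw imputer is not a chained-equations engine; it is
  exact under MCAR and serviceable under the shipped MAR option, no more.
* Greedy matching is deliberately not optimal matching; determinism and
  auditability win here.
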