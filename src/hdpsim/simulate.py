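"""Synthetic linked claims+registry cohort generator.

Generates, from a :class:`~hdpsim.config.ScenarioConfig`, the three tables the
analysis pipeline consumes plus a ground-truth record:

* ``cohort``   — one row per patient: exposure (1 = stenting analog), follow-up
  days, death indicator, hospital/physician cluster ids, and demographics used
  as investigator-forced covariates.
* ``claims``   — long format (patient_id, dimension, code, count); a row exists
  only when the code fired at least once during the baseline year.
* ``registry`` — long format (patient_id, dimension, variable, value, missing),
  dense over patients x variables.
* ``truth``    — the latent condition indicators, true propensity scores and
  generating parameters, for evaluation only (never an input to the pipeline).

The data-generating process: latent conditions Z_j ~ Bernoulli(prevalence),
independent across conditions and patients; treatment T ~ Bernoulli(expit(a0 +
sum b_j Z_j)); death time from a Weibull (default exponential) proportional-
hazards model with rate baseline_hazard * exp(sum g_j Z_j + true_log_hr * T +
hospital frailty), administratively censored at admin_censor_time. Registry
variables are the conditions passed through a capture probability (false
negatives only) and then missingness; claims codes fire per condition per
dimension with the configured sensitivity and carry zero-truncated Poisson
counts, alongside independent noise codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CLAIMS_DIMENSIONS, ScenarioConfig

AGE_GROUPS = ("65-69", "70-74", "75-79", "80+")
_AGE_PROBS = (0.24, 0.30, 0.26, 0.20)


@dataclass
class TruthRecord:
    """Ground truth of one generated cohort, for evaluation only."""

    true_log_hr: float
    conditions: pd.DataFrame  # patient_id x condition indicators
    true_propensity: np.ndarray  # strictly inside (0,1)
    hsr_prevalence_exposed: float
    hsr_prevalence_unexposed: float
    condition_codes: dict[str, dict[str, str]] = field(default_factory=dict)
    # condition name -> {claims dimension -> code token}

    def to_json_dict(self) -> dict:
        return {
            "true_log_hr": self.true_log_hr,
            "hsr_prevalence_exposed": self.hsr_prevalence_exposed,
            "hsr_prevalence_unexposed": self.hsr_prevalence_unexposed,
            "condition_codes": self.condition_codes,
            "condition_prevalence": self.conditions.drop(columns="patient_id")
            .mean()
            .to_dict(),
        }


def _zero_truncated_poisson(rng: np.random.Generator, mu: float, size: int) -> np.ndarray:
    """Draw zero-truncated Poisson(mu) counts by redrawing zeros."""
    out = rng.poisson(mu, size)
    zeros = out == 0
    while zeros.any():
        out[zeros] = rng.poisson(mu, int(zeros.sum()))
        zeros = out == 0
    return out


def generate_cohort(
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Generate one linked cohort. Deterministic given ``config`` (incl. seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    patient_id = np.arange(1, n + 1)

    # latent conditions
    names = [c.name for c in config.confounders]
    Z = np.empty((n, len(names)), dtype=np.int8)
    for j, c in enumerate(config.confounders):
        Z[:, j] = rng.random(n) < c.prevalence

    # treatment assignment: logistic on the latent conditions
    b = np.array([c.logit_treatment for c in config.confounders])
    lin = config.treatment_intercept + Z @ b
    propensity = 1.0 / (1.0 + np.exp(-lin))
    propensity = np.clip(propensity, 1e-12, 1 - 1e-12)
    exposure = (rng.random(n) < propensity).astype(np.int8)

    # clustering: physicians nested in hospitals, patients uniform on physicians
    phys_hospital = rng.integers(0, config.n_hospitals, config.n_physicians)
    physician_id = rng.integers(0, config.n_physicians, n)
    hospital_id = phys_hospital[physician_id]
    if config.cluster_frailty_sd > 0:
        log_frailty = rng.normal(0.0, config.cluster_frailty_sd, config.n_hospitals)
    else:
        log_frailty = np.zeros(config.n_hospitals)

    # survival: Weibull PH, default shape 1 (exponential)
    g = np.array([c.log_hazard for c in config.confounders])
    log_rate = (
        np.log(config.baseline_hazard)
        + Z @ g
        + config.true_log_hr * exposure
        + log_frailty[hospital_id]
    )
    rate = np.exp(log_rate)
    p_event = 1.0 - np.exp(-rate * config.admin_censor_time**config.weibull_shape)
    if p_event.max() < 1e-9 or p_event.min() > 1 - 1e-9:
        raise ValueError(
            "degenerate outcome: implied event probability is ~0 or ~1 "
            "for every patient under this configuration"
        )
    # S(t) = exp(-rate * t^shape)  =>  t = (E/rate)^(1/shape), E ~ Exp(1)
    death_time = (rng.exponential(1.0, n) / rate) ** (1.0 / config.weibull_shape)
    event = (death_time <= config.admin_censor_time).astype(np.int8)
    followup = np.minimum(death_time, config.admin_censor_time)
    followup = np.maximum(followup, 1e-6)  # follow-up strictly positive

    cohort = pd.DataFrame(
        {
            "patient_id": patient_id,
            "exposure": exposure,
            "followup_days": followup,
            "event": event,
            "hospital_id": hospital_id,
            "physician_id": physician_id,
            "age_group": rng.choice(AGE_GROUPS, n, p=_AGE_PROBS),
            "sex_male": (rng.random(n) < 0.60).astype(np.int8),
            "race_white": (rng.random(n) < 0.93).astype(np.int8),
            "proc_year": rng.integers(2005, 2009, n),
        }
    )

    registry = _build_registry(config, rng, patient_id, Z, exposure)
    claims, condition_codes = _build_claims(config, rng, patient_id, Z)

    conditions = pd.DataFrame(Z, columns=names)
    conditions.insert(0, "patient_id", patient_id)
    hsr = "high_surgical_risk"
    if hsr in names:
        h = conditions[hsr].to_numpy()
        prev1 = float(h[exposure == 1].mean()) if (exposure == 1).any() else float("nan")
        prev0 = float(h[exposure == 0].mean()) if (exposure == 0).any() else float("nan")
    else:
        prev1 = prev0 = float("nan")
    truth = TruthRecord(
        true_log_hr=config.true_log_hr,
        conditions=conditions,
        true_propensity=propensity,
        hsr_prevalence_exposed=prev1,
        hsr_prevalence_unexposed=prev0,
        condition_codes=condition_codes,
    )
    return cohort, claims, registry, truth


def _build_registry(
    config: ScenarioConfig,
    rng: np.random.Generator,
    patient_id: np.ndarray,
    Z: np.ndarray,
    exposure: np.ndarray,
) -> pd.DataFrame:
    frames = []
    for j, c in enumerate(config.confounders):
        captured = Z[:, j].astype(np.int8)
        if c.registry_capture < 1.0:
            keep = rng.random(len(patient_id)) < c.registry_capture
            captured = (captured & keep).astype(np.int8)
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": patient_id,
                    "dimension": c.registry_dimension,
                    "variable": c.name,
                    "value": captured.astype(float),
                    "missing": False,
                }
            )
        )
    registry = pd.concat(frames, ignore_index=True)
    if config.missingness_rates:
        registry = apply_missingness(
            registry,
            config.missingness_rates,
            seed=int(rng.integers(0, 2**31 - 1)),
            mechanism=config.missingness_mechanism,
            exposure=pd.Series(exposure, index=patient_id),
            mar_log_odds=config.mar_log_odds,
        )
    return registry


def _build_claims(
    config: ScenarioConfig,
    rng: np.random.Generator,
    patient_id: np.ndarray,
    Z: np.ndarray,
) -> tuple[pd.DataFrame, dict[str, dict[str, str]]]:
    n = len(patient_id)
    rows_pid, rows_cnt = [], []
    block_dim, block_code, block_len = [], [], []
    condition_codes: dict[str, dict[str, str]] = {}

    def _emit(dim: str, token: str, fired: np.ndarray, mean_count: float) -> None:
        k = int(fired.sum())
        if k == 0:
            return
        rows_pid.append(patient_id[fired])
        rows_cnt.append(_zero_truncated_poisson(rng, mean_count, k))
        block_dim.append(dim)
        block_code.append(token)
        block_len.append(k)

    code_idx = 0
    for j, c in enumerate(config.confounders):
        condition_codes[c.name] = {}
        affected = Z[:, j] == 1
        for dim in CLAIMS_DIMENSIONS:
            sens = c.claims_sensitivity.get(dim, 0.0)
            code_idx += 1
            if sens <= 0.0:
                continue
            token = f"DX{code_idx:04d}"
            condition_codes[c.name][dim] = token
            _emit(dim, token, affected & (rng.random(n) < sens), c.claims_mean_count)

    # independent noise codes, log-uniform prevalence per code
    lo, hi = config.noise_code_prevalence
    for dim in CLAIMS_DIMENSIONS:
        if config.n_noise_codes == 0:
            continue
        prevs = np.exp(rng.uniform(np.log(lo), np.log(hi), config.n_noise_codes))
        for i, p in enumerate(prevs):
            token = f"NZ{dim[:4].upper()}{i:03d}"
            _emit(dim, token, rng.random(n) < p, 1.6)

    if rows_pid:
        lens = np.array(block_len)
        claims = pd.DataFrame(
            {
                "patient_id": np.concatenate(rows_pid),
                "dimension": np.repeat(np.array(block_dim, dtype=object), lens),
                "code": np.repeat(np.array(block_code, dtype=object), lens),
                "count": np.concatenate(rows_cnt).astype(np.int64),
            }
        )
        claims = claims.sort_values(
            ["patient_id", "dimension", "code"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        claims = pd.DataFrame(
            {"patient_id": [], "dimension": [], "code": [], "count": []}
        ).astype({"patient_id": np.int64, "count": np.int64})
    return claims, condition_codes


def apply_missingness(
    registry: pd.DataFrame,
    rates: dict[str, float],
    seed: int,
    mechanism: str = "mcar",
    exposure: pd.Series | None = None,
    mar_log_odds: float = 1.0,
) -> pd.DataFrame:
    """Set registry values missing, MCAR by default.

    ``rates`` maps registry variable names to marginal missingness
    probabilities. Under ``mechanism="mar_exposure"`` the missingness log-odds
    is shifted by ``mar_log_odds`` for exposed patients (``exposure`` indexed
    by patient_id required); the marginal rate then applies to the unexposed.
    Row count and order are unchanged; untargeted variables are untouched.
    """
    known = set(registry["variable"].unique())
    unknown = sorted(set(rates) - known)
    if unknown:
        raise KeyError(
            f"unknown registry variable(s) {unknown}; known variables: {sorted(known)}"
        )
    if mechanism not in ("mcar", "mar_exposure"):
        raise ValueError("mechanism must be 'mcar' or 'mar_exposure'")
    if mechanism == "mar_exposure" and exposure is None:
        raise ValueError("mar_exposure mechanism requires the exposure series")

    rng = np.random.default_rng(seed)
    out = registry.copy()
    for var in sorted(rates):
        rate = rates[var]
        mask = (out["variable"] == var).to_numpy()
        m = int(mask.sum())
        if m == 0 or rate == 0.0:
            continue
        if mechanism == "mcar":
            miss = rng.random(m) < rate
        else:
            rate = min(rate, 1 - 1e-12)
            base_logit = np.log(rate / (1 - rate))
            exp_flags = exposure.reindex(out.loc[mask, "patient_id"]).to_numpy()
            p = 1.0 / (1.0 + np.exp(-(base_logit + mar_log_odds * exp_flags)))
            miss = rng.random(m) < p
        idx = out.index[mask][miss]
        out.loc[idx, "missing"] = True
        out.loc[idx, "value"] = np.nan
    return out


def write_tables(
    out_dir,
    cohort: pd.DataFrame,
    claims: pd.DataFrame,
    registry: pd.DataFrame,
    truth: TruthRecord | None = None,
    fmt: str = "csv",
) -> None:
    """Write the generated tables (and truth.json) to a directory."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {"cohort": cohort, "claims": claims, "registry": registry}
    for name, df in tables.items():
        if fmt == "parquet":
            df.to_parquet(out / f"{name}.parquet", index=False)
        else:
            df.to_csv(out / f"{name}.csv", index=False)
    if truth is not None:
        (out / "truth.json").write_text(json.dumps(truth.to_json_dict(), indent=2))
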