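"""Survival estimation: Kaplan-Meier cumulative mortality and Cox hazard
ratios with cluster-robust (sandwich) variance.

Cox fits use the Efron approximation for tied event times and, by default, a
sandwich variance aggregated at the hospital level (physician- or matched-
pair-level clustering are one argument away). Quintile designs enter as
indicator covariates by default; a flag switches them to baseline-hazard
strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError


@dataclass
class KmEstimate:
    horizon: float
    cumulative_incidence: float
    ci95: tuple[float, float]
    at_risk: pd.DataFrame  # time, n at risk
    degenerate_ci: bool = False


@dataclass
class HazardEstimate:
    hr: float
    ci95: tuple[float, float]
    se_log_hr: float  # robust
    n_exposed: int
    n_unexposed: int
    events_exposed: int
    events_unexposed: int
    adjustment: str = "crude"  # crude | matched | quintiles | quintiles_trimmed
    model_id: str = "crude"
    log_hr: float = field(init=False)

    def __post_init__(self) -> None:
        self.log_hr = float(np.log(self.hr))
        if not (self.ci95[0] <= self.hr <= self.ci95[1]):
            raise ValueError("CI must contain the point estimate")


def km_risk(
    times: np.ndarray,
    events: np.ndarray,
    horizon: float,
    confidence: float = 0.95,
) -> KmEstimate:
    """Product-limit cumulative incidence 1 - S(horizon) with Greenwood
    exponential (log(-log)) confidence limits."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter(alpha=1.0 - confidence)
    kmf.fit(times, events)
    surv = float(kmf.predict(horizon))
    ci = kmf.confidence_interval_survival_function_
    # step-function value at the horizon
    idx = ci.index.searchsorted(horizon, side="right") - 1
    degenerate = horizon < times.min() or events.sum() == 0
    if idx < 0:
        surv, lo_s, hi_s = 1.0, 1.0, 1.0
    else:
        row = ci.iloc[idx]
        lo_s, hi_s = float(row.iloc[0]), float(row.iloc[1])
        if np.isnan(lo_s) or np.isnan(hi_s):
            lo_s, hi_s = surv, surv
            degenerate = True
    inc = 1.0 - surv
    ci_inc = (1.0 - hi_s, 1.0 - lo_s)
    at_risk = pd.DataFrame(
        {
            "time": kmf.event_table.index.to_numpy(dtype=float),
            "at_risk": kmf.event_table["at_risk"].to_numpy(),
        }
    )
    return KmEstimate(horizon, inc, ci_inc, at_risk, degenerate_ci=bool(degenerate))


def fit_cox(
    df: pd.DataFrame,
    terms: list[str],
    duration_col: str = "followup_days",
    event_col: str = "event",
    cluster_col: str | None = "hospital_id",
    strata: list[str] | None = None,
    exposure_col: str = "exposure",
    adjustment: str = "crude",
    model_id: str = "crude",
    robust: bool = True,
) -> HazardEstimate:
    """Cox PH fit (Efron ties); returns the exposure hazard ratio.

    ``terms`` are the covariate columns (must include the exposure).
    ``cluster_col`` drives the sandwich aggregation (hospital by default; pass
    the pair id for matched designs, physician_id for physician-level, or None
    for the unclustered robust sandwich).
    """
    if exposure_col not in terms:
        raise ValueError("terms must include the exposure column")
    for arm in (0, 1):
        sub = df[df[exposure_col] == arm]
        if len(sub) == 0 or sub[event_col].sum() < 1:
            raise ValueError(f"need at least one event in exposure arm {arm}")
    cols = [duration_col, event_col] + list(terms)
    if cluster_col:
        cols.append(cluster_col)
    if strata:
        cols.extend(strata)
    data = df[list(dict.fromkeys(cols))].copy()

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                data,
                duration_col=duration_col,
                event_col=event_col,
                cluster_col=cluster_col,
                strata=strata,
                robust=robust or cluster_col is not None,
                # tight Newton stopping rule: flat partial likelihoods on tiny
                # samples otherwise stop several 1e-4 from the maximizer
                fit_options={"precision": 1e-9, "max_steps": 500},
            )
    except ConvergenceError as err:
        msg = str(err)
        if "complete separation" in msg or "monotone" in msg.lower():
            raise RuntimeError(
                "monotone partial likelihood; consider penalization or a coarser design"
            ) from err
        raise RuntimeError(f"Cox fit failed to converge: {msg}") from err

    log_hr = float(cph.params_[exposure_col])
    se = float(cph.standard_errors_[exposure_col])
    z = 1.959963984540054
    ci = (float(np.exp(log_hr - z * se)), float(np.exp(log_hr + z * se)))
    e = df[exposure_col].astype(bool)
    return HazardEstimate(
        hr=float(np.exp(log_hr)),
        ci95=ci,
        se_log_hr=se,
        n_exposed=int(e.sum()),
        n_unexposed=int((~e).sum()),
        events_exposed=int(df.loc[e, event_col].sum()),
        events_unexposed=int(df.loc[~e, event_col].sum()),
        adjustment=adjustment,
        model_id=model_id,
    )
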