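"""Multiple imputation of missing registry covariates and Rubin pooling.

Missing binary/categorical registry values are filled by drawing from the
observed conditional distribution of the variable within cells of
(exposure x event) — a deliberately simple conditional-draw engine adequate
for missingness that is (nearly) completely at random; ``mode_fill`` is the
deterministic single-fill fallback. Hazard estimates computed within each
completed dataset are combined by Rubin's rules: pooled log-HR = mean,
total variance T = W + (1 + 1/m) B with the usual t reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ImputationSet:
    m: int
    tables: list[pd.DataFrame]  # completed registry tables, no missing values
    method: str
    seed: int


@dataclass
class PooledEstimate:
    log_hr: float
    hr: float
    ci95: tuple[float, float]
    se_log_hr: float
    within_variance: float
    between_variance: float
    total_variance: float
    df: float
    m: int


def impute_registry(
    registry: pd.DataFrame,
    cohort: pd.DataFrame,
    m: int = 5,
    method: str = "draw_from_conditional",
    seed: int = 0,
) -> ImputationSet:
    """Produce ``m`` completed registry tables. Deterministic given seed."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if method not in ("draw_from_conditional", "mode_fill"):
        raise ValueError("method must be 'draw_from_conditional' or 'mode_fill'")
    miss_mask = registry["missing"].to_numpy(dtype=bool)
    if not miss_mask.any():
        return ImputationSet(m, [registry.copy() for _ in range(m)], method, seed)

    cell = cohort.set_index("patient_id")
    cell_of_patient = (cell["exposure"].astype(int) * 2 + cell["event"].astype(int)).to_dict()
    rng = np.random.default_rng(seed)

    tables = []
    for _ in range(m):
        out = registry.copy()
        for var, grp in registry.groupby("variable", sort=True):
            gm = grp["missing"].to_numpy(dtype=bool)
            if not gm.any():
                continue
            observed = grp.loc[~gm, "value"]
            pat_cells = grp["patient_id"].map(cell_of_patient)
            marginal_vals, marginal_p = _distribution(observed)
            if marginal_vals is None:
                logger.warning(
                    "variable %r missing for every patient; nothing observed to "
                    "draw from — imputing 0", var
                )
                marginal_vals, marginal_p = np.array([0.0]), np.array([1.0])
            fills = np.empty(int(gm.sum()))
            miss_rows = np.flatnonzero(gm)
            miss_cells = pat_cells.to_numpy()[miss_rows]
            for c in np.unique(miss_cells):
                in_cell = observed[(pat_cells[~gm] == c).to_numpy()]
                vals, p = _distribution(in_cell)
                if vals is None:
                    logger.warning(
                        "variable %r has no observed values in cell %s; "
                        "falling back to the marginal distribution", var, c
                    )
                    vals, p = marginal_vals, marginal_p
                sel = miss_cells == c
                if method == "mode_fill":
                    fills[sel] = vals[np.argmax(p)]
                else:
                    fills[sel] = rng.choice(vals, size=int(sel.sum()), p=p)
            idx = grp.index[miss_rows]
            out.loc[idx, "value"] = fills
            out.loc[idx, "missing"] = False
        assert not out["missing"].any()
        tables.append(out)
    return ImputationSet(m, tables, method, seed)


def _distribution(values: pd.Series) -> tuple[np.ndarray | None, np.ndarray | None]:
    values = values.dropna()
    if len(values) == 0:
        return None, None
    counts = values.value_counts().sort_index()
    return counts.index.to_numpy(dtype=float), (counts / counts.sum()).to_numpy()


def pool_rubin(estimates: list[tuple[float, float]]) -> PooledEstimate:
    """Rubin's rules over per-imputation (log-HR, variance) pairs."""
    if len(estimates) == 0:
        raise ValueError("need at least one estimate to pool")
    q = np.array([e[0] for e in estimates], dtype=float)
    u = np.array([e[1] for e in estimates], dtype=float)
    if np.any(u < 0):
        raise ValueError("variances must be nonnegative")
    m = len(q)
    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1)) if m > 1 else 0.0
    t = w + (1.0 + 1.0 / m) * b
    if b > 0 and m > 1:
        df = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2
        crit = float(stats.t.ppf(0.975, df))
    else:
        df = float("inf")
        crit = float(stats.norm.ppf(0.975))
    se = float(np.sqrt(t))
    return PooledEstimate(
        log_hr=qbar,
        hr=float(np.exp(qbar)),
        ci95=(float(np.exp(qbar - crit * se)), float(np.exp(qbar + crit * se))),
        se_log_hr=se,
        within_variance=w,
        between_variance=b,
        total_variance=t,
        df=df,
        m=m,
    )
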