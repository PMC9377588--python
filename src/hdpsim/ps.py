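"""Propensity score model variants and discrimination diagnostics.

The study design crosses two modeling strategies (investigator-specified
covariate lists vs. automated data-adaptive hdPS selection) with data sources
(claims-only, registry-only, both, and both minus the registry high-surgical-
risk dimension — the hdPS sensitivity model). Every model forces a small set of
pre-specified demographics (age group, sex, race, procedure year).

Scores come from a ridge-penalized logistic regression (tiny penalty, escalated
automatically when quasi-separation stalls convergence — near-deterministic
treatment indication makes separation a live concern here).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from .hdps import RankedCovariateList, pivot_dimension

logger = logging.getLogger(__name__)

SOURCES = ("claims", "registry", "both", "both_minus_risk")
FORCED_DEFAULT = ("age_group", "sex_male", "race_white", "proc_year")

RIDGE_LADDER = (1e-6, 1e-3, 1e-1)


@dataclass
class PsModelSpec:
    strategy: str  # "investigator" | "hdps"
    source: str  # claims | registry | both | both_minus_risk
    k: int = 500  # hdps only
    forced_covariates: tuple[str, ...] = FORCED_DEFAULT

    def __post_init__(self) -> None:
        if self.strategy not in ("investigator", "hdps"):
            raise ValueError("strategy must be 'investigator' or 'hdps'")
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}")
        if self.source == "both_minus_risk" and self.strategy != "hdps":
            raise ValueError("both_minus_risk is only defined for the hdps strategy")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    @property
    def model_id(self) -> str:
        return f"{self.strategy}_{self.source}"


@dataclass
class PsFit:
    scores: np.ndarray  # strictly inside (0,1)
    linear_predictor: np.ndarray
    c_statistic: float
    n_covariates: int
    converged: bool
    ridge_lambda: float = RIDGE_LADDER[0]
    coef: pd.Series | None = None


@dataclass
class InvestigatorLists:
    """Named variable lists an investigator pre-specifies per source.

    ``claims_codes`` maps dimension -> code tokens (entered as presence
    indicators); ``registry_variables`` lists registry variable names.
    """

    claims_codes: dict[str, list[str]] = field(default_factory=dict)
    registry_variables: list[str] = field(default_factory=list)


def investigator_lists_from_truth(truth, registry: pd.DataFrame) -> InvestigatorLists:
    """Derive the shipped investigator lists for a synthetic scenario.

    The investigator is assumed to know the standard comorbidity codes (every
    condition's claims codes) but none of the noise codes, and to specify all
    named registry variables — mirroring how real investigator-specified models
    draw on published code lists and the registry's clinical fields.
    """
    claims_codes: dict[str, list[str]] = {}
    for cond, per_dim in truth.condition_codes.items():
        for dim, code in per_dim.items():
            claims_codes.setdefault(dim, []).append(code)
    for dim in claims_codes:
        claims_codes[dim] = sorted(claims_codes[dim])
    reg_vars = sorted(registry["variable"].unique()) if len(registry) else []
    return InvestigatorLists(claims_codes, reg_vars)


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------

def _forced_design(cohort: pd.DataFrame, forced: tuple[str, ...]) -> pd.DataFrame:
    parts = []
    for col in forced:
        if col not in cohort.columns:
            raise KeyError(f"forced covariate {col!r} not in cohort table")
        s = cohort[col]
        if s.dtype == object or str(s.dtype) == "category" or s.nunique() > 2:
            dummies = pd.get_dummies(s.astype(str), prefix=col, drop_first=True)
            dummies = dummies[sorted(dummies.columns)].astype(np.int8)
            parts.append(dummies)
        else:
            parts.append(s.astype(np.int8).rename(col).to_frame())
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=cohort.index)


def _registry_uses(source: str) -> bool:
    return source in ("registry", "both", "both_minus_risk")


def _claims_uses(source: str) -> bool:
    return source in ("claims", "both", "both_minus_risk")


def assemble_design(
    spec: PsModelSpec,
    cohort: pd.DataFrame,
    claims: pd.DataFrame | None = None,
    registry: pd.DataFrame | None = None,
    ranking: RankedCovariateList | None = None,
    investigator: InvestigatorLists | None = None,
) -> pd.DataFrame:
    """Build the model's design matrix (forced covariates first, deterministic
    column order, no duplicates). For hdps, ``ranking`` must already reflect the
    requested source (including the high-surgical-risk exclusion for
    ``both_minus_risk``); the top ``spec.k`` covariates enter as indicators.
    """
    design = _forced_design(cohort, spec.forced_covariates)
    pid = cohort["patient_id"].to_numpy()

    if spec.strategy == "hdps":
        if ranking is None:
            raise ValueError("hdps strategy requires a ranking")
        cols, names = [], []
        for cov in ranking.covariates[: spec.k]:
            if spec.source == "both_minus_risk" and cov.dimension == "high_surgical_risk":
                raise ValueError(
                    "ranking passed to both_minus_risk still contains "
                    "high_surgical_risk covariates; re-rank with the dimension excluded"
                )
            names.append(cov.label)
            cols.append(cov.indicator)
        if cols:
            hd = pd.DataFrame(
                np.column_stack(cols).astype(np.int8), columns=names, index=design.index
            )
            design = pd.concat([design, hd], axis=1)
    else:
        if investigator is None:
            raise ValueError("investigator strategy requires InvestigatorLists")
        parts = [design]
        if _claims_uses(spec.source):
            if claims is None:
                raise ValueError("claims table required for this source")
            for dim in sorted(investigator.claims_codes):
                wide = pivot_dimension(claims, dim, pid, "claims")
                for code in investigator.claims_codes[dim]:
                    if code in wide.columns:
                        parts.append(
                            (wide[code] >= 1)
                            .astype(np.int8)
                            .rename(f"{dim}:{code}")
                            .reset_index(drop=True)
                            .to_frame()
                        )
        if _registry_uses(spec.source):
            if registry is None:
                raise ValueError("registry table required for this source")
            for dim in sorted(registry["dimension"].unique()):
                wide = pivot_dimension(registry, dim, pid, "registry")
                for var in sorted(wide.columns):
                    if var in investigator.registry_variables:
                        parts.append(
                            wide[var]
                            .astype(np.int8)
                            .rename(f"{dim}:{var}")
                            .reset_index(drop=True)
                            .to_frame()
                        )
        design = pd.concat(parts, axis=1)

    design = design.loc[:, ~design.columns.duplicated()]
    if design.shape[1] == 0:
        raise ValueError("empty design matrix")
    design.index = cohort.index
    return design


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_propensity(design: pd.DataFrame, exposure: np.ndarray) -> PsFit:
    """Ridge-penalized logistic propensity model.

    Starts at a tiny penalty (lambda = 1e-6, i.e. effectively maximum
    likelihood) and escalates through the ladder when the optimizer fails to
    converge — the quasi-separation fallback. Scores are clipped away from
    {0,1} by 1e-12. Deterministic given input.
    """
    y = np.asarray(exposure).astype(int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("exposure has one level")
    if min(np.sum(y == 0), np.sum(y == 1)) < 2:
        raise ValueError("need at least 2 patients per exposure arm")
    X = design.to_numpy(dtype=float)
    n = X.shape[0]

    fit = None
    converged = False
    lam_used = RIDGE_LADDER[-1]
    for lam in RIDGE_LADDER:
        # sklearn's C is per-sample inverse regularization: C = 1/(n*lambda)
        model = LogisticRegression(
            penalty="l2", C=1.0 / (n * lam), solver="lbfgs", max_iter=2000, tol=1e-9
        )
        import warnings
        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            model.fit(X, y)
            bad = any(issubclass(w.category, ConvergenceWarning) for w in caught)
        fit = model
        lam_used = lam
        if not bad and np.isfinite(model.coef_).all():
            converged = True
            break
        logger.info("propensity fit did not converge at lambda=%g; escalating", lam)

    lp = fit.intercept_[0] + X @ fit.coef_[0]
    scores = 1.0 / (1.0 + np.exp(-lp))
    scores = np.clip(scores, 1e-12, 1.0 - 1e-12)
    coef = pd.Series(fit.coef_[0], index=design.columns)
    return PsFit(
        scores=scores,
        linear_predictor=lp,
        c_statistic=c_statistic(scores, y),
        n_covariates=design.shape[1],
        converged=converged,
        ridge_lambda=lam_used,
        coef=coef,
    )


# ---------------------------------------------------------------------------
# discrimination
# ---------------------------------------------------------------------------

def c_statistic(scores: np.ndarray, exposure: np.ndarray, method: str = "rank") -> float:
    """Concordance probability P(score_exposed > score_unexposed) + 0.5 P(tie).

    ``method="rank"`` is the O(n log n) Mann-Whitney path (midranks handle
    ties); ``method="pairwise"`` enumerates all exposed x unexposed pairs.
    Both must agree — the pairwise path exists as the oracle.
    """
    s = np.asarray(scores, dtype=float)
    e = np.asarray(exposure).astype(bool)
    n1, n0 = int(e.sum()), int((~e).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both exposure arms must be non-empty")
    if method == "pairwise":
        s1, s0 = s[e], s[~e]
        gt = np.sum(s1[:, None] > s0[None, :])
        ties = np.sum(s1[:, None] == s0[None, :])
        return float((gt + 0.5 * ties) / (n1 * n0))
    ranks = rankdata(s)  # midranks
    u = ranks[e].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))
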