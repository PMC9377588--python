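"""Automated data-adaptive (high-dimensional) covariate engine.

Implements the three stages of the hdPS algorithm over coded healthcare data:

1. **Empirical identification** — within each data dimension (a source stream
   of codes: inpatient diagnoses, carrier procedures, registry medical history,
   ...), keep codes whose patient-level prevalence meets a floor (default 1%),
   then the ``top_n_codes`` most informative by deviation from ubiquity,
   min(p, 1-p).
2. **Recurrence expansion** — each kept code becomes up to three binary
   covariates: occurred at least once, at least "sporadically" (count >= median
   of the positive counts) and at least "frequently" (count >= 75th percentile
   of the positive counts); duplicate indicator vectors collapse to the lowest
   level.
3. **Prioritization and selection** — each covariate is ranked by the
   magnitude of the confounding bias it could induce on its own, the Bross
   bias multiplier (PC1*(RR-1)+1)/(PC0*(RR-1)+1), where PC1/PC0 are its
   prevalences among exposed/unexposed and RR its crude relative risk for the
   outcome; the top k (default 500) are selected for the propensity model.

Registry variables enter as their own dimensions with counts in {0,1}, so
recurrence expansion collapses to the "once" level; continuous registry
variables are binarized at the cohort median first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RECURRENCE_LEVELS = ("once", "sporadic", "frequent")


@dataclass
class DimensionSpec:
    name: str
    source: str = "claims"  # "claims" | "registry"
    top_n_codes: int = 200
    min_prevalence: float = 0.01

    def __post_init__(self) -> None:
        if self.top_n_codes < 1:
            raise ValueError("top_n_codes must be >= 1")
        if not 0.0 <= self.min_prevalence <= 0.5:
            raise ValueError("min_prevalence must be in [0, 0.5]")
        if self.source not in ("claims", "registry"):
            raise ValueError("source must be 'claims' or 'registry'")


@dataclass
class HdpsCovariate:
    dimension: str
    code: str
    recurrence_level: str  # once | sporadic | frequent
    count_threshold: float
    indicator: np.ndarray  # aligned with the cohort's patient order
    prevalence: float = float("nan")
    pc1: float = float("nan")  # prevalence among exposed
    pc0: float = float("nan")  # prevalence among unexposed
    rr_cd: float = float("nan")  # covariate-outcome relative risk (clamped >= 1)
    bias_multiplier: float = float("nan")
    abs_log_bias: float = float("nan")
    rank: int = -1

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.dimension, self.code, self.recurrence_level)

    @property
    def label(self) -> str:
        return f"{self.dimension}:{self.code}:{self.recurrence_level}"


@dataclass
class RankedCovariateList:
    covariates: list[HdpsCovariate]  # ordered, non-increasing abs_log_bias
    k_selected: int

    def __post_init__(self) -> None:
        if self.k_selected > len(self.covariates):
            raise ValueError("k_selected exceeds list length")

    @property
    def selected(self) -> list[HdpsCovariate]:
        return self.covariates[: self.k_selected]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "dimension": c.dimension,
                "code": c.code,
                "level": c.recurrence_level,
                "count_threshold": c.count_threshold,
                "prevalence": c.prevalence,
                "pc1": c.pc1,
                "pc0": c.pc0,
                "rr_cd": c.rr_cd,
                "bias_multiplier": c.bias_multiplier,
                "abs_log_bias": c.abs_log_bias,
                "rank": c.rank,
                "selected": i < self.k_selected,
            }
            for i, c in enumerate(self.covariates)
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage 1: empirical identification
# ---------------------------------------------------------------------------

def identify_candidates(
    counts_wide: pd.DataFrame, spec: DimensionSpec
) -> list[str]:
    """Candidate codes of one dimension from a patients x codes count matrix.

    Codes with prevalence (fraction of patients with count >= 1) at or above
    ``spec.min_prevalence`` pass the floor; of those, the ``top_n_codes`` with
    the largest min(p, 1-p) are kept, ties broken lexicographically by code.
    """
    if counts_wide.shape[1] == 0:
        logger.warning("dimension %s has no codes; empty candidate list", spec.name)
        return []
    prev = (counts_wide >= 1).mean(axis=0)
    prev = prev[prev >= spec.min_prevalence]
    if prev.empty:
        logger.warning(
            "dimension %s: no code meets min_prevalence=%g", spec.name, spec.min_prevalence
        )
        return []
    dev = np.minimum(prev, 1.0 - prev)
    order = sorted(prev.index, key=lambda c: (-dev[c], c))
    return order[: spec.top_n_codes]


def pivot_dimension(
    table: pd.DataFrame, dimension: str, patient_ids: np.ndarray, source: str = "claims"
) -> pd.DataFrame:
    """Long claims/registry rows of one dimension -> dense patients x codes counts.

    For registry sources the variable column plays the code role and values are
    coerced to {0,1} counts (continuous variables binarized at the cohort
    median; missing treated as 0 — run imputation upstream if that matters).
    """
    sub = table[table["dimension"] == dimension]
    if source == "claims":
        wide = sub.pivot_table(
            index="patient_id", columns="code", values="count", aggfunc="sum", fill_value=0
        )
    else:
        sub = sub.copy()
        vals = pd.to_numeric(sub["value"], errors="coerce")
        out = np.zeros(len(sub))
        for var, grp in vals.groupby(sub["variable"]):
            observed = grp.dropna()
            uniq = set(observed.unique())
            if uniq <= {0.0, 1.0}:
                binarized = grp.fillna(0.0)
            else:  # continuous: split at the cohort median of observed values
                med = float(observed.median())
                binarized = (grp > med).astype(float).where(grp.notna(), 0.0)
            out[sub["variable"].to_numpy() == var] = binarized.to_numpy()
        sub["count"] = out
        wide = sub.pivot_table(
            index="patient_id", columns="variable", values="count",
            aggfunc="max", fill_value=0,
        )
    wide = wide.reindex(patient_ids, fill_value=0)
    wide.columns = [str(c) for c in wide.columns]
    return wide


# ---------------------------------------------------------------------------
# stage 2a: recurrence expansion
# ---------------------------------------------------------------------------

def expand_recurrence(
    dimension: str, code: str, counts: np.ndarray
) -> list[HdpsCovariate]:
    """Expand one code's per-patient counts into recurrence-level covariates.

    Thresholds: once = count >= 1; sporadic = count >= median of positive
    counts; frequent = count >= 75th percentile of positive counts (linear
    interpolation over patients with count >= 1). A level whose indicator
    duplicates a lower level is dropped.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0) or not np.all(np.equal(np.mod(counts, 1), 0)):
        raise ValueError("counts must be nonnegative integers")
    pos = counts[counts >= 1]
    if pos.size == 0:
        raise ValueError(f"code {code!r} has all-zero counts; filter upstream")
    thresholds = {
        "once": 1.0,
        "sporadic": float(np.percentile(pos, 50)),
        "frequent": float(np.percentile(pos, 75)),
    }
    out: list[HdpsCovariate] = []
    seen: list[np.ndarray] = []
    for level in RECURRENCE_LEVELS:
        thr = thresholds[level]
        ind = (counts >= thr).astype(np.int8)
        if any(np.array_equal(ind, s) for s in seen):
            continue
        seen.append(ind)
        out.append(HdpsCovariate(dimension, code, level, thr, ind))
    return out


# ---------------------------------------------------------------------------
# stage 2b: Bross bias-multiplier prioritization
# ---------------------------------------------------------------------------

def bias_multiplier(pc1: float, pc0: float, rr_cd: float) -> float:
    """Bross bias multiplier (PC1*(RR-1)+1)/(PC0*(RR-1)+1)."""
    for name, v in (("pc1", pc1), ("pc0", pc0), ("rr_cd", rr_cd)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")
    if not (0.0 <= pc1 <= 1.0 and 0.0 <= pc0 <= 1.0):
        raise ValueError("pc1 and pc0 must be in [0,1]")
    if rr_cd <= 0:
        raise ValueError("rr_cd must be > 0")
    return (pc1 * (rr_cd - 1.0) + 1.0) / (pc0 * (rr_cd - 1.0) + 1.0)


def crude_risk_ratio(
    covariate: np.ndarray, outcome: np.ndarray, correction: float = 0.1
) -> float:
    """Crude covariate-outcome risk ratio with +`correction` on all four cells
    of the 2x2 table whenever any cell is zero (keeps the ratio finite)."""
    c = np.asarray(covariate, dtype=bool)
    y = np.asarray(outcome, dtype=bool)
    a = float(np.sum(c & y))  # covariate+, outcome+
    b = float(np.sum(c & ~y))
    d = float(np.sum(~c & y))
    e = float(np.sum(~c & ~y))
    if min(a, b, d, e) == 0:
        a, b, d, e = a + correction, b + correction, d + correction, e + correction
    return (a / (a + b)) / (d / (d + e))


def assess_covariate(
    cov: HdpsCovariate,
    exposure: np.ndarray,
    outcome: np.ndarray,
    clamp_protective: bool = True,
) -> HdpsCovariate:
    """Fill prevalence/association fields and the bias multiplier in place.

    The outcome used for prioritization is the binary any-death indicator.
    With ``clamp_protective`` the relative risk is replaced by
    max(RR, 1/RR) before the multiplier, so protective proxies rank
    symmetrically with harmful ones.
    """
    ind = cov.indicator.astype(bool)
    e = np.asarray(exposure, dtype=bool)
    cov.prevalence = float(ind.mean())
    cov.pc1 = float(ind[e].mean()) if e.any() else float("nan")
    cov.pc0 = float(ind[~e].mean()) if (~e).any() else float("nan")
    rr = crude_risk_ratio(ind, outcome)
    if clamp_protective:
        rr = max(rr, 1.0 / rr)
    cov.rr_cd = rr
    cov.bias_multiplier = bias_multiplier(cov.pc1, cov.pc0, rr)
    cov.abs_log_bias = abs(float(np.log(cov.bias_multiplier)))
    return cov


# ---------------------------------------------------------------------------
# stage 3: ranking and selection
# ---------------------------------------------------------------------------

def rank_and_select(
    covariates: list[HdpsCovariate], k: int = 500
) -> RankedCovariateList:
    """Sort by abs_log_bias descending (ties lexicographic on the covariate
    key) and flag the top min(k, len) as selected."""
    if k < 1:
        raise ValueError("k must be >= 1")
    for c in covariates:
        if not np.isfinite(c.abs_log_bias):
            raise ValueError(f"covariate {c.label} lacks a computed abs_log_bias")
    ordered = sorted(covariates, key=lambda c: (-c.abs_log_bias, c.key))
    for i, c in enumerate(ordered):
        c.rank = i + 1
    return RankedCovariateList(ordered, min(k, len(ordered)))


# ---------------------------------------------------------------------------
# end-to-end driver over the generated table schemas
# ---------------------------------------------------------------------------

def default_dimension_specs(
    claims: pd.DataFrame | None,
    registry: pd.DataFrame | None,
    top_n_codes: int = 200,
    min_prevalence: float = 0.01,
) -> list[DimensionSpec]:
    specs = []
    if claims is not None and len(claims):
        for d in sorted(claims["dimension"].unique()):
            specs.append(DimensionSpec(d, "claims", top_n_codes, min_prevalence))
    if registry is not None and len(registry):
        for d in sorted(registry["dimension"].unique()):
            specs.append(DimensionSpec(d, "registry", top_n_codes, min_prevalence))
    return specs


def generate_covariates(
    cohort: pd.DataFrame,
    claims: pd.DataFrame | None = None,
    registry: pd.DataFrame | None = None,
    specs: list[DimensionSpec] | None = None,
) -> list[HdpsCovariate]:
    """Run identification + recurrence expansion over all requested dimensions."""
    if specs is None:
        specs = default_dimension_specs(claims, registry)
    pid = cohort["patient_id"].to_numpy()
    out: list[HdpsCovariate] = []
    for spec in specs:
        table = claims if spec.source == "claims" else registry
        if table is None or not len(table):
            logger.warning("dimension %s: source table empty", spec.name)
            continue
        wide = pivot_dimension(table, spec.name, pid, spec.source)
        candidates = identify_candidates(wide, spec)
        for code in candidates:
            counts = wide[code].to_numpy()
            out.extend(expand_recurrence(spec.name, code, counts.astype(np.int64)))
    return out


def rank_covariates(
    cohort: pd.DataFrame,
    claims: pd.DataFrame | None = None,
    registry: pd.DataFrame | None = None,
    k: int = 500,
    specs: list[DimensionSpec] | None = None,
    exclude_dimensions: tuple[str, ...] = (),
    clamp_protective: bool = True,
) -> RankedCovariateList:
    """Full hdPS covariate pipeline: identify, expand, prioritize, select.

    ``exclude_dimensions`` drops whole dimensions (e.g. the registry
    high-surgical-risk dimension) before prioritization and selection.
    """
    covs = generate_covariates(cohort, claims, registry, specs)
    covs = [c for c in covs if c.dimension not in exclude_dimensions]
    exposure = cohort["exposure"].to_numpy()
    outcome = cohort["event"].to_numpy()  # any death during follow-up
    for c in covs:
        assess_covariate(c, exposure, outcome, clamp_protective=clamp_protective)
    return rank_and_select(covs, k=k)
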