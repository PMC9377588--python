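"""Propensity-score adjustment approaches: 1:1 caliper matching, quintile
stratification, and 5% asymmetric trimming, plus covariate-balance diagnostics.

The matching caliper follows the standard reading of "0.2 times the logit of
the propensity score": 0.2 x SD of the logit-transformed scores over the whole
cohort (`caliper_absolute=True` gives the literal 0.2-on-the-logit-scale
alternative). Matching is greedy nearest-neighbor without replacement with
fixed, documented tie-breaks so runs are deterministic.

Asymmetric trimming removes treated patients below the alpha-quantile of the
treated PS distribution and untreated patients above the (1-alpha)-quantile of
the untreated distribution — the tails where actual treatment contradicts
predicted treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("propensity scores must lie strictly inside (0,1)")
    return np.log(p / (1.0 - p))


@dataclass
class MatchResult:
    pairs: list[tuple[int, int]]  # (exposed index, unexposed index)
    caliper_width: float  # on the logit scale
    n_unmatched_exposed: int

    @property
    def matched_indices(self) -> np.ndarray:
        if not self.pairs:
            return np.array([], dtype=int)
        return np.array([i for pair in self.pairs for i in pair], dtype=int)


@dataclass
class StrataAssignment:
    labels: np.ndarray  # quintile 1..5 per analysis-sample row
    cut_points: np.ndarray  # 4 reals


@dataclass
class TrimResult:
    retained: np.ndarray  # indices into the input arrays
    lower_cut: float  # alpha-quantile of PS among exposed
    upper_cut: float  # (1-alpha)-quantile of PS among unexposed


def match_1to1(
    ps: np.ndarray,
    exposure: np.ndarray,
    caliper_mult: float = 0.2,
    caliper_absolute: bool = False,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbor matching on the logit PS within a caliper.

    Exposed patients are processed in descending PS order; each takes the
    unexposed neighbor with the smallest absolute logit distance within the
    caliper (distance ties go to the smaller unexposed index), without
    replacement. Exposed order ties are broken by smaller index.
    """
    ps = np.asarray(ps, dtype=float)
    e = np.asarray(exposure).astype(bool)
    if not e.any() or e.all():
        raise ValueError("both exposure arms must be non-empty")
    lp = _logit(ps)
    width = caliper_mult if caliper_absolute else caliper_mult * float(np.std(lp, ddof=0))

    exp_idx = np.flatnonzero(e)
    une_idx = np.flatnonzero(~e)
    order = exp_idx[np.lexsort((exp_idx, -ps[exp_idx]))]  # desc PS, ties small idx

    available = np.ones(len(une_idx), dtype=bool)
    une_lp = lp[une_idx]
    pairs: list[tuple[int, int]] = []
    for i in order:
        if not available.any():
            break
        dist = np.abs(une_lp - lp[i])
        dist[~available] = np.inf
        j = int(np.argmin(dist))  # argmin returns the first minimum: smaller index
        if dist[j] <= width:
            pairs.append((int(i), int(une_idx[j])))
            available[j] = False
    # invariant: no pair violates the caliper
    assert all(abs(lp[a] - lp[b]) <= width + 1e-12 for a, b in pairs)
    return MatchResult(pairs, width, int(len(exp_idx) - len(pairs)))


def assign_quintiles(ps: np.ndarray) -> StrataAssignment:
    """Quintile labels 1-5 with cut points at the 20/40/60/80th percentiles
    (linear interpolation). A score equal to a cut point goes to the lower
    stratum: label = 1 + #cut points strictly below the score."""
    ps = np.asarray(ps, dtype=float)
    if len(np.unique(ps)) < 5:
        raise ValueError("need at least 5 distinct scores for quintiles")
    cuts = np.percentile(ps, [20, 40, 60, 80])
    labels = 1 + np.sum(ps[:, None] > cuts[None, :], axis=1)
    return StrataAssignment(labels.astype(int), cuts)


def asymmetric_trim(
    ps: np.ndarray,
    exposure: np.ndarray,
    alpha: float = 0.05,
    cuts: tuple[float, float] | None = None,
) -> TrimResult:
    """Asymmetric trimming at level ``alpha``; precomputed ``cuts`` may be
    supplied (e.g. to verify idempotence on an already-trimmed sample)."""
    ps = np.asarray(ps, dtype=float)
    e = np.asarray(exposure).astype(bool)
    if not e.any() or e.all():
        raise ValueError("both exposure arms must be non-empty")
    if not 0.0 <= alpha < 0.5:
        raise ValueError("alpha must be in [0, 0.5)")
    if cuts is None:
        lower = float(np.quantile(ps[e], alpha))
        upper = float(np.quantile(ps[~e], 1.0 - alpha))
    else:
        lower, upper = cuts
    keep = np.where(e, ps >= lower, ps <= upper)
    retained = np.flatnonzero(keep)
    if not e[retained].any() or e[retained].all():
        raise ValueError("trimming emptied an exposure arm")
    return TrimResult(retained, lower, upper)


def standardized_differences(
    design: pd.DataFrame,
    exposure: np.ndarray,
    subset: np.ndarray | None = None,
) -> pd.DataFrame:
    """Standardized mean differences before and (optionally) after adjustment.

    SMD = (mean_exposed - mean_unexposed) / sqrt((var_exposed + var_unexposed)/2)
    with sample (ddof=1) variances. ``subset`` is the post-adjustment analysis
    sample (matched indices, or retained indices after trimming). Covariates
    with zero pooled variance get SMD 0 when the means agree and are flagged
    otherwise.
    """
    e = np.asarray(exposure).astype(bool)

    def _smd_frame(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = design.iloc[idx].to_numpy(dtype=float)
        ei = e[idx]
        m1, m0 = X[ei].mean(axis=0), X[~ei].mean(axis=0)
        v1 = X[ei].var(axis=0, ddof=1) if ei.sum() > 1 else np.zeros(X.shape[1])
        v0 = X[~ei].var(axis=0, ddof=1) if (~ei).sum() > 1 else np.zeros(X.shape[1])
        denom = np.sqrt((v1 + v0) / 2.0)
        diff = m1 - m0
        smd = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), np.where(np.isclose(diff, 0), 0.0, np.nan))
        return smd, diff

    all_idx = np.arange(len(design))
    smd_before, _ = _smd_frame(all_idx)
    out = pd.DataFrame({"covariate": design.columns, "smd_before": smd_before})
    if subset is not None:
        smd_after, _ = _smd_frame(np.asarray(subset))
        out["smd_after"] = smd_after
    out["degenerate"] = out.filter(like="smd").isna().any(axis=1)
    return out
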