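"""Orchestration of the full study design grid.

One grid run crosses every propensity-score model variant (strategy x data
source) with every adjustment approach (quintile adjustment with and without
asymmetric trimming, 1:1 caliper matching), on top of a shared multiple-
imputation set, and reports per-cell hazard ratios next to the crude estimate
— the simulated analog of the design-comparison table. ``replicate`` repeats
the whole grid over independently generated cohorts and summarizes per-cell
bias, empirical SE, RMSE and benchmark coverage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .adjust import assign_quintiles, asymmetric_trim, match_1to1, standardized_differences
from .config import ScenarioConfig
from .hdps import RankedCovariateList, rank_covariates
from .impute import impute_registry, pool_rubin
from .ps import (
    InvestigatorLists,
    PsModelSpec,
    assemble_design,
    fit_propensity,
    investigator_lists_from_truth,
)
from .simulate import TruthRecord, generate_cohort
from .survival import fit_cox

logger = logging.getLogger(__name__)

ADJUSTMENTS = ("quintiles", "quintiles_trimmed", "matched")


def default_model_specs(k: int = 500) -> list[PsModelSpec]:
    """The seven model variants of the study design."""
    return [
        PsModelSpec("investigator", "claims"),
        PsModelSpec("investigator", "registry"),
        PsModelSpec("investigator", "both"),
        PsModelSpec("hdps", "claims", k=k),
        PsModelSpec("hdps", "registry", k=k),
        PsModelSpec("hdps", "both_minus_risk", k=k),
        PsModelSpec("hdps", "both", k=k),
    ]


@dataclass
class GridSpec:
    models: list[PsModelSpec] = field(default_factory=default_model_specs)
    adjustments: tuple[str, ...] = ADJUSTMENTS
    benchmark_hr: float = 1.0
    m: int = 5  # imputations
    imputation_method: str = "draw_from_conditional"
    trim_alpha: float = 0.05
    caliper_mult: float = 0.2
    quintiles_as_strata: bool = False

    def __post_init__(self) -> None:
        if not self.models or not self.adjustments:
            raise ValueError("need at least one model and one adjustment")
        for a in self.adjustments:
            if a not in ADJUSTMENTS:
                raise ValueError(f"unknown adjustment {a!r}; known: {ADJUSTMENTS}")


@dataclass
class GridResult:
    cells: pd.DataFrame  # one row per (model, adjustment) plus the crude row
    model_info: pd.DataFrame  # model_id, c_statistic, n_covariates, converged
    benchmark_hr: float
    seed: int
    rankings: dict[str, RankedCovariateList] = field(default_factory=dict)
    balance: dict[str, pd.DataFrame] = field(default_factory=dict)


@dataclass
class ReplicationSummary:
    per_cell: pd.DataFrame  # bias, emp SE, RMSE, coverage per grid cell
    per_rep: pd.DataFrame  # raw per-replicate cell estimates
    model_info: pd.DataFrame  # per-replicate c-statistics
    seeds: list[int]
    benchmark_hr: float


# ---------------------------------------------------------------------------
# single-cohort grid
# ---------------------------------------------------------------------------

def _hdps_rankings(
    cohort: pd.DataFrame,
    claims: pd.DataFrame,
    registry: pd.DataFrame,
    sources: set[str],
    k: int,
) -> dict[str, RankedCovariateList]:
    out = {}
    if "claims" in sources:
        out["claims"] = rank_covariates(cohort, claims=claims, registry=None, k=k)
    if "registry" in sources:
        out["registry"] = rank_covariates(cohort, claims=None, registry=registry, k=k)
    if "both" in sources:
        out["both"] = rank_covariates(cohort, claims=claims, registry=registry, k=k)
    if "both_minus_risk" in sources:
        out["both_minus_risk"] = rank_covariates(
            cohort, claims=claims, registry=registry, k=k,
            exclude_dimensions=("high_surgical_risk",),
        )
    return out


def _cox_df(cohort: pd.DataFrame) -> pd.DataFrame:
    return cohort[
        ["patient_id", "exposure", "followup_days", "event", "hospital_id", "physician_id"]
    ].reset_index(drop=True)


def _cell_estimate(
    cohort: pd.DataFrame,
    scores: np.ndarray,
    adjustment: str,
    spec: GridSpec,
) -> tuple[float, float, dict[str, int], np.ndarray]:
    """(log-HR, robust variance, counts, analysis-subset indices) for one cell."""
    df = _cox_df(cohort)
    e = df["exposure"].to_numpy()

    if adjustment == "matched":
        res = match_1to1(scores, e, caliper_mult=spec.caliper_mult)
        idx = res.matched_indices
        sub = df.iloc[idx].reset_index(drop=True)
        sub["pair_id"] = np.repeat(np.arange(len(res.pairs)), 2)
        est = fit_cox(sub, ["exposure"], cluster_col="pair_id", adjustment=adjustment)
    else:
        if adjustment == "quintiles_trimmed":
            trim = asymmetric_trim(scores, e, alpha=spec.trim_alpha)
            idx = trim.retained
        else:
            idx = np.arange(len(df))
        sub = df.iloc[idx].reset_index(drop=True)
        strata = assign_quintiles(scores[idx])  # quintiles on the analysis sample
        sub["ps_quintile"] = strata.labels
        if spec.quintiles_as_strata:
            est = fit_cox(
                sub, ["exposure"], strata=["ps_quintile"], adjustment=adjustment
            )
        else:
            for q in range(2, 6):
                sub[f"q{q}"] = (sub["ps_quintile"] == q).astype(np.int8)
            est = fit_cox(
                sub, ["exposure"] + [f"q{q}" for q in range(2, 6)], adjustment=adjustment
            )
    counts = {
        "n_exposed": est.n_exposed,
        "n_unexposed": est.n_unexposed,
        "events_exposed": est.events_exposed,
        "events_unexposed": est.events_unexposed,
    }
    return est.log_hr, est.se_log_hr**2, counts, idx


def run_grid(
    cohort: pd.DataFrame,
    claims: pd.DataFrame,
    registry: pd.DataFrame,
    spec: GridSpec,
    seed: int = 0,
    investigator: InvestigatorLists | None = None,
    truth: TruthRecord | None = None,
    compute_balance: bool = False,
) -> GridResult:
    """Execute imputation -> PS per model -> each adjustment -> Cox per cell.

    Cell failures are recorded per cell (column ``error``) and never abort the
    grid. Deterministic given inputs and ``seed``.
    """
    if investigator is None:
        if truth is None:
            raise ValueError("provide investigator lists or a truth record to derive them")
        investigator = investigator_lists_from_truth(truth, registry)

    rng = np.random.SeedSequence(seed)
    imp_seed = int(rng.generate_state(1)[0] % (2**31 - 1))
    imps = impute_registry(
        registry, cohort, m=spec.m, method=spec.imputation_method, seed=imp_seed
    )

    hdps_sources = {m.source for m in spec.models if m.strategy == "hdps"}
    max_k = max((m.k for m in spec.models if m.strategy == "hdps"), default=500)

    # crude estimate (registry-free, so independent of imputation)
    crude = fit_cox(_cox_df(cohort), ["exposure"], adjustment="crude", model_id="crude")

    cell_estimates: dict[tuple[str, str], list[tuple[float, float]]] = {}
    cell_counts: dict[tuple[str, str], dict[str, int]] = {}
    cell_errors: dict[tuple[str, str], str] = {}
    model_rows: dict[str, dict] = {}
    rankings_first: dict[str, RankedCovariateList] = {}
    balance: dict[str, pd.DataFrame] = {}

    claims_ranking_cache: RankedCovariateList | None = None
    for i_imp, reg_i in enumerate(imps.tables):
        rankings: dict[str, RankedCovariateList] = {}
        if hdps_sources:
            need = set(hdps_sources)
            if "claims" in need and claims_ranking_cache is not None:
                rankings["claims"] = claims_ranking_cache
                need.discard("claims")
            rankings.update(_hdps_rankings(cohort, claims, reg_i, need, max_k))
            if "claims" in rankings and claims_ranking_cache is None:
                claims_ranking_cache = rankings["claims"]
        if i_imp == 0:
            rankings_first = dict(rankings)

        for mspec in spec.models:
            mid = mspec.model_id
            try:
                design = assemble_design(
                    mspec, cohort, claims, reg_i,
                    ranking=rankings.get(mspec.source), investigator=investigator,
                )
                fit = fit_propensity(design, cohort["exposure"].to_numpy())
            except Exception as err:  # PS failure poisons all the model's cells
                logger.error("PS fit failed for %s: %s", mid, err)
                for adj in spec.adjustments:
                    cell_errors[(mid, adj)] = f"ps_fit: {err}"
                continue
            info = model_rows.setdefault(
                mid,
                {
                    "model_id": mid, "strategy": mspec.strategy, "source": mspec.source,
                    "c_statistic": [], "n_covariates": fit.n_covariates,
                    "converged": True,
                },
            )
            info["c_statistic"].append(fit.c_statistic)
            info["converged"] = info["converged"] and fit.converged

            for adj in spec.adjustments:
                key = (mid, adj)
                try:
                    log_hr, var, counts, idx = _cell_estimate(cohort, fit.scores, adj, spec)
                except Exception as err:
                    logger.error("cell %s failed: %s", key, err)
                    logger.debug(traceback.format_exc())
                    cell_errors[key] = str(err)
                    continue
                cell_estimates.setdefault(key, []).append((log_hr, var))
                cell_counts[key] = counts
                if compute_balance and i_imp == 0:
                    balance[f"{mid}_{adj}"] = standardized_differences(
                        design, cohort["exposure"].to_numpy(), subset=idx
                    )

    rows = [
        {
            "model_id": "crude", "strategy": "crude", "source": "none",
            "adjustment": "crude", "hr": crude.hr, "ci_lo": crude.ci95[0],
            "ci_hi": crude.ci95[1], "se_log_hr": crude.se_log_hr,
            "log_hr": crude.log_hr, "n_exposed": crude.n_exposed,
            "n_unexposed": crude.n_unexposed, "events_exposed": crude.events_exposed,
            "events_unexposed": crude.events_unexposed, "error": "",
        }
    ]
    for mspec in spec.models:
        for adj in spec.adjustments:
            key = (mspec.model_id, adj)
            row = {
                "model_id": mspec.model_id, "strategy": mspec.strategy,
                "source": mspec.source, "adjustment": adj,
            }
            if key in cell_estimates:
                pooled = pool_rubin(cell_estimates[key])
                row.update(
                    hr=pooled.hr, ci_lo=pooled.ci95[0], ci_hi=pooled.ci95[1],
                    se_log_hr=pooled.se_log_hr, log_hr=pooled.log_hr,
                    **cell_counts[key], error="",
                )
            else:
                row.update(
                    hr=np.nan, ci_lo=np.nan, ci_hi=np.nan, se_log_hr=np.nan,
                    log_hr=np.nan, n_exposed=0, n_unexposed=0, events_exposed=0,
                    events_unexposed=0, error=cell_errors.get(key, "unknown"),
                )
            rows.append(row)

    minfo = pd.DataFrame(
        [
            {**r, "c_statistic": float(np.mean(r["c_statistic"]))}
            for r in model_rows.values()
        ]
    )
    return GridResult(
        cells=pd.DataFrame(rows),
        model_info=minfo,
        benchmark_hr=spec.benchmark_hr,
        seed=seed,
        rankings=rankings_first,
        balance=balance,
    )


# ---------------------------------------------------------------------------
# replication
# ---------------------------------------------------------------------------

def replicate(
    scenario: ScenarioConfig,
    spec: GridSpec,
    n_reps: int,
    base_seed: int = 0,
    collect: "callable | None" = None,
) -> ReplicationSummary:
    """Repeat the full grid on independently generated cohorts.

    Cohort i uses scenario seed ``base_seed + i``. ``collect``, if given, is
    called with (rep index, cohort, claims, registry, truth, GridResult) for
    any extra per-replicate bookkeeping (e.g. ranking-recovery checks).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    import dataclasses as _dc

    seeds, rep_rows, minfo_rows = [], [], []
    for i in range(n_reps):
        cfg = _dc.replace(scenario, seed=base_seed + i)
        cohort, claims, registry, truth = generate_cohort(cfg)
        result = run_grid(
            cohort, claims, registry, spec, seed=base_seed + i, truth=truth
        )
        seeds.append(base_seed + i)
        cells = result.cells.copy()
        cells["rep"] = i
        rep_rows.append(cells)
        mi = result.model_info.copy()
        mi["rep"] = i
        minfo_rows.append(mi)
        if collect is not None:
            collect(i, cohort, claims, registry, truth, result)
        logger.info("replicate %d/%d done", i + 1, n_reps)

    per_rep = pd.concat(rep_rows, ignore_index=True)
    bench = np.log(spec.benchmark_hr)
    summaries = []
    for (mid, adj), grp in per_rep.groupby(["model_id", "adjustment"], sort=False):
        ok = grp[np.isfinite(grp["log_hr"])]
        n_ok = len(ok)
        fail_frac = 1.0 - n_ok / len(grp)
        if n_ok >= 2:
            bias = float(ok["log_hr"].mean() - bench)
            emp_se = float(ok["log_hr"].std(ddof=1))
            rmse = float(np.sqrt(np.mean((ok["log_hr"] - bench) ** 2)))
            cover = float(
                ((ok["ci_lo"] <= spec.benchmark_hr) & (spec.benchmark_hr <= ok["ci_hi"])).mean()
            )
        else:
            bias = emp_se = rmse = cover = float("nan")
        summaries.append(
            {
                "model_id": mid, "adjustment": adj, "n_valid": n_ok,
                "failure_fraction": fail_frac, "invalid": fail_frac > 0.2,
                "mean_log_hr": bias + bench if n_ok >= 2 else float("nan"),
                "bias": bias, "empirical_se": emp_se, "rmse": rmse,
                "coverage": cover,
            }
        )
    return ReplicationSummary(
        per_cell=pd.DataFrame(summaries),
        per_rep=per_rep,
        model_info=pd.concat(minfo_rows, ignore_index=True),
        seeds=seeds,
        benchmark_hr=spec.benchmark_hr,
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def write_report(
    result: "GridResult | ReplicationSummary",
    out_dir: str | Path,
    config: ScenarioConfig | None = None,
) -> list[Path]:
    """Write the run's CSV reports and a manifest; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False, float_format="%.10g")
        written.append(p)

    if isinstance(result, GridResult):
        _w(result.cells, "table2_analog.csv")
        forest = result.cells[
            ["model_id", "adjustment", "hr", "ci_lo", "ci_hi"]
        ].copy()
        _w(forest, "forest.csv")
        _w(result.model_info, "models.csv")
        for source, ranking in result.rankings.items():
            top = ranking.to_frame().head(25)
            _w(top, f"ranking_top25_{source}.csv")
        if result.balance:
            bal_dir = out / "balance"
            bal_dir.mkdir(exist_ok=True)
            for name, df in result.balance.items():
                p = bal_dir / f"{name}.csv"
                df.to_csv(p, index=False, float_format="%.10g")
                written.append(p)
        seeds = [result.seed]
    else:
        _w(result.per_cell, "replication_summary.csv")
        _w(result.per_rep, "replication_cells.csv")
        _w(result.model_info, "replication_models.csv")
        seeds = result.seeds

    manifest = {
        "seeds": seeds,
        "benchmark_hr": result.benchmark_hr,
        "versions": _versions(),
    }
    if config is not None:
        cfg = config.to_dict()
        manifest["config"] = cfg
        manifest["config_sha256"] = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()
    p = out / "run_manifest.json"
    p.write_text(json.dumps(manifest, indent=2))
    written.append(p)
    return written


def _versions() -> dict[str, str]:
    import lifelines
    import sklearn

    return {
        "hdpsim": "0.1.0",
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "lifelines": lifelines.__version__,
        "scikit-learn": sklearn.__version__,
    }
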