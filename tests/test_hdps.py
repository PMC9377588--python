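"""hdPS covariate engine: identification, recurrence expansion, Bross ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdpsim import bias_multiplier, expand_recurrence, identify_candidates, rank_and_select
from hdpsim.hdps import (
    DimensionSpec,
    HdpsCovariate,
    assess_covariate,
    crude_risk_ratio,
    pivot_dimension,
)
import oracles


def _wide(presence: dict[str, list[int]]) -> pd.DataFrame:
    return pd.DataFrame(presence)


# ---------------------------------------------------------------------------
# identification
# ---------------------------------------------------------------------------

class TestIdentifyCandidates:
    def test_absent_code_excluded(self):
        wide = _wide({"A": [0] * 5, "B": [1, 1, 0, 0, 0]})
        spec = DimensionSpec("d", top_n_codes=10, min_prevalence=0.01)
        assert identify_candidates(wide, spec) == ["B"]

    def test_ubiquitous_code_passes_floor_but_ranks_last(self):
        wide = _wide({"ALL": [1] * 10, "HALF": [1] * 5 + [0] * 5, "FEW": [1] * 2 + [0] * 8})
        spec = DimensionSpec("d", top_n_codes=10, min_prevalence=0.01)
        got = identify_candidates(wide, spec)
        assert got == ["HALF", "FEW", "ALL"]  # min(p, 1-p): 0.5, 0.2, 0.0

    def test_top_n_keeps_largest_deviation_from_ubiquity(self):
        # prevalences 0.05, 0.10, ..., 0.50 over 20 patients
        n = 20
        wide = _wide({f"c{p:02d}": [1] * p + [0] * (n - p) for p in range(1, 11)})
        # columns c01..c10 with prevalence 0.05..0.50
        spec = DimensionSpec("d", top_n_codes=3, min_prevalence=0.01)
        got = identify_candidates(wide, spec)
        assert got == ["c10", "c09", "c08"]  # prevalence 0.50, 0.45, 0.40

    def test_empty_dimension_warns_and_returns_empty(self, caplog):
        spec = DimensionSpec("d")
        with caplog.at_level("WARNING"):
            assert identify_candidates(_wide({}), spec) == []
        assert any("d" in r.message for r in caplog.records)

    def test_prevalence_floor_applied(self):
        wide = _wide({"rare": [1] + [0] * 99, "ok": [1] * 5 + [0] * 95})
        spec = DimensionSpec("d", min_prevalence=0.02)
        assert identify_candidates(wide, spec) == ["ok"]


# ---------------------------------------------------------------------------
# recurrence expansion
# ---------------------------------------------------------------------------

class TestExpandRecurrence:
    def test_hand_worked_quantiles(self):
        """counts [0,1,1,2,5]: positive counts [1,1,2,5] -> median 1.5,
        q75 2.75; three distinct indicator vectors."""
        covs = expand_recurrence("d", "c", np.array([0, 1, 1, 2, 5]))
        by_level = {c.recurrence_level: c for c in covs}
        assert set(by_level) == {"once", "sporadic", "frequent"}
        assert by_level["sporadic"].count_threshold == pytest.approx(1.5)
        assert by_level["frequent"].count_threshold == pytest.approx(2.75)
        assert by_level["once"].indicator.tolist() == [0, 1, 1, 1, 1]
        assert by_level["sporadic"].indicator.tolist() == [0, 0, 0, 1, 1]
        assert by_level["frequent"].indicator.tolist() == [0, 0, 0, 0, 1]

    def test_degenerate_counts_collapse_to_once(self):
        covs = expand_recurrence("d", "c", np.array([0, 1, 1, 1]))
        assert [c.recurrence_level for c in covs] == ["once"]

    def test_constant_counts_single_covariate(self):
        covs = expand_recurrence("d", "c", np.array([3, 3, 3]))
        assert len(covs) == 1
        assert covs[0].indicator.tolist() == [1, 1, 1]

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            expand_recurrence("d", "c", np.zeros(4, dtype=int))

    @given(
        st.lists(st.integers(min_value=0, max_value=8), min_size=3, max_size=30).filter(
            lambda xs: any(x > 0 for x in xs)
        )
    )
    @settings(deadline=None, max_examples=60)
    def test_levels_are_nested_and_distinct(self, counts):
        covs = expand_recurrence("d", "c", np.array(counts))
        inds = [c.indicator for c in covs]
        # nested: each higher level implies the lower
        for lower, higher in zip(inds, inds[1:]):
            assert np.all(higher <= lower)
        # pairwise distinct after the duplicate drop
        for i in range(len(inds)):
            for j in range(i + 1, len(inds)):
                assert not np.array_equal(inds[i], inds[j])


# ---------------------------------------------------------------------------
# Bross multiplier + prioritization
# ---------------------------------------------------------------------------

class TestBiasMultiplier:
    def test_hand_worked_example(self):
        bm = bias_multiplier(0.2, 0.1, 2.0)
        assert bm == pytest.approx(1.2 / 1.1)
        assert abs(np.log(bm)) == pytest.approx(0.08701, abs=1e-5)

    def test_null_relative_risk_gives_unity(self):
        assert bias_multiplier(0.4, 0.05, 1.0) == pytest.approx(1.0)

    def test_balanced_covariate_gives_unity(self):
        assert bias_multiplier(0.3, 0.3, 5.0) == pytest.approx(1.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bias_multiplier(1.2, 0.1, 2.0)
        with pytest.raises(ValueError):
            bias_multiplier(0.1, 0.1, -1.0)
        with pytest.raises(ValueError):
            bias_multiplier(float("nan"), 0.1, 2.0)

    @given(
        st.floats(0.0, 1.0),
        st.floats(0.0, 1.0),
        st.floats(0.05, 20.0),
    )
    @settings(deadline=None, max_examples=100)
    def test_swap_symmetry(self, pc1, pc0, rr):
        """Swapping (pc1, pc0) maps the multiplier to its reciprocal, so
        |log bias| is symmetric in the two prevalences."""
        a = bias_multiplier(pc1, pc0, rr)
        b = bias_multiplier(pc0, pc1, rr)
        assert np.log(a) == pytest.approx(-np.log(b), abs=1e-9)
        assert abs(np.log(a)) == pytest.approx(abs(np.log(b)), abs=1e-9)

    def test_matches_rational_oracle_on_random_instances(self, rng):
        for _ in range(100):
            pc1, pc0 = rng.random(2)
            rr = float(np.exp(rng.normal(0, 1)))
            assert bias_multiplier(pc1, pc0, rr) == pytest.approx(
                oracles.bross_multiplier(pc1, pc0, rr), rel=1e-9
            )

    def test_zero_cell_correction_keeps_rr_finite(self):
        cov = np.array([1, 1, 0, 0, 0], dtype=bool)
        out = np.array([0, 0, 1, 0, 0], dtype=bool)  # a = 0 cell
        rr = crude_risk_ratio(cov, out)
        assert np.isfinite(rr) and rr > 0


class TestRankAndSelect:
    def _cov(self, dim, code, level, alb):
        c = HdpsCovariate(dim, code, level, 1.0, np.array([1, 0]))
        c.abs_log_bias = alb
        c.bias_multiplier = float(np.exp(alb))
        return c

    def test_orders_by_abs_log_bias_and_selects_k(self):
        covs = [
            self._cov("d", "a", "once", 0.3),
            self._cov("d", "b", "once", 0.0),
            self._cov("d", "c", "once", 0.1),
        ]
        ranked = rank_and_select(covs, k=2)
        assert [c.code for c in ranked.covariates] == ["a", "c", "b"]
        assert [c.code for c in ranked.selected] == ["a", "c"]
        assert [c.rank for c in ranked.covariates] == [1, 2, 3]

    def test_k_larger_than_list_selects_all(self):
        covs = [self._cov("d", "a", "once", 0.2), self._cov("d", "b", "once", 0.1)]
        assert rank_and_select(covs, k=99).k_selected == 2

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            rank_and_select([self._cov("d", "a", "once", 0.1)], k=0)

    def test_matches_brute_force_resort(self, rng):
        """Ranking equals an independently computed sort on random instances."""
        for _ in range(25):
            n = int(rng.integers(2, 40))
            covs = [
                self._cov("d", f"c{i}", "once", float(rng.choice([0.0, 0.1, 0.2, rng.random()])))
                for i in range(n)
            ]
            ranked = rank_and_select(list(covs), k=5)
            expect = sorted(covs, key=lambda c: (-c.abs_log_bias, c.dimension, c.code, c.recurrence_level))
            assert [c.code for c in ranked.covariates] == [c.code for c in expect]

    def test_assessment_fills_consistent_fields(self, rng):
        n = 200
        ind = (rng.random(n) < 0.3).astype(np.int8)
        exposure = rng.random(n) < 0.4
        outcome = rng.random(n) < 0.2
        cov = HdpsCovariate("d", "c", "once", 1.0, ind)
        assess_covariate(cov, exposure, outcome)
        assert 0 <= cov.pc1 <= 1 and 0 <= cov.pc0 <= 1
        assert cov.rr_cd >= 1.0  # protective clamp
        assert cov.abs_log_bias == pytest.approx(abs(np.log(cov.bias_multiplier)))


def test_registry_pivot_binarizes_continuous_at_median():
    reg = pd.DataFrame(
        {
            "patient_id": [1, 2, 3, 4],
            "dimension": "imaging",
            "variable": "stenosis_pct",
            "value": [10.0, 60.0, 80.0, 95.0],
            "missing": False,
        }
    )
    wide = pivot_dimension(reg, "imaging", np.array([1, 2, 3, 4]), "registry")
    # median 70 -> above-median indicator
    assert wide["stenosis_pct"].tolist() == [0.0, 0.0, 1.0, 1.0]
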