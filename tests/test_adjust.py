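"""Matching, quintile stratification, trimming and balance diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdpsim import (
    assign_quintiles,
    asymmetric_trim,
    match_1to1,
    standardized_differences,
)
import oracles


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

class TestMatching:
    def test_hand_greedy_trace(self):
        """Exposed {0.9, 0.5} vs unexposed {0.52, 0.55, 0.95} with a wide
        caliper: 0.9 (processed first) takes 0.95, then 0.5 takes 0.52."""
        ps = np.array([0.9, 0.5, 0.52, 0.55, 0.95])
        e = np.array([1, 1, 0, 0, 0])
        res = match_1to1(ps, e, caliper_mult=100.0, caliper_absolute=True)
        got = {(ps[a], ps[b]) for a, b in res.pairs}
        assert got == {(0.9, 0.95), (0.5, 0.52)}
        assert res.n_unmatched_exposed == 0

    def test_zero_caliper_matches_only_exact_ties(self):
        ps = np.array([0.3, 0.4, 0.3, 0.5])
        e = np.array([1, 1, 0, 0])
        res = match_1to1(ps, e, caliper_mult=0.0)
        assert len(res.pairs) == 1
        a, b = res.pairs[0]
        assert ps[a] == ps[b] == 0.3

    def test_caliper_never_violated(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            ps = rng.uniform(0.05, 0.95, n)
            e = (rng.random(n) < 0.4).astype(int)
            if e.sum() in (0, n):
                continue
            res = match_1to1(ps, e)
            lp = np.log(ps / (1 - ps))
            for a, b in res.pairs:
                assert abs(lp[a] - lp[b]) <= res.caliper_width + 1e-12

    def test_each_patient_in_at_most_one_pair(self, rng):
        ps = rng.uniform(0.1, 0.9, 40)
        e = (rng.random(40) < 0.5).astype(int)
        res = match_1to1(ps, e)
        flat = [i for p in res.pairs for i in p]
        assert len(flat) == len(set(flat))

    def test_matches_brute_force_oracle_on_small_instances(self, rng):
        """<= 20-patient instances reproduce an independent greedy re-trace."""
        checked = 0
        while checked < 100:
            n = int(rng.integers(4, 21))
            ps = np.round(rng.uniform(0.05, 0.95, n), 3)
            e = (rng.random(n) < 0.5).astype(int)
            if e.sum() in (0, n):
                continue
            res = match_1to1(ps, e)
            expect = oracles.greedy_match(list(ps), list(e), res.caliper_width)
            assert res.pairs == expect
            checked += 1

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            match_1to1(np.array([0.1, 0.2]), np.array([1, 1]))


# ---------------------------------------------------------------------------
# quintiles
# ---------------------------------------------------------------------------

class TestQuintiles:
    def test_ten_equally_spaced_scores_two_per_quintile(self):
        ps = np.linspace(0.05, 0.95, 10)
        res = assign_quintiles(ps)
        counts = np.bincount(res.labels, minlength=6)[1:]
        assert counts.tolist() == [2, 2, 2, 2, 2]

    def test_labels_monotone_in_score(self, rng):
        ps = rng.uniform(0.01, 0.99, 97)
        res = assign_quintiles(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(res.labels[order]) >= 0)

    def test_cut_points_match_independent_percentile_routine(self, rng):
        for _ in range(25):
            ps = rng.uniform(0.01, 0.99, int(rng.integers(10, 200)))
            res = assign_quintiles(ps)
            expect = [oracles.percentile_linear(ps, q) for q in (20, 40, 60, 80)]
            assert np.allclose(res.cut_points, expect, atol=1e-12)

    def test_boundary_scores_go_to_lower_stratum(self):
        ps = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]) / 1.1
        res = assign_quintiles(ps)
        # the value sitting exactly on a cut point belongs to the lower quintile
        cuts = res.cut_points
        for v, label in zip(ps, res.labels):
            assert label == 1 + int(np.sum(v > cuts))

    def test_partition_property(self, rng):
        ps = rng.uniform(0.01, 0.99, 60)
        res = assign_quintiles(ps)
        assert res.labels.shape == ps.shape
        assert set(np.unique(res.labels)) <= {1, 2, 3, 4, 5}

    def test_too_few_distinct_scores_rejected(self):
        with pytest.raises(ValueError):
            assign_quintiles(np.array([0.2, 0.2, 0.2, 0.3, 0.3]))


# ---------------------------------------------------------------------------
# asymmetric trimming
# ---------------------------------------------------------------------------

class TestTrimming:
    def test_alpha_zero_retains_everyone(self, rng):
        ps = rng.uniform(0.05, 0.95, 50)
        e = (rng.random(50) < 0.4).astype(int)
        res = asymmetric_trim(ps, e, alpha=0.0)
        assert len(res.retained) == 50

    def test_hand_quantile_on_equally_spaced_exposed(self):
        """20 equally spaced exposed scores: the 5% quantile falls at
        0.95*(first) + 0.05*(second) by linear interpolation, so exactly the
        lowest exposed patient drops."""
        exp_ps = np.linspace(0.30, 0.87, 20)
        une_ps = np.linspace(0.10, 0.60, 20)
        ps = np.concatenate([exp_ps, une_ps])
        e = np.array([1] * 20 + [0] * 20)
        res = asymmetric_trim(ps, e, alpha=0.05)
        dropped = sorted(set(range(40)) - set(res.retained))
        dropped_exposed = [i for i in dropped if e[i] == 1]
        assert dropped_exposed == [int(np.argmin(exp_ps))]
        assert res.lower_cut == pytest.approx(oracles.percentile_linear(exp_ps, 5))
        assert res.upper_cut == pytest.approx(oracles.percentile_linear(une_ps, 95))

    def test_trim_directions_are_asymmetric(self, rng):
        ps = rng.uniform(0.05, 0.95, 200)
        e = (rng.random(200) < 0.5).astype(int)
        res = asymmetric_trim(ps, e, alpha=0.1)
        kept = res.retained
        assert np.all(ps[kept][e[kept] == 1] >= res.lower_cut)
        assert np.all(ps[kept][e[kept] == 0] <= res.upper_cut)

    def test_idempotent_with_cached_cuts(self, rng):
        ps = rng.uniform(0.05, 0.95, 120)
        e = (rng.random(120) < 0.4).astype(int)
        first = asymmetric_trim(ps, e, alpha=0.05)
        second = asymmetric_trim(
            ps[first.retained], e[first.retained], alpha=0.05,
            cuts=(first.lower_cut, first.upper_cut),
        )
        assert len(second.retained) == len(first.retained)

    def test_emptying_an_arm_rejected(self):
        ps = np.array([0.1, 0.9])
        e = np.array([1, 0])
        with pytest.raises(ValueError):
            # lower cut = the single exposed score... trimming cannot empty
            asymmetric_trim(np.array([0.9, 0.1]), np.array([0, 1]), cuts=(0.95, 0.05), alpha=0.05)
        del ps, e


# ---------------------------------------------------------------------------
# balance
# ---------------------------------------------------------------------------

class TestStandardizedDifferences:
    def test_identical_arms_give_zero(self):
        design = pd.DataFrame({"x": [1, 0, 1, 0], "z": [0.5, 0.2, 0.5, 0.2]})
        e = np.array([1, 1, 0, 0])
        out = standardized_differences(design, e)
        assert np.allclose(out["smd_before"], 0.0)

    def test_hand_formula_on_binary_prevalences(self):
        """96.7% vs 44.5% binary imbalance: SMD ~ 1.40 by the pooled-SD
        formula (with n chosen so arm prevalences are exact)."""
        n1, n0 = 1000, 1000
        x1 = np.r_[np.ones(967), np.zeros(33)]
        x0 = np.r_[np.ones(445), np.zeros(555)]
        design = pd.DataFrame({"hsr": np.r_[x1, x0]})
        e = np.r_[np.ones(n1), np.zeros(n0)].astype(int)
        out = standardized_differences(design, e)
        expect = (0.967 - 0.445) / np.sqrt((0.967 * 0.033 + 0.445 * 0.555) / 2)
        assert out["smd_before"].iloc[0] == pytest.approx(expect, rel=2e-3)
        assert expect == pytest.approx(1.40, abs=0.01)

    def test_zero_variance_equal_means_reported_zero(self):
        design = pd.DataFrame({"const": np.ones(6)})
        e = np.array([1, 1, 1, 0, 0, 0])
        out = standardized_differences(design, e)
        assert out["smd_before"].iloc[0] == 0.0
        assert not out["degenerate"].iloc[0]

    def test_subset_reporting_adds_after_column(self, rng):
        design = pd.DataFrame({"x": rng.random(30)})
        e = (rng.random(30) < 0.5).astype(int)
        if e.sum() in (0, 30):
            e[:15] = 1
            e[15:] = 0
        out = standardized_differences(design, e, subset=np.arange(20))
        assert {"smd_before", "smd_after"} <= set(out.columns)
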