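"""Geometry normalisation, paired rates, and exact rank-based tests."""

import math
from itertools import combinations, product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from microcal.stats import (
    CompartmentGeometry,
    omnibus_test,
    paired_ratios,
    paired_signed_rank_test,
    rank_sum_test,
    summarize_group,
    surface_area,
)


# --- independent enumeration oracles ---------------------------------------

def enumerate_rank_sum_p(a, b):
    """Two-sided exact Mann-Whitney p by direct enumeration over all
    partitions of the pooled sample (midranks for ties)."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    na = len(a)
    w_obs = ranks[:na].sum()
    sums = [sum(ranks[list(idx)]) for idx in combinations(range(len(pooled)), na)]
    sums = np.array(sums)
    lo = np.mean(sums <= w_obs + 1e-9)
    hi = np.mean(sums >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(lo, hi))


def enumerate_signed_rank_p(x, y):
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    sums = [sum(r for r, s in zip(ranks, signs) if s)
            for signs in product([False, True], repeat=len(d))]
    sums = np.array(sums)
    lo = np.mean(sums <= w_obs + 1e-9)
    hi = np.mean(sums >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(lo, hi))


# --- geometry ---------------------------------------------------------------

class TestSurfaceArea:
    def test_soma_sphere_707(self):
        exact, rounded = surface_area(CompartmentGeometry(), "soma")
        assert rounded == 707
        assert exact == pytest.approx(4 * math.pi * 7.5**2)

    def test_process_cylinder_71(self):
        exact, rounded = surface_area(CompartmentGeometry(), "process")
        assert rounded == 71
        assert exact == pytest.approx(2 * math.pi * 0.75 * 15.0)

    def test_soma_to_process_ratio_about_tenfold(self):
        soma, _ = surface_area(CompartmentGeometry(), "soma")
        proc, _ = surface_area(CompartmentGeometry(), "process")
        assert soma / proc == pytest.approx(10.0, abs=0.01)

    def test_zero_radius_gives_zero(self):
        g = CompartmentGeometry(soma_radius_um=0.0)
        assert surface_area(g, "soma")[0] == 0.0

    def test_scaling_laws(self):
        g = CompartmentGeometry()
        g2 = CompartmentGeometry(soma_radius_um=15.0, process_radius_um=1.5,
                                 process_length_um=30.0)
        assert surface_area(g2, "soma")[0] == \
            pytest.approx(4 * surface_area(g, "soma")[0])
        assert surface_area(g2, "process")[0] == \
            pytest.approx(4 * surface_area(g, "process")[0])


# --- paired rates -----------------------------------------------------------

class TestPairedRatios:
    def test_forced_arithmetic(self):
        cells = {"c1": {"soma": [0.1], "process": [0.2, 0.4]}}
        records, median = paired_ratios(cells)
        assert records[0].mean_process_rate == pytest.approx(0.3)
        assert records[0].ratio == pytest.approx(3.0)
        assert median == pytest.approx(3.0)

    def test_equal_rates_ratio_one(self):
        cells = {f"c{i}": {"soma": [0.2], "process": [0.2, 0.2]}
                 for i in range(4)}
        _, median = paired_ratios(cells)
        assert median == pytest.approx(1.0)

    def test_zero_soma_rate_gives_nan_ratio_but_keeps_cell(self):
        cells = {"c1": {"soma": [0.0], "process": [0.3]}}
        records, _ = paired_ratios(cells)
        assert len(records) == 1
        assert math.isnan(records[0].ratio)

    def test_cell_missing_compartment_excluded_with_warning(self):
        cells = {"c1": {"soma": [0.1]},
                 "c2": {"soma": [0.1], "process": [0.2]}}
        with pytest.warns(UserWarning):
            records, _ = paired_ratios(cells)
        assert [r.cell_id for r in records] == ["c2"]

    def test_poisson_simulation_recovers_known_ratio(self, rng):
        # per-cell Poisson counts over 5 min with process:soma rate ratio 3.5
        for rho in (1.0, 2.0, 3.5):
            cells = {}
            soma_rate = 0.2
            for i in range(200):
                s = rng.poisson(soma_rate * 5) / 5.0
                procs = rng.poisson(rho * soma_rate * 5, size=3) / 5.0
                cells[f"c{i}"] = {"soma": [s], "process": list(procs)}
            records, _ = paired_ratios(cells)
            mean_p = np.mean([r.mean_process_rate for r in records])
            mean_s = np.mean([r.soma_rate for r in records])
            se = rho * soma_rate * np.sqrt(
                1 / (3 * 5 * soma_rate * rho * 200) + 1 / (5 * soma_rate * 200))
            assert abs(mean_p / mean_s - rho) < 3 * max(se, 0.05 * rho)


# --- rank-sum test ----------------------------------------------------------

class TestRankSum:
    def test_identical_samples_p_one(self):
        p, method = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == 1.0
        assert method == "exact"

    def test_separated_triples_exact_p(self):
        # enumerate all C(6,3)=20 assignments: 2/20 are as extreme
        p, method = rank_sum_test([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)
        assert method == "exact"

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(30):
            a = rng.normal(size=rng.integers(2, 6))
            b = rng.normal(size=rng.integers(2, 6))
            p, _ = rank_sum_test(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-9)

    @settings(max_examples=250, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 6), min_size=2, max_size=4),
           st.lists(st.integers(0, 6), min_size=2, max_size=4))
    def test_exact_branch_equals_enumeration_with_ties(self, a, b):
        p, method = rank_sum_test(a, b)
        assert method == "exact"
        assert p == pytest.approx(enumerate_rank_sum_p(a, b), abs=1e-12)

    def test_large_sample_type_one_error_calibrated(self, rng):
        rejections = 0
        reps = 1000
        for _ in range(reps):
            a = rng.normal(size=30)
            b = rng.normal(size=30)
            p, method = rank_sum_test(a, b)
            assert method == "normal"
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07


# --- signed-rank test -------------------------------------------------------

class TestSignedRank:
    def test_equal_samples_p_one(self):
        p, method = paired_signed_rank_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0
        assert "all-zero" in method

    def test_six_positive_differences_exact(self):
        # all-positive signs: 2 of 2^6 sign patterns are as extreme
        p, method = paired_signed_rank_test([2, 3, 4, 5, 6, 7],
                                            [1, 2, 3, 4, 5, 6])
        assert p == pytest.approx(2 / 64)
        assert method.startswith("exact")

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(30):
            n = rng.integers(4, 10)
            x = rng.normal(size=n)
            y = x + rng.normal(size=n)
            p, _ = paired_signed_rank_test(x, y)
            ref = sps.wilcoxon(x, y, alternative="two-sided",
                               mode="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-9)

    @settings(max_examples=250, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 8), st.integers(0, 8)),
                    min_size=2, max_size=8))
    def test_exact_branch_equals_enumeration(self, pairs):
        x = [float(a) for a, _ in pairs]
        y = [float(b) for _, b in pairs]
        if all(a == b for a, b in pairs):
            p, _ = paired_signed_rank_test(x, y)
            assert p == 1.0
            return
        p, method = paired_signed_rank_test(x, y)
        assert method.startswith("exact")
        assert p == pytest.approx(enumerate_signed_rank_p(x, y), abs=1e-12)

    def test_large_sample_type_one_error_calibrated(self, rng):
        rejections = 0
        reps = 1000
        for _ in range(reps):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            p, method = paired_signed_rank_test(x, y)
            assert method.startswith("normal")
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07


# --- summaries and delegation ----------------------------------------------

def test_group_summary_mean_sem_fold():
    s = summarize_group([1.0, 2.0, 3.0], "g", reference_mean=1.0)
    assert s.mean == pytest.approx(2.0)
    assert s.sem == pytest.approx(np.std([1, 2, 3], ddof=1) / np.sqrt(3))
    assert s.fold_vs_reference == pytest.approx(2.0)


def test_omnibus_test_delegates_and_detects_shift(rng):
    groups = {
        "a": list(rng.normal(0, 1, 40)),
        "b": list(rng.normal(0, 1, 40)),
        "c": list(rng.normal(3, 1, 40)),
    }
    p, method = omnibus_test(groups)
    assert p < 1e-6
    assert "Kruskal" in method
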