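import itertools

import numpy as np
import pandas as pd
import pytest

from senindex.stats import (
    SegmentedFit,
    bh_adjust,
    compare_groups,
    preranked_gsea,
    rank_by_correlation,
    segmented_fit,
    shapiro_gate,
    timepoint_trend,
    wilcoxon_rank_sum,
)

from .conftest import gsea_positional_oracle, wilcoxon_enumeration_p


class TestWilcoxon:
    def test_exact_one_sided_example(self):
        """x entirely below y: one-sided p = 1/C(6,3) = 0.05."""
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], alternative="less")
        assert p == pytest.approx(0.05)
        _, p2 = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], alternative="two-sided")
        assert p2 == pytest.approx(0.1)

    def test_matches_enumeration_for_all_small_tie_free_samples(self, rng):
        """Exact p agrees with full rank-assignment enumeration for every
        sample-size combination up to 6+6 (random tie-free values)."""
        for n, m in itertools.product(range(1, 7), range(1, 7)):
            vals = rng.permutation(np.arange(1, n + m + 1)).astype(float)
            x, y = vals[:n], vals[n:]
            for alt in ("less", "greater", "two-sided"):
                _, p = wilcoxon_rank_sum(x, y, alternative=alt)
                assert p == pytest.approx(
                    wilcoxon_enumeration_p(x, y, alt)), (n, m, alt)

    def test_identical_samples_large_p(self):
        x = np.arange(10.0)
        _, p = wilcoxon_rank_sum(x, x)
        assert p >= 0.99

    def test_label_swap_keeps_two_sided_p(self, rng):
        x, y = rng.random(15), rng.random(20)
        _, p1 = wilcoxon_rank_sum(x, y)
        _, p2 = wilcoxon_rank_sum(y, x)
        assert p1 == pytest.approx(p2)

    def test_empty_sample_error(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestShapiroGate:
    def test_normal_quantiles_route_parametric(self):
        from scipy.stats import norm

        x = norm.ppf(np.linspace(0.01, 0.99, 50))
        assert shapiro_gate(x) == "parametric"

    def test_cauchy_routes_nonparametric_in_most_seeds(self):
        from scipy.stats import cauchy

        votes = sum(
            shapiro_gate(cauchy.rvs(size=50, random_state=s)) == "nonparametric"
            for s in range(20)
        )
        assert votes >= 15

    def test_too_small_sample(self):
        with pytest.raises(ValueError):
            shapiro_gate([1.0, 2.0])

    def test_compare_groups_routes(self, rng):
        out = compare_groups(rng.normal(0, 1, 40), rng.normal(2, 1, 40))
        assert out["test"] in ("t", "wilcoxon")
        assert out["p"] < 0.01


class TestTimepointTrend:
    def test_noiseless_linear_recovery(self):
        t = np.repeat([0, 1, 2, 4, 7, 10], 5)
        y = 0.3 * t + 0.1
        slope, p, r2 = timepoint_trend(y, t)
        assert slope == pytest.approx(0.3, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_null_type_one_error_near_alpha(self):
        """Flat truth with noise: the slope test rejects at ~ the nominal rate."""
        rejections = 0
        n_sim = 500
        t = np.repeat([0.0, 1, 2, 4, 7, 10], 8)
        for s in range(n_sim):
            rng = np.random.default_rng(s)
            y = rng.normal(0, 1, len(t))
            _, p, _ = timepoint_trend(y, t)
            rejections += p < 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.03)

    def test_aging_cohort_positive_slope(self):
        """A synthetic aging series (senescent fraction rising with age)
        produces a significantly positive senescence trend."""
        from senindex.simulate import CohortConfig, generate_scores

        rng = np.random.default_rng(0)
        all_scores, all_t = [], []
        for age in (1, 3, 6, 12, 18, 24, 30):
            frac = 0.02 + 0.01 * age
            cfg = CohortConfig(n_patients=3, sen_fraction_R=frac,
                               sen_fraction_NR=frac, cells_per_patient=60.0,
                               seed=age)
            scores, _ = generate_scores(cfg)
            all_scores.append(scores["senescence"].to_numpy())
            all_t.append(np.full(len(scores), age, dtype=float))
        slope, p, _ = timepoint_trend(np.concatenate(all_scores),
                                      np.concatenate(all_t))
        assert slope > 0
        assert p < 0.05

    def test_too_few_timepoints(self):
        with pytest.raises(ValueError):
            timepoint_trend([1, 2, 3, 4], [0, 0, 1, 1])


class TestSegmentedFit:
    def test_noiseless_two_slope_recovery(self):
        """Fast early rise (slope 0.14 to day 1) then a slow phase (0.01):
        the break and both slopes are recovered from noiseless data."""
        x = np.array([0.0, 1, 2, 4, 7, 10])
        y = np.where(x <= 1, 0.14 * x, 0.14 + 0.01 * (x - 1))
        fit = segmented_fit(x, y)
        assert fit.breakpoint == pytest.approx(1.0, abs=0.05)
        assert fit.slope_left == pytest.approx(0.14, abs=1e-6)
        assert fit.slope_right == pytest.approx(0.01, abs=1e-6)
        assert fit.identifiable

    def test_pure_linear_is_unidentifiable(self):
        x = np.linspace(0, 10, 12)
        y = 0.5 * x + 1
        fit = segmented_fit(x, y)
        assert not fit.identifiable
        assert fit.slope_left == pytest.approx(fit.slope_right, abs=1e-6)

    def test_sse_never_exceeds_single_line(self, rng):
        for _ in range(20):
            x = np.sort(rng.uniform(0, 10, 12))
            y = rng.normal(0, 1, 12)
            if len(np.unique(x)) < 3:
                continue
            fit = segmented_fit(x, y)
            assert fit.sse <= fit.sse_single_line + 1e-9

    def test_grid_equals_brute_force(self, rng):
        """The selected breakpoint's SSE equals the minimum over an explicit
        scan of the same candidates."""
        x = np.array([0.0, 1, 2, 3, 4, 6, 8, 10])
        y = np.where(x <= 3, 0.2 * x, 0.6 + 0.02 * (x - 3)) + rng.normal(0, 0.01, len(x))
        grid = np.linspace(0.5, 9.5, 37)
        fit = segmented_fit(x, y, candidate_breakpoints=grid)
        sses = []
        for b in grid:
            design = np.column_stack([np.ones_like(x), x, np.maximum(x - b, 0)])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            r = y - design @ coef
            sses.append(r @ r)
        assert fit.sse == pytest.approx(min(sses))

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            segmented_fit([0, 1, 2], [0, 1, 2])


class TestPrerankedGsea:
    @staticmethod
    def _metric():
        return pd.Series(np.linspace(2.0, -2.0, 10),
                         index=[f"g{i}" for i in range(10)])

    def test_top_k_set_reaches_es_one_at_weight_zero(self):
        res = preranked_gsea(self._metric(), ["g0", "g1", "g2"], weight=0,
                             n_perm=100, seed=0)
        assert res.es == pytest.approx(1.0)
        assert res.nes > 0 and 0 < res.p <= 1

    def test_bottom_k_set_reaches_minus_one_at_weight_zero(self):
        res = preranked_gsea(self._metric(), ["g7", "g8", "g9"], weight=0,
                             n_perm=100, seed=0)
        assert res.es == pytest.approx(-1.0)
        assert res.nes < 0

    @pytest.mark.parametrize("weight", [0.0, 1.0])
    @pytest.mark.parametrize("gene_set", [
        ["g0", "g4", "g5"], ["g2", "g3", "g9"], ["g1"], ["g0", "g9"],
    ])
    def test_es_matches_positional_oracle(self, gene_set, weight):
        metric = self._metric()
        res = preranked_gsea(metric, gene_set, weight=weight, n_perm=100, seed=1)
        assert res.es == pytest.approx(
            gsea_positional_oracle(metric, gene_set, weight), abs=1e-12)

    def test_universe_padding_below_set_only_rescales_misses(self):
        """At weight 0, adding genes that rank below every set gene changes
        only the miss decrement, as the oracle confirms."""
        metric = self._metric()
        padded = pd.concat([metric, pd.Series([-3.0, -4.0], index=["p1", "p2"])])
        for gs in (["g0", "g1"], ["g0", "g3"]):
            res = preranked_gsea(padded, gs, weight=0, n_perm=100, seed=0)
            assert res.es == pytest.approx(
                gsea_positional_oracle(padded, gs, 0.0), abs=1e-12)

    def test_seeded_reproducibility(self):
        a = preranked_gsea(self._metric(), ["g0", "g5"], n_perm=200, seed=5)
        b = preranked_gsea(self._metric(), ["g0", "g5"], n_perm=200, seed=5)
        assert a == b

    def test_empty_intersection_error(self):
        with pytest.raises(ValueError):
            preranked_gsea(self._metric(), ["nope"], n_perm=100)

    def test_rank_by_correlation_signs(self):
        ages = [7.0, 35.0, 75.0, 90.0]
        expr = pd.DataFrame(
            {"s1": [1, 9, 5], "s2": [2, 7, 5], "s3": [3, 4, 5], "s4": [4, 2, 5]},
            index=["up_with_age", "down_with_age", "flat"], dtype=float)
        r = rank_by_correlation(expr, ages)
        assert r["up_with_age"] > 0.9
        assert r["down_with_age"] < -0.9
        assert r["flat"] == 0.0


def test_bh_adjustment_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    p = rng.random(25)
    np.testing.assert_allclose(bh_adjust(p),
                               multipletests(p, method="fdr_bh")[1])
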