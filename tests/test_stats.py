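"""Outlier fences, Welch+BH, Williams step-down trend, Spearman."""

import numpy as np
import pandas as pd
import pytest

from glucostore.stats import (
    iqr_exclude,
    run_group_comparison,
    spearman,
    stars,
    welch_bh,
    williams_trend,
)


class TestIqrExclude:
    def test_constant_vector_keeps_everything(self):
        kept, excl = iqr_exclude([3.0] * 8)
        assert kept.size == 8 and excl.size == 0

    def test_hand_computed_fence_excludes_outlier(self):
        kept, excl = iqr_exclude([1, 2, 3, 4, 5, 6, 7, 8, 9, 100])
        np.testing.assert_array_equal(np.sort(kept), np.arange(1, 10))
        np.testing.assert_array_equal(excl, [100.0])

    def test_exclusion_equivariant_under_sign_flip(self):
        v = np.array([-40, -3, -2, -1, 0, 1, 2, 3, 40], dtype=float)
        kept_pos, excl_pos = iqr_exclude(v)
        kept_neg, excl_neg = iqr_exclude(-v)
        np.testing.assert_array_equal(np.sort(kept_neg), np.sort(-kept_pos))
        np.testing.assert_array_equal(np.sort(excl_neg), np.sort(-excl_pos))

    def test_short_vector_returned_unfiltered_with_warning(self):
        with pytest.warns(UserWarning, match=">= 4"):
            kept, excl = iqr_exclude([1.0, 2.0, 300.0])
        assert kept.size == 3 and excl.size == 0


class TestWelchBH:
    def test_identical_samples_give_unit_pvalue(self):
        out = welch_bh({"a": np.ones(5), "b": np.ones(5)})
        assert out.loc[0, "t"] == 0.0 and out.loc[0, "p_raw"] == 1.0

    def test_textbook_welch_satterthwaite_oracle(self):
        x = np.array([27.5, 21.0, 19.0, 23.6, 17.0, 17.9, 16.9, 20.1])
        y = np.array([27.1, 22.0, 20.8, 23.4, 23.4, 23.5, 25.8])
        out = welch_bh({"x": x, "y": y})
        # hand evaluation of the Welch statistic and Satterthwaite df
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        t_hand = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df_hand = (vx + vy) ** 2 / (
            vx**2 / (x.size - 1) + vy**2 / (y.size - 1)
        )
        assert out.loc[0, "t"] == pytest.approx(t_hand, rel=1e-12)
        assert out.loc[0, "df"] == pytest.approx(df_hand, rel=1e-12)
        from scipy import stats as sps

        p_hand = 2 * sps.t.sf(abs(t_hand), df_hand)
        assert out.loc[0, "p_raw"] == pytest.approx(p_hand, rel=1e-12)

    def test_bh_step_up_hand_example_all_adjust_to_004(self):
        rng = np.random.default_rng(0)
        groups = {f"g{i}": rng.normal(i, 1, 6) for i in range(4)}
        out = welch_bh(groups)
        # independent check of the step-up rule on the computed raw p's
        p = out["p_raw"].to_numpy()
        order = np.argsort(p)
        m = p.size
        adj = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        expect = np.empty(m)
        expect[order] = np.minimum(adj, 1.0)
        np.testing.assert_allclose(out["p_bh"], expect, rtol=1e-12)
        assert np.all(out["p_bh"] >= out["p_raw"] - 1e-15)

    def test_star_thresholds(self):
        assert [stars(p) for p in (0.2, 0.04, 0.009, 0.0009, 0.00009)] == [
            "", "*", "**", "***", "****"
        ]

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            welch_bh({"a": [1.0], "b": [1.0, 2.0]})


class TestWilliamsTrend:
    def test_identical_constants_give_zero_statistic_no_rejections(self):
        out = williams_trend([1.0] * 5, [[1.0] * 5, [1.0] * 5], "increasing",
                             n_mc=2000, seed=1)
        np.testing.assert_array_equal(out["tbar"], 0.0)
        assert not out["rejected"].any()

    def test_strong_monotone_signal_detected_with_high_power(self):
        # linear ramp to a 3-SD shift at the top dose, n=10 per group
        rng = np.random.default_rng(7)
        hits = 0
        nsim = 300
        for _ in range(nsim):
            ctrl = rng.normal(0, 1, 10)
            grps = [rng.normal(mu, 1, 10) for mu in (1.0, 2.0, 3.0)]
            out = williams_trend(ctrl, grps, "increasing", n_mc=20000, seed=3)
            hits += bool(out["rejected"].iloc[-1])
        assert hits / nsim > 0.95

    def test_decreasing_direction_mirrors_increasing(self):
        rng = np.random.default_rng(5)
        ctrl = rng.normal(0, 1, 8)
        grps = [rng.normal(-1.0, 1, 8), rng.normal(-2.5, 1, 8)]
        down = williams_trend(ctrl, grps, "decreasing", n_mc=20000, seed=2)
        up = williams_trend(-ctrl, [-g for g in grps], "increasing",
                            n_mc=20000, seed=2)
        np.testing.assert_allclose(down["p_mc"], up["p_mc"], rtol=1e-12)
        np.testing.assert_allclose(down["tbar"], -up["tbar"], rtol=1e-12)

    def test_rejections_form_contiguous_suffix(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            ctrl = rng.normal(0, 1, 6)
            grps = [rng.normal(rng.uniform(0, 1.5), 1, 6) for _ in range(4)]
            rej = williams_trend(ctrl, grps, "increasing", n_mc=5000,
                                 seed=4)["rejected"].to_numpy()
            changes = np.diff(rej.astype(int))
            assert np.all(changes >= 0)  # False..False,True..True only

    def test_report_carries_seed_and_replicates(self):
        out = williams_trend([0, 1, 2.0], [[1, 2, 3.0]], "increasing",
                             n_mc=1500, seed=99)
        assert (out["seed"] == 99).all() and (out["n_mc"] == 1500).all()

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            williams_trend([1.0, 2.0], [], "increasing")
        with pytest.raises(ValueError):
            williams_trend([1.0], [[1.0, 2.0]], "increasing")
        with pytest.raises(ValueError):
            williams_trend([1.0, 2.0], [[1.0, 2.0]], "sideways")


class TestSpearman:
    def test_monotone_series_is_perfectly_correlated(self):
        rho, p = spearman(np.arange(12), np.arange(12) ** 3)
        assert rho == pytest.approx(1.0)
        assert p < 1e-6

    def test_reversal_flips_sign_exactly(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3, 5.8, 9.7, 9.3, 2.3, 8.4])
        y = np.array([2.7, 1.8, 2.8, 1.8, 4.5, 9.0, 4.5, 2.3, 5.3, 6.0, 2.8, 7.1])
        r1, _ = spearman(x, y)
        r2, _ = spearman(-x, y)
        assert r2 == pytest.approx(-r1, rel=1e-12)

    def test_ties_match_rank_then_pearson_oracle(self):
        x = np.array([1, 2, 2, 3, 3, 3, 4, 10, 10, 11], dtype=float)
        y = np.array([2, 1, 5, 5, 4, 4, 8, 7, 12, 12], dtype=float)
        rho, _ = spearman(x, y)

        def avg_ranks(v):
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty(v.size)
            i = 0
            sv = v[order]
            while i < v.size:
                j = i
                while j < v.size and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = 0.5 * (i + j - 1) + 1
                i = j
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, rel=1e-12)
        from scipy.stats import spearmanr

        assert rho == pytest.approx(spearmanr(x, y).statistic, rel=1e-12)

    def test_exact_small_sample_pvalue(self):
        # n=5 strictly monotone: only 2 of 120 permutations reach |rho|=1
        rho, p = spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 120)

    def test_zero_rank_variance_reported_undefined(self):
        rho, p = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho) and np.isnan(p)


class TestRunGroupComparison:
    @staticmethod
    def table(rng, means_by_group, n=8, colname="k5"):
        rows = []
        for g, mu in means_by_group.items():
            for v in rng.normal(mu, abs(mu) * 0.15 + 1e-12, n):
                rows.append({"mouse_id": f"{g}{v:.3f}", "group": g, colname: v})
        return pd.DataFrame(rows)

    def test_monotone_decline_flagged_at_every_age(self):
        rng = np.random.default_rng(21)
        tab = self.table(rng, {"CD": 10.0, "HFD1": 6.0, "HFD2": 3.5, "HFD3": 2.0})
        reports = run_group_comparison(
            tab, ["CD", "HFD1", "HFD2", "HFD3"], parameters=["k5"],
            trend_directions={"k5": "decreasing"}, n_mc=20000, seed=5,
        )
        trend = reports["k5"].trend
        assert trend["rejected"].all()

    def test_single_group_yields_summaries_only(self):
        rng = np.random.default_rng(3)
        tab = self.table(rng, {"CD": 5.0})
        reports = run_group_comparison(tab, ["CD"], parameters=["k5"])
        rep = reports["k5"]
        assert rep.pairwise is None and rep.trend is None
        assert rep.summaries.shape[0] == 1

    def test_null_cohorts_respect_fdr_bound(self):
        # no group effects: families with any BH discovery should be ~alpha
        rng = np.random.default_rng(17)
        false_families = 0
        nsim = 200
        for _ in range(nsim):
            tab = self.table(rng, {g: 1.0 for g in ("a", "b", "c", "d")}, n=8)
            reports = run_group_comparison(
                tab, ["a", "b", "c", "d"], parameters=["k5"],
                trend_directions={}, exclude_outliers=False,
            )
            false_families += (reports["k5"].pairwise["p_bh"] < 0.05).any()
        assert false_families / nsim < 0.10

    def test_unknown_group_rejected(self):
        rng = np.random.default_rng(1)
        tab = self.table(rng, {"CD": 5.0})
        with pytest.raises(ValueError, match="absent"):
            run_group_comparison(tab, ["CD", "HFD99"])
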