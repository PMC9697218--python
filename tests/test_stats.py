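"""Statistical battery vs brute-force arithmetic and enumeration oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from eegisc.stats import (
    ancova_group_cov,
    build_mixed_table,
    cohen_d,
    fit_mixed,
    kendall_tau,
    pearson_r,
    welch_t,
    wilcoxon_one_sample,
)


def welch_oracle(a, b):
    """Direct Welch formula arithmetic."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    return t, df


class TestWelch:
    def test_identical_samples(self):
        r = welch_t([1.0, 2, 3, 2], [1.0, 2, 3, 2])
        assert r.statistic == pytest.approx(0, abs=1e-12)
        assert r.p_value == pytest.approx(1, abs=1e-12)

    def test_equal_n_equal_var_df(self):
        # Satterthwaite collapses to n_a + n_b - 2 for equal n, equal variance
        a = np.array([1.0, 2, 3, 4])
        r = welch_t(a, a + 2.0)
        assert r.df == pytest.approx(6.0, abs=1e-9)

    def test_toy_vectors_match_formula(self):
        a, b = (1.0, 2, 3, 4), (3.0, 4, 5, 6)
        r = welch_t(a, b)
        t, df = welch_oracle(a, b)
        assert r.statistic == pytest.approx(t, abs=1e-10)
        assert r.df == pytest.approx(df, abs=1e-10)

    def test_cohen_d_pooled_sd(self):
        a, b = np.array([1.0, 2, 3, 4]), np.array([3.0, 4, 5, 6])
        sp = math.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        assert cohen_d(a, b) == pytest.approx((a.mean() - b.mean()) / sp, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0, 1, 1], [2.0, 2, 2])


def ancova_ss_oracle(y, g, x):
    """Type-II sums of squares by explicit least squares projections."""
    y = np.asarray(y, float)
    g01 = (np.asarray(g) == np.unique(g)[1]).astype(float)
    x = np.asarray(x, float)
    one = np.ones_like(y)

    def rss(*cols):
        design = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        return ((y - design @ beta) ** 2).sum()

    rss_full = rss(one, g01, x)
    ss_g = rss(one, x) - rss_full       # group adjusting for covariate
    ss_x = rss(one, g01) - rss_full
    return ss_g, ss_x, rss_full


@pytest.fixture(scope="module")
def simulated():
    rng = np.random.default_rng(77)
    n = 200
    g = np.repeat(["a", "b"], n // 2)
    x = rng.normal(10, 3, n)
    y = 2.0 * (g == "b") + 0.5 * x + rng.normal(0, 1, n)
    return y, g, x


class TestAncova:

    def test_f_and_eta_match_ss_oracle(self, simulated):
        y, g, x = simulated
        res = ancova_group_cov(y, g, x)["group"]
        ss_g, _, rss_full = ancova_ss_oracle(y, g, x)
        df_err = len(y) - 3
        f_oracle = (ss_g / 1) / (rss_full / df_err)
        assert res.statistic == pytest.approx(f_oracle, abs=1e-8)
        assert res.effect_size == pytest.approx(ss_g / (ss_g + rss_full), abs=1e-8)
        assert 0 <= res.effect_size <= 1

    def test_ss_decomposition_adds_up(self, simulated):
        y, g, x = simulated
        res = ancova_group_cov(y, g, x)["group"]
        ss = res.extra["ss"]
        # Type-II group SS equals the increment over the covariate-only model
        ss_g, ss_x, rss_full = ancova_ss_oracle(y, g, x)
        assert ss["C(g)"] == pytest.approx(ss_g, abs=1e-8)
        assert ss["x"] == pytest.approx(ss_x, abs=1e-8)
        assert ss["Residual"] == pytest.approx(rss_full, abs=1e-8)

    def test_identical_groups_null(self, rng):
        y = np.tile(rng.normal(size=50), 2)
        g = np.repeat(["a", "b"], 50)
        x = np.tile(rng.normal(size=50), 2)
        res = ancova_group_cov(y, g, x)
        assert res["group"].statistic == pytest.approx(0, abs=1e-9)
        means = res["adjusted_means"].extra["means"]
        assert means["a"] == pytest.approx(means["b"], abs=1e-9)

    def test_orthogonal_covariate_leaves_means(self, rng):
        n = 100
        g = np.repeat(["a", "b"], n // 2)
        y = rng.normal(size=n) + 1.0 * (g == "b")
        x = np.tile([-1.0, 1.0], n // 2)     # balanced, uncorrelated with y by design
        res = ancova_group_cov(y, g, x)
        means = res["adjusted_means"].extra["means"]
        raw_a, raw_b = y[g == "a"].mean(), y[g == "b"].mean()
        assert means["a"] == pytest.approx(raw_a, abs=0.05)
        assert means["b"] == pytest.approx(raw_b, abs=0.05)

    def test_interaction_reported_separately(self, simulated):
        y, g, x = simulated
        res = ancova_group_cov(y, g, x)
        assert "interaction" in res
        assert 0 <= res["interaction"].p_value <= 1

    def test_constant_covariate_degrades_to_anova(self, rng):
        y = rng.normal(size=20)
        g = np.repeat(["a", "b"], 10)
        res = ancova_group_cov(y, g, np.ones(20))
        assert "interaction" not in res
        assert np.isfinite(res["group"].statistic)


def kendall_oracle(x, y):
    """O(n^2) concordant/discordant/tie counting for tau-b."""
    n = len(x)
    c = d = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            c += 1
        else:
            d += 1
    n0 = n * (n - 1) / 2
    return (c - d) / math.sqrt((n0 - tx) * (n0 - ty))


class TestCorrelations:
    def test_concordant_tau_one(self):
        assert kendall_tau([1, 2, 3, 4], [10, 20, 30, 40]).statistic == pytest.approx(1)

    def test_reversed_tau_minus_one(self):
        assert kendall_tau([1, 2, 3, 4], [4, 3, 2, 1]).statistic == pytest.approx(-1)

    def test_tau_b_matches_pair_counting(self):
        x, y = [1, 2, 2, 3], [1, 3, 2, 4]
        assert kendall_tau(x, y).statistic == pytest.approx(
            kendall_oracle(x, y), abs=1e-12
        )

    def test_tau_b_ties_random_cases(self, rng):
        for _ in range(5):
            x = rng.integers(0, 4, size=12).tolist()
            y = rng.integers(0, 4, size=12).tolist()
            if len(set(x)) == 1 or len(set(y)) == 1:
                continue
            assert kendall_tau(x, y).statistic == pytest.approx(
                kendall_oracle(x, y), abs=1e-12
            )

    def test_pearson_matches_numpy(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert pearson_r(x, y).statistic == pytest.approx(
            np.corrcoef(x, y)[0, 1], abs=1e-12
        )

    def test_zero_variance_gives_nan(self):
        assert np.isnan(kendall_tau([1, 1, 1, 1], [1, 2, 3, 4]).statistic)
        assert np.isnan(pearson_r([1, 1, 1], [1, 2, 3]).statistic)


def wilcoxon_enumeration_oracle(x, alternative="greater"):
    """Exact one-tailed p by enumerating all 2^n sign assignments."""
    x = np.asarray(x, float)
    ranks = np.argsort(np.argsort(np.abs(x))) + 1.0
    w_obs = ranks[x > 0].sum()
    n = len(x)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if alternative == "greater" and w >= w_obs:
            count += 1
    return count / 2 ** n


class TestWilcoxon:
    def test_all_positive_n10_exact_p(self):
        x = np.arange(1, 11, dtype=float)
        r = wilcoxon_one_sample(x, alternative="greater")
        assert r.p_value == pytest.approx(1 / 2 ** 10, abs=1e-12)

    def test_antisymmetric_p_at_least_half(self):
        x = np.array([1.0, -1.5, 2.0, -2.5, 3.0, -3.5, 4.0, -4.5])
        r = wilcoxon_one_sample(x, alternative="greater")
        assert r.p_value >= 0.5

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            x = np.round(rng.normal(0.3, 1.0, size=10), 3)
            x = x[x != 0]
            if len(np.unique(np.abs(x))) < len(x) or len(x) < 6:
                continue
            r = wilcoxon_one_sample(x, alternative="greater")
            assert r.p_value == pytest.approx(
                wilcoxon_enumeration_oracle(x), abs=1e-12
            )

    def test_effect_size_r_convention(self):
        x = np.arange(1, 11, dtype=float)
        r = wilcoxon_one_sample(x)
        # all-positive: Z = (55 - 27.5)/sqrt(96.25), r = Z/sqrt(10)
        z = 27.5 / math.sqrt(10 * 11 * 21 / 24)
        assert r.effect_size == pytest.approx(z / math.sqrt(10), abs=1e-9)

    def test_all_zeros_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_one_sample(np.zeros(10))


class TestMixedModel:
    def _table(self, n_subj=6, n_win=30, effect=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subj):
            intercept = rng.normal(0, 0.05)
            gmd = rng.integers(2, 14)
            for w in range(n_win):
                movement = ["neither", "arm", "leg", "both"][w % 4]
                y = (
                    0.2 + intercept + effect * (movement != "neither")
                    + rng.normal(0, 0.05)
                )
                rows.append(
                    {
                        "subject": f"P{s+1}", "group": "patient", "video": 1,
                        "window": w, "t_start": 0.3 * w, "t_end": 0.3 * w + 1.5,
                        "topk_sum": y, "movement": movement, "GMD": gmd,
                    }
                )
        return pd.DataFrame(rows)

    def test_design_bookkeeping(self):
        table = self._table(3, 10)
        built, formula = build_mixed_table(table, score_columns=["GMD"])
        assert len(built) == 30
        assert built["subject"].nunique() == 3
        assert "C(movement" in formula and "gmd" in formula

    def test_single_level_drops_movement(self):
        table = self._table(3, 10)
        table["movement"] = "neither"
        _, formula = build_mixed_table(table, score_columns=["GMD"])
        assert "movement" not in formula

    def test_recovers_known_movement_effect(self):
        table = self._table(n_subj=10, n_win=40, effect=0.1, seed=3)
        results, fit = fit_mixed(table, score_columns=[], random_movement_slope=False)
        est = np.mean(
            [
                results[k].extra["estimate"]
                for k in results
                if k.startswith("C(movement")
            ]
        )
        se = max(results[k].extra["se"] for k in results if k.startswith("C(movement"))
        assert abs(est - 0.1) < 2 * se

    def test_null_movement_not_significant_on_average(self):
        # modest check in place of a full type-I sweep: median p over a few
        # null replicates should be far from 0
        ps = []
        for seed in range(8):
            table = self._table(n_subj=8, n_win=24, effect=0.0, seed=seed)
            results, _ = fit_mixed(table, score_columns=[], random_movement_slope=False)
            ps.extend(
                results[k].p_value for k in results if k.startswith("C(movement")
            )
        assert np.median(ps) > 0.1
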