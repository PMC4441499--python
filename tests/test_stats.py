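import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from erpmicro.errors import (IncompleteDesignError, InvalidArgumentError,
                             UndefinedRateError)
from erpmicro.stats import (StatMap, cluster_filter, error_rates,
                            planned_comparison, rm_anova2, t_critical,
                            vmiq_score, vmiq_total, voxelwise_paired_t)


class TestErrorRates:
    def _log(self, go_missed, nogo_pressed, n_go=80, n_nogo=80):
        rows = []
        for i in range(n_go):
            rows.append({"class": "go_target", "responded": i >= go_missed})
        for i in range(n_nogo):
            rows.append({"class": "nogo_target", "responded": i < nogo_pressed})
        return pd.DataFrame(rows)

    def test_two_missed_of_eighty(self):
        om, com = error_rates(self._log(2, 0))
        assert om == pytest.approx(2.5)
        assert com == 0.0

    def test_counts_match_bruteforce(self):
        rng = np.random.default_rng(0)
        log = self._log(int(rng.integers(0, 20)), int(rng.integers(0, 20)))
        om, com = error_rates(log)
        go = log[log["class"] == "go_target"]
        nogo = log[log["class"] == "nogo_target"]
        assert om == pytest.approx(100 * sum(~go.responded) / len(go))
        assert com == pytest.approx(100 * sum(nogo.responded) / len(nogo))

    def test_empty_class_rejected(self):
        with pytest.raises(UndefinedRateError):
            error_rates(pd.DataFrame({"class": ["go_target"], "responded": [True]}))


class TestVmiq:
    def test_extremes_span_24_to_120(self):
        assert vmiq_score(np.ones(24, dtype=int)) == 24
        assert vmiq_score(np.full(24, 5)) == 120

    def test_total_is_sum_of_perspectives(self):
        assert vmiq_total(30, 40) == 70

    def test_out_of_range_rejected(self):
        bad = np.ones(24, dtype=int)
        bad[3] = 6
        with pytest.raises(InvalidArgumentError):
            vmiq_score(bad)


def _presence(n_subjects, conditions, maps, seed=0, effect=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        base = rng.normal(100, 10)
        for ci, c in enumerate(conditions):
            for m in maps:
                val = base + rng.normal(0, 5)
                if ci == 0 and m == maps[0]:
                    val += effect
                rows.append({"subject": f"S{s}", "condition": c,
                             "template": m, "presence_ms": val})
    return pd.DataFrame(rows)


def _anova_oracle(tab):
    """Direct sums-of-squares decomposition of a two-way within design."""
    piv = tab.pivot_table(index="subject", columns=["condition", "template"],
                          values="presence_ms")
    conds = sorted(tab.condition.unique())
    maps = sorted(tab.template.unique())
    n, a, b = len(piv), len(conds), len(maps)
    Y = piv.to_numpy().reshape(n, a, b)
    grand = Y.mean()
    ss_A = n * b * ((Y.mean(axis=(0, 2)) - grand) ** 2).sum()
    ss_B = n * a * ((Y.mean(axis=(0, 1)) - grand) ** 2).sum()
    ss_S = a * b * ((Y.mean(axis=(1, 2)) - grand) ** 2).sum()
    cell_AB = Y.mean(axis=0)
    ss_AB = n * ((cell_AB - Y.mean(axis=(0, 2))[:, None]
                  - Y.mean(axis=(0, 1))[None, :] + grand) ** 2).sum()
    cell_AS = Y.mean(axis=2)
    ss_AS = b * ((cell_AS - Y.mean(axis=(1, 2))[:, None]
                  - Y.mean(axis=(0, 2))[None, :] + grand) ** 2).sum()
    cell_BS = Y.mean(axis=1)
    ss_BS = a * ((cell_BS - Y.mean(axis=(1, 2))[:, None]
                  - Y.mean(axis=(0, 1))[None, :] + grand) ** 2).sum()
    ss_tot = ((Y - grand) ** 2).sum()
    ss_ABS = ss_tot - ss_A - ss_B - ss_S - ss_AB - ss_AS - ss_BS
    F_A = (ss_A / (a - 1)) / (ss_AS / ((a - 1) * (n - 1)))
    F_B = (ss_B / (b - 1)) / (ss_BS / ((b - 1) * (n - 1)))
    F_AB = (ss_AB / ((a - 1) * (b - 1))) / (ss_ABS / ((a - 1) * (b - 1) * (n - 1)))
    return F_A, F_B, F_AB


class TestRmAnova:
    def test_interaction_df_2x3_n15(self):
        tab = _presence(15, ["go", "nogo"], [0, 1, 2], seed=1)
        res = {r.effect: r for r in rm_anova2(tab)}
        inter = res["Condition x Map"]
        assert (inter.df1, inter.df2) == (2, 28)

    def test_interaction_df_2x6_n15(self):
        tab = _presence(15, ["go", "nogo"], list(range(6)), seed=2)
        res = {r.effect: r for r in rm_anova2(tab)}
        inter = res["Condition x Map"]
        assert (inter.df1, inter.df2) == (5, 70)

    def test_f_values_match_sums_of_squares_oracle(self):
        tab = _presence(4, ["go", "nogo"], [0, 1, 2], seed=3)
        res = {r.effect: r for r in rm_anova2(tab)}
        F_A, F_B, F_AB = _anova_oracle(tab)
        assert res["Condition"].F == pytest.approx(F_A, abs=1e-9)
        assert res["Map"].F == pytest.approx(F_B, abs=1e-9)
        assert res["Condition x Map"].F == pytest.approx(F_AB, abs=1e-9)

    def test_unbalanced_design_rejected(self):
        tab = _presence(4, ["go", "nogo"], [0, 1], seed=4)
        with pytest.raises(IncompleteDesignError):
            rm_anova2(tab.iloc[:-1])

    def test_two_condition_main_effect_equals_paired_t_squared(self):
        tab = _presence(10, ["go", "nogo"], [0], seed=5, effect=8.0)
        res = {r.effect: r for r in rm_anova2(tab)}
        piv = tab.pivot_table(index="subject", columns="condition",
                              values="presence_ms")
        t, _ = sps.ttest_rel(piv["go"], piv["nogo"])
        assert res["Condition"].F == pytest.approx(t**2, abs=1e-9)


class TestPlannedComparison:
    def test_identical_presence_gives_zero_f(self):
        tab = _presence(8, ["go", "nogo"], [0], seed=6)
        piv = tab.pivot_table(index="subject", columns="condition",
                              values="presence_ms")
        tab.loc[tab.condition == "nogo", "presence_ms"] = (
            tab.loc[tab.condition == "go", "presence_ms"].to_numpy())
        res = planned_comparison(tab, 0, ("go", "nogo"))
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_f_equals_paired_t_squared(self):
        tab = _presence(15, ["go", "nogo"], [0, 1], seed=7, effect=10.0)
        res = planned_comparison(tab, 0, ("go", "nogo"))
        sub = tab[tab.template == 0]
        piv = sub.pivot_table(index="subject", columns="condition",
                              values="presence_ms")
        t, p = sps.ttest_rel(piv["go"], piv["nogo"])
        assert res.F == pytest.approx(t**2, abs=1e-9)
        assert res.p == pytest.approx(p, abs=1e-12)
        assert (res.df1, res.df2) == (1, 14)


class TestVoxelT:
    def test_identical_conditions_give_zero_t(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(15, 50))
        stat = voxelwise_paired_t(a, a.copy())
        assert np.all(stat.t[~np.isnan(stat.t)] == 0) or np.all(np.isnan(stat.t))
        assert not stat.mask.any()

    def test_critical_threshold_df14(self):
        assert round(t_critical(14, 0.05), 2) == 2.14

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(8, 5))
        b = rng.normal(size=(8, 5))
        stat = voxelwise_paired_t(a, b)
        for v in range(5):
            d = a[:, v] - b[:, v]
            t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
            assert stat.t[v] == pytest.approx(t, abs=1e-12)

    def test_zero_variance_voxel_excluded(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(6, 4))
        b = a.copy()
        b[:, 2] = a[:, 2] - 1.0  # constant difference -> zero variance
        stat = voxelwise_paired_t(a, b)
        assert 2 in stat.excluded
        assert np.isnan(stat.t[2])


def _chain_adjacency(n):
    return {i: [j for j in (i - 1, i + 1) if 0 <= j < n] for i in range(n)}


class TestClusterFilter:
    def _stat(self, tvals, t_crit=2.0):
        t = np.asarray(tvals, float)
        mask = np.abs(t) > t_crit
        return StatMap(t, np.zeros_like(t), mask, [], t_crit, 14, [])

    def test_nine_contiguous_voxels_removed(self):
        t = np.zeros(30)
        t[5:14] = 3.0  # 9 voxels
        out = cluster_filter(self._stat(t), _chain_adjacency(30), 10)
        assert not out.mask.any()

    def test_ten_contiguous_voxels_retained(self):
        t = np.zeros(30)
        t[5:15] = 3.0  # 10 voxels
        out = cluster_filter(self._stat(t), _chain_adjacency(30), 10)
        assert out.mask.sum() == 10
        assert out.clusters == [list(range(5, 15))]

    def test_opposite_signs_do_not_merge(self):
        t = np.zeros(30)
        t[5:10] = 3.0
        t[10:15] = -3.0  # adjacent but opposite sign: two 5-voxel components
        out = cluster_filter(self._stat(t), _chain_adjacency(30), 6)
        assert not out.mask.any()

    def test_matches_floodfill_oracle_on_3d_grid(self):
        rng = np.random.default_rng(3)
        shape = (6, 6, 6)
        n = np.prod(shape)
        t = np.where(rng.random(n) < 0.4, 3.0, 0.0)
        adj = {}
        for i in range(n):
            z, y, x = np.unravel_index(i, shape)
            nbrs = []
            for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                               (0, 0, 1), (0, 0, -1)):
                zz, yy, xx = z + dz, y + dy, x + dx
                if 0 <= zz < 6 and 0 <= yy < 6 and 0 <= xx < 6:
                    nbrs.append(int(np.ravel_multi_index((zz, yy, xx), shape)))
            adj[i] = nbrs
        out = cluster_filter(self._stat(t), adj, 10)
        # oracle: scipy labeling of the suprathreshold set
        from scipy import ndimage

        labels, _ = ndimage.label((t > 2.0).reshape(shape))
        oracle_mask = np.zeros(shape, bool)
        for lab in range(1, labels.max() + 1):
            comp = labels == lab
            if comp.sum() >= 10:
                oracle_mask |= comp
        np.testing.assert_array_equal(out.mask, oracle_mask.ravel())

    def test_monotone_in_min_cluster(self):
        rng = np.random.default_rng(4)
        t = np.where(rng.random(100) < 0.5, 3.0, 0.0)
        adj = _chain_adjacency(100)
        sizes = [cluster_filter(self._stat(t), adj, m).mask.sum()
                 for m in (1, 3, 5, 10)]
        assert sizes == sorted(sizes, reverse=True)


def test_null_false_positive_rate_calibrated():
    """Under H0 the per-voxel rejection rate at alpha=.05 stays within .05 +- .01."""
    rng = np.random.default_rng(5)
    a = rng.normal(size=(15, 2000))
    b = rng.normal(size=(15, 2000))
    stat = voxelwise_paired_t(a, b, alpha=0.05)
    fpr = stat.mask.mean()
    assert abs(fpr - 0.05) <= 0.01
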