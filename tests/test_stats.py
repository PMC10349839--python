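from functools import reduce

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gazefield import (
    SummaryGroup,
    generalized_eta_sq,
    min_detectable_d,
    mixed_anova,
    paired_t,
    welch_t,
)
from gazefield.stats import two_sample_power


def tidy_from_array(y):
    """Tidy frame from a (G, S, A[, B]) array of cell means."""
    rows = []
    it = np.ndindex(*y.shape)
    for idx in it:
        row = dict(
            group=f"g{idx[0]}",
            participant_id=f"g{idx[0]}s{idx[1]}",
            condition=f"c{idx[2]}",
            value=float(y[idx]),
        )
        if len(idx) == 4:
            row["bin"] = f"b{idx[3]}"
        rows.append(row)
    return pd.DataFrame(rows)


def projection_ss(y, effect_axes):
    """Independent oracle: SS of a (pure) factorial effect via orthogonal
    projection onto kron-structured contrast subspaces."""
    mats = []
    for ax, k in enumerate(y.shape):
        if ax in effect_axes:
            C = np.eye(k) - np.ones((k, k)) / k
            # any basis of the contrast space
            q, r = np.linalg.qr(C)
            mats.append(q[:, : k - 1])
        else:
            mats.append(np.ones((k, 1)) / np.sqrt(k))
    X = reduce(np.kron, mats)
    v = y.ravel(order="C")
    coef, *_ = np.linalg.lstsq(X, v, rcond=None)
    proj = X @ coef
    return float(proj @ proj)


def oracle_table(y, within_names):
    """Full split-plot SS oracle built on projection_ss, pooling nested
    subject terms exactly as the split-plot decomposition requires."""
    g, n = y.shape[:2]
    ss = {}
    ss["group"] = projection_ss(y, (0,))
    strata = {"subjects": projection_ss(y, (1,)) + projection_ss(y, (0, 1))}
    for k, w in enumerate(within_names):
        ax = 2 + k
        ss[w] = projection_ss(y, (ax,))
        ss[f"group x {w}"] = projection_ss(y, (0, ax))
        strata[f"{w} x subjects"] = projection_ss(y, (1, ax)) + projection_ss(
            y, (0, 1, ax)
        )
    if len(within_names) == 2:
        a, b = within_names
        ss[f"{a} x {b}"] = projection_ss(y, (2, 3))
        ss[f"group x {a} x {b}"] = projection_ss(y, (0, 2, 3))
        strata[f"{a} x {b} x subjects"] = projection_ss(y, (1, 2, 3)) + projection_ss(
            y, (0, 1, 2, 3)
        )
    return ss, strata


class TestMixedAnova:
    def test_hand_checkable_2x2_toy(self):
        # 2 groups x 2 subjects x 2 conditions, integer data
        y = np.array(
            [
                [[4.0, 6.0], [2.0, 8.0]],  # group 0: s0 (4,6), s1 (2,8)
                [[5.0, 9.0], [7.0, 11.0]],  # group 1
            ]
        )
        res = mixed_anova(
            tidy_from_array(y), dv="value", between="group", within="condition",
            subject="participant_id",
        )
        # textbook split-plot arithmetic, done explicitly:
        grand = y.mean()  # 6.5
        ss_total = ((y - grand) ** 2).sum()  # 60
        ss_group = 4 * ((y[0].mean() - grand) ** 2 + (y[1].mean() - grand) ** 2)
        subj_means = y.mean(axis=2)
        group_means = y.mean(axis=(1, 2))
        ss_subj = 2 * ((subj_means - group_means[:, None]) ** 2).sum()
        cond_means = y.mean(axis=(0, 1))
        ss_cond = 4 * ((cond_means - grand) ** 2).sum()
        cell = y.mean(axis=1)
        ss_gxc = 2 * (
            (cell - group_means[:, None] - cond_means[None, :] + grand) ** 2
        ).sum()
        ss_err = ss_total - ss_group - ss_subj - ss_cond - ss_gxc
        assert res.effect("group")["SS"] == pytest.approx(ss_group)
        assert res.effect("condition")["SS"] == pytest.approx(ss_cond)
        assert res.effect("group x condition")["SS"] == pytest.approx(ss_gxc)
        assert res.error_strata["subjects"][0] == pytest.approx(ss_subj)
        assert res.error_strata["condition x subjects"][0] == pytest.approx(ss_err)
        # and the generalized effect size against its definition
        ges = ss_cond / (ss_cond + ss_subj + ss_err)
        assert generalized_eta_sq(res, "condition") == pytest.approx(ges)

    def test_equal_group_cell_means_give_zero_group_effect(self, rng):
        base = rng.normal(size=(1, 4, 3))
        y = np.concatenate([base + [[[0]]], base + [[[0]]]], axis=0)
        # add subject-specific offsets so data are not degenerate
        y = y + rng.normal(scale=0.5, size=(2, 4, 1))
        # force group means equal cell-by-cell
        y[1] = y[1] - y[1].mean(axis=0, keepdims=True) + y[0].mean(axis=0, keepdims=True)
        res = mixed_anova(
            tidy_from_array(y), dv="value", between="group", within="condition",
            subject="participant_id",
        )
        assert res.effect("group")["SS"] == pytest.approx(0.0, abs=1e-18)
        assert res.effect("group")["F"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("shape", [(2, 3, 3), (2, 6, 3), (2, 4, 3, 5), (2, 6, 2, 4)])
    def test_matches_projection_oracle_on_random_designs(self, shape, rng):
        y = rng.normal(size=shape)
        within = ["condition"] if len(shape) == 3 else ["condition", "bin"]
        res = mixed_anova(
            tidy_from_array(y), dv="value", between="group", within=within,
            subject="participant_id",
        )
        ss_oracle, strata_oracle = oracle_table(y, within)
        for name, ss in ss_oracle.items():
            assert res.effect(name)["SS"] == pytest.approx(ss, abs=1e-9), name
        for name, ss in strata_oracle.items():
            assert res.error_strata[name][0] == pytest.approx(ss, abs=1e-9), name

    def test_ss_additivity(self, rng):
        y = rng.normal(size=(2, 5, 3, 4))
        res = mixed_anova(
            tidy_from_array(y), dv="value", between="group",
            within=["condition", "bin"], subject="participant_id",
        )
        total = float(((y - y.mean()) ** 2).sum())
        parts = res.table["SS"].sum() + sum(s for s, _ in res.error_strata.values())
        assert parts == pytest.approx(total, abs=1e-9)

    def test_dfs_match_design_algebra(self, rng):
        y = rng.normal(size=(2, 15, 3, 5))
        res = mixed_anova(
            tidy_from_array(y), dv="value", between="group",
            within=["condition", "bin"], subject="participant_id",
        )
        assert res.effect("condition")["df"] == 2
        assert res.error_strata["condition x subjects"][1] == 56
        assert res.effect("bin")["df"] == 4
        assert res.error_strata["bin x subjects"][1] == 112
        assert res.error_strata["condition x bin x subjects"][1] == 224

    def test_agrees_with_pingouin_mixed_anova(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.normal(size=(2, 8, 3))
        df = tidy_from_array(y)
        mine = mixed_anova(
            df, dv="value", between="group", within="condition",
            subject="participant_id",
        )
        theirs = pg.mixed_anova(
            data=df, dv="value", within="condition", between="group",
            subject="participant_id",
        ).set_index("Source")
        assert mine.effect("group")["F"] == pytest.approx(theirs.loc["group", "F"])
        assert mine.effect("condition")["F"] == pytest.approx(
            theirs.loc["condition", "F"]
        )
        assert mine.effect("group x condition")["F"] == pytest.approx(
            theirs.loc["Interaction", "F"]
        )

    def test_unbalanced_data_rejected(self, rng):
        y = rng.normal(size=(2, 4, 3))
        df = tidy_from_array(y).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            mixed_anova(df, dv="value", between="group", within="condition",
                        subject="participant_id")

    def test_ges_bounds_and_zero_iff_no_effect(self, rng):
        y = rng.normal(size=(2, 5, 3))
        res = mixed_anova(tidy_from_array(y), dv="value", between="group",
                          within="condition", subject="participant_id")
        for name in res.table["effect"]:
            v = generalized_eta_sq(res, name)
            assert 0 <= v <= 1
            assert (v == 0) == (res.effect(name)["SS"] == 0)


class TestWelch:
    def test_printed_summary_statistics(self):
        res = welch_t(SummaryGroup(1.86, 0.14, 14), SummaryGroup(0.87, 0.09, 15))
        assert res.t == pytest.approx(5.95, abs=5e-3)
        assert res.df == pytest.approx(22.42, abs=0.02)
        assert res.p < 0.001

    def test_equal_means_t_zero_p_one(self):
        res = welch_t(SummaryGroup(1.0, 0.2, 10), SummaryGroup(1.0, 0.3, 12))
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_antisymmetry(self):
        a, b = SummaryGroup(2.0, 0.2, 8), SummaryGroup(1.1, 0.4, 14)
        r1, r2 = welch_t(a, b), welch_t(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.df == pytest.approx(r2.df)
        assert r1.p == pytest.approx(r2.p)

    def test_equal_n_equal_se_reduces_to_pooled_df(self):
        res = welch_t(SummaryGroup(1.5, 0.2, 9), SummaryGroup(1.0, 0.2, 9))
        assert res.df == pytest.approx(2 * (9 - 1))

    def test_invalid_summaries_rejected(self):
        with pytest.raises(ValueError):
            SummaryGroup(1.0, 0.0, 10)
        with pytest.raises(ValueError):
            SummaryGroup(1.0, 0.1, 1)


class TestPairedT:
    def test_hand_arithmetic(self):
        res = paired_t([2, 4, 6, 8], [1, 2, 3, 4])
        # differences (1,2,3,4): mean 2.5, sd 1.29099, t = 2.5/(1.29099/2)
        assert res.t == pytest.approx(3.873, abs=1e-3)
        assert res.df == 3

    def test_zero_variance_differences_raise(self):
        with pytest.raises(ValueError):
            paired_t([1, 2, 3], [0, 1, 2])

    def test_swap_flips_sign_keeps_p(self):
        x, y = [3.0, 5.0, 4.0, 7.0], [2.0, 6.0, 1.0, 3.0]
        r1, r2 = paired_t(x, y), paired_t(y, x)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_p_values_uniform_under_null(self, rng):
        ps = []
        for _ in range(400):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            ps.append(paired_t(x, y).p)
        assert sps.kstest(ps, "uniform").pvalue > 1e-3


class TestPower:
    def test_fifteen_per_group_design_two_decimals(self):
        assert round(min_detectable_d(15, 0.05, 0.80), 2) == 1.06

    def test_large_n_matches_normal_approximation(self):
        approx = (sps.norm.ppf(0.975) + sps.norm.ppf(0.80)) * np.sqrt(2 / 1000)
        assert min_detectable_d(1000, 0.05, 0.80) == pytest.approx(approx, abs=2e-3)

    def test_power_at_alpha_gives_zero_effect(self):
        assert min_detectable_d(15, 0.05, 0.05) == 0.0

    def test_monotonicity(self):
        d_ns = [min_detectable_d(n, 0.05, 0.80) for n in (10, 20, 40)]
        assert d_ns[0] > d_ns[1] > d_ns[2]
        d_alphas = [min_detectable_d(15, a, 0.80) for a in (0.01, 0.05, 0.10)]
        assert d_alphas[0] > d_alphas[1] > d_alphas[2]
        d_pows = [min_detectable_d(15, 0.05, p) for p in (0.6, 0.8, 0.95)]
        assert d_pows[0] < d_pows[1] < d_pows[2]

    def test_power_function_consistency(self):
        d = min_detectable_d(15, 0.05, 0.80)
        assert two_sample_power(d, 15, 0.05) == pytest.approx(0.80, abs=1e-6)
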