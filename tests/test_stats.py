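import itertools
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from infant_erp.stats import (
    MedianSplitResult,
    NonParamResult,
    format_anova,
    independent_t,
    median_split_snr_check,
    mixed_anova,
    mixed_anova_2x2,
    mixed_anova_2x2x2,
    paired_t,
    posthoc_tests,
    scheffe_adjusted_p,
    split_half_analysis,
    wilcoxon_effect,
)
from infant_erp.study_design import ROI_LEFT_FRONTOCENTRAL, WINDOW_ANTERIOR_SHIFT

from conftest import make_epochs


def brute_force_mixed_2x2x2(y, groups):
    """Independent cell-means SS decomposition for a balanced mixed design
    with one between factor and two 2-level within factors.

    ``y``: subjects x A x B; ``groups``: per-subject labels.
    """
    N = y.shape[0]
    glv = sorted(set(groups))
    groups = np.asarray(groups)
    grand = y.mean()
    subj_mean = y.mean(axis=(1, 2))
    g_mean = {g: y[groups == g].mean() for g in glv}
    n = {g: int((groups == g).sum()) for g in glv}
    ss_G = 4 * sum(n[g] * (g_mean[g] - grand) ** 2 for g in glv)
    ss_S = 4 * ((subj_mean - grand) ** 2).sum() - ss_G
    a_mean = y.mean(axis=(0, 2))
    b_mean = y.mean(axis=(0, 1))
    ss_A = 2 * N * ((a_mean - grand) ** 2).sum()
    ss_B = 2 * N * ((b_mean - grand) ** 2).sum()
    ag = {g: y[groups == g].mean(axis=(0, 2)) for g in glv}
    bg = {g: y[groups == g].mean(axis=(0, 1)) for g in glv}
    ss_AG = 2 * sum(n[g] * ((ag[g] - a_mean - g_mean[g] + grand) ** 2).sum() for g in glv)
    ss_BG = 2 * sum(n[g] * ((bg[g] - b_mean - g_mean[g] + grand) ** 2).sum() for g in glv)
    sa = y.mean(axis=2)
    sb = y.mean(axis=1)
    ss_AS = ss_BS = 0.0
    for g in glv:
        sub = sa[groups == g]
        ss_AS += 2 * ((sub - sub.mean(axis=1, keepdims=True) - ag[g][None, :] + g_mean[g]) ** 2).sum()
        sub = sb[groups == g]
        ss_BS += 2 * ((sub - sub.mean(axis=1, keepdims=True) - bg[g][None, :] + g_mean[g]) ** 2).sum()
    ab = y.mean(axis=0)
    ss_AB = N * ((ab - a_mean[:, None] - b_mean[None, :] + grand) ** 2).sum()
    abg = {g: y[groups == g].mean(axis=0) for g in glv}
    ss_ABG = sum(
        n[g]
        * (
            (
                abg[g] - ab - ag[g][:, None] - bg[g][None, :]
                + a_mean[:, None] + b_mean[None, :] + g_mean[g] - grand
            )
            ** 2
        ).sum()
        for g in glv
    )
    ss_T = ((y - grand) ** 2).sum()
    ss_ABS = ss_T - (ss_G + ss_S + ss_A + ss_AG + ss_AS + ss_B + ss_BG + ss_BS + ss_AB + ss_ABG)
    return {
        "group": (ss_G, ss_S),
        "condition": (ss_A, ss_AS),
        "group x condition": (ss_AG, ss_AS),
        "hemisphere": (ss_B, ss_BS),
        "group x hemisphere": (ss_BG, ss_BS),
        "condition x hemisphere": (ss_AB, ss_ABS),
        "group x condition x hemisphere": (ss_ABG, ss_ABS),
    }


def long_format(y, groups):
    rows = []
    for s in range(y.shape[0]):
        for a, an in enumerate(("own", "stranger")):
            for b, bn in enumerate(("left", "right")):
                rows.append(
                    dict(subject=f"s{s}", group=groups[s], condition=an,
                         hemisphere=bn, value=y[s, a, b])
                )
    return pd.DataFrame(rows)


class TestMixedAnova2x2x2:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 4
        y = rng.normal(size=(2 * n, 2, 2))
        groups = ["ten"] * n + ["one"] * n
        oracle = brute_force_mixed_2x2x2(y, groups)
        table = mixed_anova_2x2x2(long_format(y, groups)).set_index("effect")
        for effect, (ss_eff, ss_err) in oracle.items():
            row = table.loc[effect]
            assert row["ss_effect"] == pytest.approx(ss_eff, rel=1e-8)
            assert row["ss_error"] == pytest.approx(ss_err, rel=1e-8)

    def test_constant_dv(self):
        y = np.full((8, 2, 2), 3.0)
        table = mixed_anova_2x2x2(long_format(y, ["ten"] * 4 + ["one"] * 4))
        assert (table["F"] == 0).all()
        assert (table["p"] == 1).all()

    def test_partial_eta_sq_range(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=(12, 2, 2))
        table = mixed_anova_2x2x2(long_format(y, ["ten"] * 6 + ["one"] * 6))
        assert ((table["partial_eta_sq"] >= 0) & (table["partial_eta_sq"] <= 1)).all()
        np.testing.assert_allclose(
            table["partial_eta_sq"],
            table["ss_effect"] / (table["ss_effect"] + table["ss_error"]),
        )

    def test_missing_cell_raises(self):
        rng = np.random.default_rng(0)
        df = long_format(rng.normal(size=(4, 2, 2)), ["ten", "ten", "one", "one"])
        with pytest.raises(ValueError):
            mixed_anova_2x2x2(df[~((df.subject == "s0") & (df.hemisphere == "left"))])

    def test_dfs(self):
        rng = np.random.default_rng(1)
        table = mixed_anova_2x2x2(
            long_format(rng.normal(size=(30, 2, 2)), ["ten"] * 15 + ["one"] * 15)
        )
        assert (table["df_effect"] == 1).all()
        assert (table["df_error"] == 28).all()


class TestMixedAnova2x2:
    def test_f_equals_squared_paired_t_one_group(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=10)
        y = x + 0.7 + rng.normal(size=10)
        df = pd.DataFrame(
            dict(
                subject=[f"s{i}" for i in range(10)] * 2,
                condition=["own"] * 10 + ["stranger"] * 10,
                value=np.concatenate([x, y]),
            )
        )
        table = mixed_anova(df, between=None, within=["condition"]).set_index("effect")
        t, p = sps.ttest_rel(x, y)
        assert table.loc["condition", "F"] == pytest.approx(t**2, rel=1e-10)
        assert table.loc["condition", "p"] == pytest.approx(p, rel=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        rows = []
        for g, gname in enumerate(("ten", "one")):
            for s in range(8):
                base = rng.normal()
                for c, cname in enumerate(("own", "stranger")):
                    rows.append(
                        dict(subject=f"{gname}{s}", group=gname, condition=cname,
                             value=base + 0.6 * (c == 0) * (g == 1) + rng.normal())
                    )
        df = pd.DataFrame(rows)
        ours = mixed_anova_2x2(df).set_index("effect")
        theirs = pg.mixed_anova(
            df, dv="value", within="condition", between="group", subject="subject"
        ).set_index("Source")
        for our_name, their_name in (
            ("group", "group"), ("condition", "condition"),
            ("group x condition", "Interaction"),
        ):
            assert ours.loc[our_name, "F"] == pytest.approx(theirs.loc[their_name, "F"], rel=1e-9)
            assert ours.loc[our_name, "ss_effect"] == pytest.approx(theirs.loc[their_name, "SS"], rel=1e-9)
            assert ours.loc[our_name, "partial_eta_sq"] == pytest.approx(theirs.loc[their_name, "np2"], rel=1e-9)

    def test_total_ss_decomposition(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=(10, 2))
        rows = []
        for s in range(10):
            for c, cname in enumerate(("own", "stranger")):
                rows.append(dict(subject=f"s{s}", group="ten" if s < 5 else "one",
                                 condition=cname, value=y[s, c]))
        df = pd.DataFrame(rows)
        table = mixed_anova_2x2(df).set_index("effect")
        ss_total = ((y - y.mean()) ** 2).sum()
        # between stratum error + within stratum error + all effect SS
        total = (
            table.loc["group", "ss_effect"] + table.loc["group", "ss_error"]
            + table.loc["condition", "ss_effect"]
            + table.loc["group x condition", "ss_effect"]
            + table.loc["condition", "ss_error"]
        )
        assert total == pytest.approx(ss_total, rel=1e-10)

    def test_format_report(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(10, 2))
        rows = [
            dict(subject=f"s{s}", group="ten" if s < 5 else "one",
                 condition=c, value=y[s, i])
            for s in range(10) for i, c in enumerate(("own", "stranger"))
        ]
        text = format_anova(mixed_anova_2x2(pd.DataFrame(rows)))
        assert "F(1,8)" in text and "etap2" in text


class TestCalibrationAndPower:
    def test_type_i_error_2x2(self):
        rng = np.random.default_rng(6)
        n_reps, n = 400, 6
        hits = 0
        for _ in range(n_reps):
            y = rng.normal(size=(2 * n, 2)) + rng.normal(size=(2 * n, 1))
            rows = [
                dict(subject=f"s{s}", group="ten" if s < n else "one",
                     condition=c, value=y[s, i])
                for s in range(2 * n) for i, c in enumerate(("own", "stranger"))
            ]
            table = mixed_anova_2x2(pd.DataFrame(rows)).set_index("effect")
            hits += table.loc["condition", "p"] < 0.05
        assert 0.02 <= hits / n_reps <= 0.08

    def test_power_within_effect(self):
        rng = np.random.default_rng(7)
        n_reps, n = 100, 8
        hits_name = hits_group = 0
        for _ in range(n_reps):
            y = rng.normal(size=(2 * n, 2)) + rng.normal(size=(2 * n, 1))
            y[:, 0] += 1.5  # within effect only
            rows = [
                dict(subject=f"s{s}", group="ten" if s < n else "one",
                     condition=c, value=y[s, i])
                for s in range(2 * n) for i, c in enumerate(("own", "stranger"))
            ]
            table = mixed_anova_2x2(pd.DataFrame(rows)).set_index("effect")
            hits_name += table.loc["condition", "p"] < 0.05
            hits_group += table.loc["group", "p"] < 0.05
        assert hits_name / n_reps > 0.8
        assert hits_group / n_reps < 0.2


class TestPostHoc:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_t(x, x.copy())
        assert res.statistic == 0.0 and res.p == 1.0

    def test_constant_difference_degenerate(self):
        res = paired_t(np.array([1.0, 2.0, 3.0, 4.0]), np.array([2.0, 3.0, 4.0, 5.0]))
        assert res.degenerate

    def test_paired_t_matches_scipy(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=12), rng.normal(size=12)
        res = paired_t(x, y)
        t, p = sps.ttest_rel(x, y)
        assert res.statistic == pytest.approx(t)
        assert res.p == pytest.approx(p)

    def test_independent_t_matches_scipy(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=10), rng.normal(size=14) + 0.5
        res = independent_t(x, y)
        t, p = sps.ttest_ind(x, y)
        assert res.statistic == pytest.approx(t)
        assert res.p == pytest.approx(p)

    @pytest.mark.parametrize("seed", range(5))
    def test_scheffe_never_smaller(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=10), rng.normal(size=10) + rng.normal()
        res = paired_t(x, y, n_cells=4)
        assert res.p_scheffe >= res.p - 1e-12

    def test_posthoc_on_table(self):
        rng = np.random.default_rng(10)
        rows = []
        for s in range(10):
            d = rng.normal()
            rows.append(dict(subject=f"s{s}", group="one", condition="own", value=d + 1.0))
            rows.append(dict(subject=f"s{s}", group="one", condition="stranger", value=d))
        res = posthoc_tests(pd.DataFrame(rows), group="one")
        assert res.degenerate  # constant +1 difference

    def test_scheffe_requires_cells(self):
        with pytest.raises(ValueError):
            scheffe_adjusted_p(1.0, 10, 1)


class TestWilcoxon:
    def test_all_positive(self):
        res = wilcoxon_effect(np.arange(1.0, 16.0))
        assert res.n_positive == 15 and res.n_total == 15
        assert res.p < 0.001

    def test_exact_p_matches_enumeration_n6(self):
        d = np.array([1.5, -0.4, 2.2, 0.9, -1.1, 3.0])
        res = wilcoxon_effect(d)
        ranks = sps.rankdata(np.abs(d))
        total = ranks.sum()
        w_obs = ranks[d > 0].sum()
        t_obs = min(w_obs, total - w_obs)
        count = 0
        for signs in itertools.product([0, 1], repeat=6):
            w = sum(r for r, s in zip(ranks, signs) if s)
            if min(w, total - w) <= t_obs:
                count += 1
        assert res.p == pytest.approx(count / 64)

    def test_zeros_dropped_but_counted(self):
        d = np.array([0.0, 0.0, 1.0, 2.0, -0.5])
        res = wilcoxon_effect(d)
        assert res.n_total == 5
        assert res.n_positive == 2

    def test_direction_negative(self):
        d = np.array([-1.0, -2.0, 3.0])
        res = wilcoxon_effect(d, direction="negative")
        assert res.n_positive == 2

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_effect(np.zeros(5))

    def test_z_sign_and_magnitude(self):
        # strong one-sided effect -> clearly negative z
        res = wilcoxon_effect(np.arange(1.0, 16.0))
        assert res.z < -3.0

    def test_null_calibration(self):
        rng = np.random.default_rng(11)
        n_reps = 500
        ps = np.empty(n_reps)
        for i in range(n_reps):
            ps[i] = wilcoxon_effect(rng.normal(size=15)).p
        rate = (ps < 0.05).mean()
        assert 0.02 <= rate <= 0.08
        # distribution close to uniform (conservative discreteness allowed)
        assert sps.kstest(ps, "uniform").statistic < 0.08

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(12)
        d = rng.normal(size=12)
        res = wilcoxon_effect(d)
        ref = sps.wilcoxon(d, method="exact")
        assert res.p == pytest.approx(ref.pvalue)


class TestSplitHalf:
    def _epoch_sets(self, montage, n_subjects=6, effect_second_half=0.0, seed=0):
        rng = np.random.default_rng(seed)
        sets, groups = {}, {}
        n_trials, nch = 40, len(montage.labels)
        for s in range(n_subjects):
            conds = ["own", "stranger"] * (n_trials // 2)
            data = rng.normal(scale=2.0, size=(n_trials, nch, 425))
            for i, c in enumerate(conds):
                if c == "own" and i >= n_trials // 2:
                    data[i] += effect_second_half
            sid = f"s{s}"
            sets[sid] = make_epochs(montage, data, conds)
            groups[sid] = "ten" if s < n_subjects // 2 else "one"
        return sets, groups

    def test_partition_property(self, montage):
        sets, groups = self._epoch_sets(montage)
        ep = sets["s0"]
        boundary = (max(ep.trial_indices) + 2) // 2
        first = ep.subset(np.asarray(ep.trial_indices) < boundary)
        second = ep.subset(np.asarray(ep.trial_indices) >= boundary)
        assert first.n_trials + second.n_trials == ep.n_trials
        assert set(first.trial_indices) | set(second.trial_indices) == set(ep.trial_indices)
        assert not set(first.trial_indices) & set(second.trial_indices)

    def test_stationary_effects_rarely_interact(self, montage):
        hits = 0
        reps = 10
        for rep in range(reps):
            sets, groups = self._epoch_sets(montage, seed=rep)
            anova, _ = split_half_analysis(
                sets, groups, [ROI_LEFT_FRONTOCENTRAL], WINDOW_ANTERIOR_SHIFT
            )
            p = anova.set_index("effect").loc["condition x half", "p"]
            hits += p < 0.05
        assert hits <= 2

    def test_second_half_effect_detected(self, montage):
        sets, groups = self._epoch_sets(montage, n_subjects=8, effect_second_half=5.0, seed=42)
        anova, _ = split_half_analysis(
            sets, groups, [ROI_LEFT_FRONTOCENTRAL], WINDOW_ANTERIOR_SHIFT
        )
        p = anova.set_index("effect").loc["condition x half", "p"]
        assert p < 0.05

    def test_min_trials_enforced(self, montage):
        sets, groups = self._epoch_sets(montage, n_subjects=2)
        with pytest.raises(ValueError):
            split_half_analysis(
                sets, groups, [ROI_LEFT_FRONTOCENTRAL], WINDOW_ANTERIOR_SHIFT,
                min_trials=50,
            )

    def test_long_table_structure(self, montage):
        sets, groups = self._epoch_sets(montage, n_subjects=4)
        _, table = split_half_analysis(
            sets, groups, [ROI_LEFT_FRONTOCENTRAL], WINDOW_ANTERIOR_SHIFT
        )
        assert len(table) == 4 * 2 * 2  # subject x condition x half


class TestMedianSplit:
    def test_partition(self):
        values = {f"s{i}": float(i) for i in range(10)}
        counts = {f"s{i}": 20.0 + i for i in range(10)}
        res = median_split_snr_check(values, counts)
        assert len(res.below) + len(res.above) == 10
        assert set(res.below) | set(res.above) == set(values)

    def test_identical_values_t_zero(self):
        values = {f"s{i}": 1.0 for i in range(10)}
        counts = {f"s{i}": 20.0 + i for i in range(10)}
        res = median_split_snr_check(values, counts)
        assert res.t == 0.0 and res.p == 1.0

    def test_membership_recount(self):
        rng = np.random.default_rng(13)
        values = {f"s{i}": float(rng.normal()) for i in range(30)}
        counts = {f"s{i}": float(rng.integers(20, 80)) for i in range(30)}
        res = median_split_snr_check(values, counts)
        med = np.median(list(counts.values()))
        assert set(res.below) == {s for s, c in counts.items() if c < med}
        assert set(res.above) == {s for s, c in counts.items() if c >= med}

    def test_nonparam_result_format(self):
        res = NonParamResult(12, 15, -2.33, 0.02)
        assert "12 out of 15" in str(res)
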