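"""ANCOVA, SNK post-hoc, deviation tests, two-factor ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ratgait.stats import (
    deviation_test,
    fit_velocity_adjusted,
    oneway_anova,
    snk_posthoc,
    two_factor_anova,
)


def sim_groups(rng, means, n, slope=0.0, sd=0.5, v_mean=30.0, v_sd=3.0):
    ys, gs, vs = [], [], []
    for g, mu in means.items():
        v = rng.normal(v_mean, v_sd, n)
        ys.append(mu + slope * v + rng.normal(0, sd, n))
        gs.extend([g] * n)
        vs.append(v)
    return np.concatenate(ys), np.array(gs), np.concatenate(vs)


class TestVelocityAdjusted:
    def test_zero_slope_data_recovers_group_means(self):
        rng = np.random.default_rng(0)
        v = rng.normal(30, 3, 40)
        y = np.where(np.arange(40) < 20, 70.0, 65.0)
        g = np.where(np.arange(40) < 20, "a", "b")
        m = fit_velocity_adjusted(y, g, v)
        assert m.adjusted_means["a"] == pytest.approx(70.0, abs=1e-9)
        assert m.adjusted_means["b"] == pytest.approx(65.0, abs=1e-9)
        assert m.slope == pytest.approx(0.0, abs=1e-9)

    def test_slope_recovered_within_three_se(self):
        rng = np.random.default_rng(7)
        y, g, v = sim_groups(rng, {"a": 80.0, "b": 75.0}, n=30, slope=-0.2)
        m = fit_velocity_adjusted(y, g, v)
        assert abs(m.slope - (-0.2)) < 3 * m.slope_se

    def test_df_accounting(self):
        rng = np.random.default_rng(1)
        y, g, v = sim_groups(rng, {"a": 1.0, "b": 2.0, "c": 3.0}, n=10)
        m = fit_velocity_adjusted(y, g, v)
        assert m.df_resid == 30 - 3 - 1

    def test_constant_velocity_rejected(self):
        y = np.arange(20.0)
        g = np.repeat(["a", "b"], 10)
        with pytest.raises(ValueError, match="constant within"):
            fit_velocity_adjusted(y, g, np.full(20, 30.0))

    def test_slope_constrained_fit_reproduces_oneway_anova(self):
        rng = np.random.default_rng(5)
        y, g, v = sim_groups(rng, {"a": 70.0, "b": 66.0, "c": 72.0}, n=12)
        m = fit_velocity_adjusted(y, g, v, include_velocity=False)
        F, p, _, _ = oneway_anova(y, g)
        assert m.anova_F == pytest.approx(F, abs=1e-9)
        assert m.anova_p == pytest.approx(p, abs=1e-9)

    def test_null_simulation_false_positive_rate(self):
        """Identical groups: SNK family-wise error stays near alpha."""
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 200
        for _ in range(reps):
            y, g, v = sim_groups(rng, {"a": 70.0, "b": 70.0, "c": 70.0}, n=8)
            m = fit_velocity_adjusted(y, g, v)
            ph = snk_posthoc(m.adjusted_means, m.mse, m.df_resid, m.group_sizes)
            if ph.comparisons["significant"].any():
                rejections += 1
        rate = rejections / reps
        assert 0.005 <= rate <= 0.12


class TestSNK:
    def test_two_equal_means_not_significant(self):
        ph = snk_posthoc({"a": 5.0, "b": 5.0}, mse=1.0, df=10, sizes={"a": 6, "b": 6})
        row = ph.comparisons.iloc[0]
        assert not row["significant"]
        assert row["p"] == pytest.approx(1.0, abs=1e-9)

    def test_k2_reduces_to_two_sample_t(self):
        """For two groups SNK is algebraically a two-sample pooled t-test."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            a, b = rng.normal(0, 1, 8), rng.normal(0.8, 1, 8)
            t, p_t = sps.ttest_ind(a, b)
            sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
                len(a) + len(b) - 2
            )
            ph = snk_posthoc(
                {"a": a.mean(), "b": b.mean()},
                mse=sp2,
                df=len(a) + len(b) - 2,
                sizes={"a": len(a), "b": len(b)},
            )
            assert ph.comparisons.iloc[0]["p"] == pytest.approx(p_t, abs=1e-6)

    def test_outlier_instance_against_q_table_oracle(self):
        """Only comparisons involving the extreme mean are significant."""
        means = {"a": 10.0, "b": 10.3, "c": 10.5, "d": 16.0}
        mse, df, n = 1.0, 20, 6
        ph = snk_posthoc(means, mse, df, {k: n for k in means})
        se = np.sqrt(mse / n)
        for _, row in ph.comparisons.iterrows():
            involves_d = "d" in (row["group_a"], row["group_b"])
            if involves_d:
                # oracle: compare q statistic against the critical value directly
                q = (means["d"] - means[row["group_a"] if row["group_b"] == "d" else row["group_b"]]) / se
                qc = sps.studentized_range.ppf(0.95, row["span"], df)
                assert row["significant"] == (q > qc)
                assert row["significant"]
            else:
                assert not row["significant"]

    def test_containment_blocks_enclosed_pairs(self):
        # middle means close together; the widest span non-significant
        means = {"a": 0.0, "b": 0.05, "c": 0.1, "d": 0.15}
        ph = snk_posthoc(means, mse=1.0, df=12, sizes={k: 4 for k in means})
        assert not ph.comparisons["significant"].any()
        # enclosed pairs carry no q statistic (blocked without testing)
        spans2 = ph.comparisons[ph.comparisons["span"] < 4]
        assert spans2["q"].isna().all()

    def test_snk_at_least_as_powerful_as_tukey(self):
        """Any pair Tukey HSD rejects (critical span = k) SNK also rejects."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            mus = rng.normal(0, 2, 4)
            means = {f"g{i}": mu for i, mu in enumerate(mus)}
            mse, df, n = 1.0, 16, 5
            ph = snk_posthoc(means, mse, df, {k: n for k in means})
            se = np.sqrt(mse / n)
            q_tukey = sps.studentized_range.ppf(0.95, 4, df)
            snk_sig = {
                frozenset((r["group_a"], r["group_b"]))
                for _, r in ph.comparisons.iterrows()
                if r["significant"]
            }
            for i in range(4):
                for j in range(i + 1, 4):
                    pair = frozenset((f"g{i}", f"g{j}"))
                    if abs(mus[i] - mus[j]) / se > q_tukey:
                        assert pair in snk_sig

    def test_published_critical_values(self):
        """scipy's studentized-range quantiles agree with classical tables."""
        table = {
            (2, 10): 3.15, (3, 10): 3.88, (4, 10): 4.33,
            (2, 20): 2.95, (3, 20): 3.58, (4, 20): 3.96,
            (2, 60): 2.83, (3, 60): 3.40, (4, 60): 3.74,
        }
        for (k, df), q in table.items():
            got = sps.studentized_range.ppf(0.95, k, df)
            assert got == pytest.approx(q, abs=0.01)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            snk_posthoc({"a": 0, "b": 1}, mse=1.0, df=0, sizes={"a": 3, "b": 3})


class TestDeviationTest:
    def test_exact_match_gives_t_zero_p_one(self):
        dt = deviation_test([0.5, 0.5, 0.5], 0.5)
        assert dt.t == 0.0
        assert dt.p_adjusted == 1.0

    def test_bonferroni_cap(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.5, 0.05, 6)
        dt = deviation_test(x, 0.5, family_size=4)
        assert dt.p_adjusted <= 1.0
        assert dt.p_adjusted == pytest.approx(min(1.0, dt.p_raw * 4))

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(4)
        for fam in (1, 2, 4, 8):
            x = rng.normal(0.55, 0.03, 6)
            dt = deviation_test(x, 0.5, family_size=fam)
            assert dt.p_adjusted >= dt.p_raw
            if fam == 1:
                assert dt.p_adjusted == dt.p_raw

    def test_zero_variance_nonzero_deviation_flagged(self):
        dt = deviation_test([0.6, 0.6, 0.6], 0.5)
        assert dt.p_adjusted == 0.0
        assert dt.below_machine_floor

    def test_matches_scipy_one_sample_t(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0.53, 0.04, 6)
        dt = deviation_test(x, 0.5)
        t, p = sps.ttest_1samp(x, 0.5)
        assert dt.t == pytest.approx(t, abs=1e-12)
        assert dt.p_raw == pytest.approx(p, abs=1e-12)

    def test_type_one_error_calibration_small(self):
        """Nominal alpha under a Gaussian null (fast sanity version)."""
        rng = np.random.default_rng(13)
        rej = sum(
            deviation_test(rng.normal(0.5, 0.05, 6), 0.5).p_adjusted < 0.05
            for _ in range(400)
        )
        assert 0.02 <= rej / 400 <= 0.08


class TestTwoFactorAnova:
    def design(self, effects_g, effects_l, interaction=0.0, noise=0.0, n=4, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, eg in effects_g.items():
            for l, el in effects_l.items():
                inter = interaction if (g == "np" and l == "RH") else 0.0
                for _ in range(n):
                    rows.append((g, l, 10.0 + eg + el + inter + rng.normal(0, noise)))
        df = pd.DataFrame(rows, columns=["group", "limb", "y"])
        return df

    def test_all_equal_gives_zero_f_unit_p(self):
        df = self.design({"a": 0, "b": 0}, {"LH": 0, "RH": 0})
        table, ph = two_factor_anova(df["y"], df["group"], df["limb"])
        for term in table.index[:-1]:
            assert table.loc[term, "F"] == 0.0
            assert table.loc[term, "PR(>F)"] == 1.0
        assert not ph.comparisons["significant"].any()

    def test_additive_effects_zero_interaction_ss(self):
        df = self.design({"a": 0, "np": 2.0}, {"LH": 0, "RH": -1.0})
        table, _ = two_factor_anova(df["y"], df["group"], df["limb"])
        assert table.loc["C(group):C(limb)", "sum_sq"] == pytest.approx(0.0, abs=1e-9)

    def test_balanced_design_matches_sums_of_squares_oracle(self):
        df = self.design({"a": 0, "np": 1.5}, {"LH": 0, "RH": -0.8},
                         interaction=0.6, noise=1.0, n=5, seed=21)
        table, _ = two_factor_anova(df["y"], df["group"], df["limb"])
        # from-scratch balanced two-way decomposition
        y = df["y"].to_numpy()
        grand = y.mean()
        ss_g = sum(
            len(s) * (s.mean() - grand) ** 2 for _, s in df.groupby("group")["y"]
        )
        ss_l = sum(
            len(s) * (s.mean() - grand) ** 2 for _, s in df.groupby("limb")["y"]
        )
        cell = df.groupby(["group", "limb"])["y"]
        ss_cells = sum(len(s) * (s.mean() - grand) ** 2 for _, s in cell)
        ss_int = ss_cells - ss_g - ss_l
        ss_err = sum(((s - s.mean()) ** 2).sum() for _, s in cell)
        assert table.loc["C(group)", "sum_sq"] == pytest.approx(ss_g, abs=1e-9)
        assert table.loc["C(limb)", "sum_sq"] == pytest.approx(ss_l, abs=1e-9)
        assert table.loc["C(group):C(limb)", "sum_sq"] == pytest.approx(ss_int, abs=1e-9)
        assert table.loc["Residual", "sum_sq"] == pytest.approx(ss_err, abs=1e-9)
        # F ratios too
        f_g = (ss_g / 1) / (ss_err / (len(y) - 4))
        assert table.loc["C(group)", "F"] == pytest.approx(f_g, abs=1e-9)

    def test_empty_cell_rejected(self):
        df = self.design({"a": 0, "b": 0}, {"LH": 0, "RH": 0})
        df = df[~((df["group"] == "b") & (df["limb"] == "RH"))]
        with pytest.raises(ValueError, match="empty"):
            two_factor_anova(df["y"], df["group"], df["limb"])
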