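"""Behavioral indices against hand-computed and counting oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from priomatch.behavior import (bootstrap_condition_means, classify_groups,
                                mixed_anova, partial_eta_sq_ci,
                                response_efficiency, sdt_indices)
from conftest import make_trials


def _eff_table(scores):
    return pd.DataFrame({"subject": [f"s{i}" for i in range(len(scores))],
                         "diff_score": scores})


class TestResponseEfficiency:
    def test_efficiency_arithmetic(self):
        rows = [dict(rt_ms=600.0, accuracy=1.0) for _ in range(9)]
        rows.append(dict(rt_ms=600.0, accuracy=0.0, response="no"))
        rows += [dict(label="friend", rt_ms=650.0)] * 10
        rows += [dict(label="stranger", rt_ms=700.0)] * 10
        eff = response_efficiency(make_trials(rows))
        # mean correct RT 600, accuracy 0.9 -> E = 666.67
        assert eff["eff_self"].iloc[0] == pytest.approx(600.0 / 0.9, abs=0.01)
        # accuracy 1 -> E equals mean RT
        assert eff["eff_friend"].iloc[0] == pytest.approx(650.0)
        assert eff["diff_score"].iloc[0] == pytest.approx(600 / 0.9 - 650)

    def test_positive_diff_marks_friend_priority(self):
        rows = [dict(rt_ms=700.0)] * 5 + [dict(label="friend", rt_ms=650.0)] * 5
        rows += [dict(label="stranger")] * 5
        eff = response_efficiency(make_trials(rows))
        assert eff["diff_score"].iloc[0] == pytest.approx(50.0)

    def test_zero_accuracy_cell_flagged_undefined(self):
        rows = [dict(response="no", accuracy=0.0)] * 5
        rows += [dict(label="friend")] * 5 + [dict(label="stranger")] * 5
        eff = response_efficiency(make_trials(rows))
        assert np.isnan(eff["eff_self"].iloc[0])
        assert np.isnan(eff["diff_score"].iloc[0])

    def test_slow_trials_enter_neither_rt_nor_accuracy(self):
        rows = [dict(rt_ms=600.0)] * 4 + \
            [dict(response="none", rt_ms=np.nan, accuracy=np.nan)] * 4
        rows += [dict(label="friend")] * 4 + [dict(label="stranger")] * 4
        eff = response_efficiency(make_trials(rows))
        assert eff["acc_self"].iloc[0] == 1.0
        assert eff["rt_self"].iloc[0] == 600.0

    @given(rt=st.floats(100, 1000), acc=st.floats(0.05, 1.0),
           d_rt=st.floats(0, 200), d_acc=st.floats(0, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_efficiency_monotone_in_rt_and_accuracy(self, rt, acc, d_rt, d_acc):
        assert (rt + d_rt) / acc >= rt / acc
        assert rt / max(acc - d_acc, 0.05) >= rt / acc


class TestClassifyGroups:
    def test_hand_ranked_assignment(self):
        out = classify_groups(_eff_table([10, 5, -1, -20, -30]))
        by = out.set_index("subject")["group"]
        assert set(by[by == "FP"].index) == {"s0", "s1"}
        assert set(by[by == "SP"].index) == {"s3", "s4"}
        assert by["s2"] == "unassigned"

    def test_all_negative_scores_raise(self):
        with pytest.raises(ValueError):
            classify_groups(_eff_table([-1, -2, -3]))

    def test_sp_shortfall_raises_with_count(self):
        with pytest.raises(ValueError, match="need 3"):
            classify_groups(_eff_table([3, 2, 1, -5, -6]))

    def test_exact_zero_is_unassigned(self):
        out = classify_groups(_eff_table([4, 0.0, -9]))
        assert out.set_index("subject")["group"]["s1"] == "unassigned"

    def test_invariant_to_subject_ordering(self):
        eff = _eff_table([10, 5, -1, -20, -30])
        shuffled = eff.sample(frac=1, random_state=3)
        a = classify_groups(eff).sort_values("subject").reset_index(drop=True)
        b = classify_groups(shuffled).sort_values("subject").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
        fp = set(a[a["group"] == "FP"]["subject"])
        sp = set(a[a["group"] == "SP"]["subject"])
        assert not fp & sp


class TestSDT:
    def _trials_with_rates(self, n, hits, fas, label="self"):
        rows = []
        for i in range(n):
            rows.append(dict(label=label, match="match",
                             response="yes" if i < hits else "no"))
        for i in range(n):
            rows.append(dict(label=label, match="nonmatch",
                             response="yes" if i < fas else "no"))
        return make_trials(rows)

    def test_known_rates_give_textbook_values(self):
        """H = Phi(1), F = 0.5 -> d' = 1, beta = exp(-1/2)."""
        n = 10000
        h = int(round(stats.norm.cdf(1.0) * n))
        t = self._trials_with_rates(n, h, n // 2)
        out = sdt_indices(t)
        assert out["d_prime"].iloc[0] == pytest.approx(1.0, abs=1e-3)
        assert out["beta"].iloc[0] == pytest.approx(np.exp(-0.5), abs=1e-3)

    def test_equal_rates_give_zero_sensitivity_unit_beta(self):
        out = sdt_indices(self._trials_with_rates(40, 20, 20))
        assert out["d_prime"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["beta"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_swapping_rates_negates_dprime_and_inverts_beta(self):
        a = sdt_indices(self._trials_with_rates(50, 40, 10)).iloc[0]
        b = sdt_indices(self._trials_with_rates(50, 10, 40)).iloc[0]
        assert b["d_prime"] == pytest.approx(-a["d_prime"])
        assert b["beta"] == pytest.approx(1.0 / a["beta"])

    def test_counting_oracle_on_synthetic_cohort(self, small_cohort):
        """d'/beta equal direct tabulation of hits/FAs + formulas."""
        _, trials = small_cohort
        out = sdt_indices(trials).set_index(["subject", "label"])
        t = trials[trials["response"].isin(["yes", "no"])]
        for (subj, lab), cell in t.groupby(["subject", "label"]):
            m = cell[cell["match"] == "match"]
            nm = cell[cell["match"] == "nonmatch"]
            h = (m["response"] == "yes").sum() / len(m)
            f = (nm["response"] == "yes").sum() / len(nm)
            h = np.clip(h, 1 / (2 * len(m)), 1 - 1 / (2 * len(m)))
            f = np.clip(f, 1 / (2 * len(nm)), 1 - 1 / (2 * len(nm)))
            zh, zf = stats.norm.ppf(h), stats.norm.ppf(f)
            row = out.loc[(subj, lab)]
            assert row["d_prime"] == pytest.approx(zh - zf, abs=1e-12)
            assert row["beta"] == pytest.approx(np.exp((zf**2 - zh**2) / 2),
                                                rel=1e-12)
            assert row["beta"] > 0

    def test_extreme_rates_are_corrected(self):
        out = sdt_indices(self._trials_with_rates(20, 20, 0))
        assert np.isfinite(out["d_prime"].iloc[0])
        out_ll = sdt_indices(self._trials_with_rates(20, 20, 0),
                             correction="loglinear")
        assert np.isfinite(out_ll["d_prime"].iloc[0])

    def test_missing_cell_raises(self):
        rows = [dict(match="match")] * 5
        with pytest.raises(ValueError):
            sdt_indices(make_trials(rows))


class TestBootstrap:
    def test_degenerate_data_reproduces_point_mass(self):
        rows = [dict(subject=f"s{i}", label=lab, rt_ms=500.0)
                for i in range(4) for lab in ("self", "friend", "stranger")]
        out = bootstrap_condition_means(make_trials(rows), n_boot=50, seed=1)
        assert (out["mean_accuracy"] == 1.0).all()
        assert (out["mean_rt_ms"] == 500.0).all()

    def test_bootstrap_mean_of_means_near_sample_mean(self, small_cohort):
        _, trials = small_cohort
        out = bootstrap_condition_means(trials, n_boot=400, seed=2)
        t = trials[(trials["match"] == "match") &
                   trials["response"].isin(["yes", "no"])]
        per_subj = t.groupby(["subject", "label"])["accuracy"].mean().reset_index()
        for lab in ("self", "friend", "stranger"):
            cell = out[out["label"] == lab]["mean_accuracy"]
            target = per_subj[per_subj["label"] == lab]["accuracy"].mean()
            se = cell.std()
            assert abs(cell.mean() - target) < 3 * se / np.sqrt(len(cell)) + 1e-9

    def test_fixed_seed_reproducible(self, small_cohort):
        _, trials = small_cohort
        a = bootstrap_condition_means(trials, n_boot=20, seed=7)
        b = bootstrap_condition_means(trials, n_boot=20, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestMixedANOVA:
    def _toy(self, noise=0.0, crossed=False, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, gname in enumerate(("A", "B")):
            for s in range(3):
                for w, wname in enumerate(("w1", "w2")):
                    mu = 10 + g + w
                    if crossed:
                        mu = 10 + (w if g == 0 else 1 - w) * 4
                    rows.append(dict(subject=f"{gname}{s}", group=gname,
                                     level=wname,
                                     y=mu + noise * rng.normal()))
        return pd.DataFrame(rows)

    def test_parallel_group_profiles_give_null_interaction(self):
        out = mixed_anova(self._toy(noise=0.3), "y", "level", "group")
        aov = out["anova"].set_index("effect")
        assert aov.loc["Interaction", "F"] < stats.f.ppf(0.99, 1, 4)

    def test_crossed_means_without_noise_are_decisive(self):
        out = mixed_anova(self._toy(noise=1e-6, crossed=True), "y", "level",
                          "group")
        aov = out["anova"].set_index("effect")
        assert aov.loc["Interaction", "p"] < 1e-9

    def test_agrees_with_hand_computed_sums_of_squares(self):
        """Between-group F from the classic SS decomposition on a toy table."""
        df = self._toy(noise=1.0, seed=5)
        out = mixed_anova(df, "y", "level", "group")
        aov = out["anova"].set_index("effect")
        # hand computation: split SS into between-subject strata
        wide = df.pivot_table(index=["subject", "group"], columns="level",
                              values="y")
        subj_means = wide.mean(axis=1)
        grand = subj_means.mean()
        groups = subj_means.groupby(level="group")
        n_per, k = 3, 2
        ss_group = k * sum(len(v) * (v.mean() - grand) ** 2
                           for _, v in groups)
        ss_subj = k * sum((subj_means - subj_means.groupby(level="group")
                           .transform("mean")) ** 2)
        f_group = (ss_group / 1) / (ss_subj / 4)
        assert aov.loc["group", "F"] == pytest.approx(f_group, rel=1e-6)

    def test_eta_squared_ci_brackets_point_estimate(self):
        lo, hi = partial_eta_sq_ci(8.0, 1, 40, conf=0.90)
        eta = 8.0 / (8.0 + 40)
        assert lo <= eta <= hi
        assert 0 <= lo < hi < 1

    def test_single_level_raises(self):
        df = self._toy().query("level == 'w1'")
        with pytest.raises(ValueError):
            mixed_anova(df, "y", "level", "group")
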