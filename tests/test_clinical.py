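import numpy as np
import pandas as pd
import pytest

from hopfstrat.clinical import (
    balanced_bootstrap,
    change_scores,
    chi2_2x2,
    fit_linear_bootstrap,
    fit_logistic_bootstrap,
    nested_anova,
)
from hopfstrat.cohort import SyntheticCohortSpec, generate_behavior_only


def _brute_force_chi2(table):
    obs = np.asarray(table, float)
    total = obs.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = obs[i].sum() * obs[:, j].sum() / total
            stat += (obs[i, j] - e) ** 2 / e
    return stat


class TestChi2:
    def test_trial_allocation_worked_example(self):
        stat, df, p = chi2_2x2([[10, 10], [10, 12]])
        assert round(stat, 2) == 0.09
        assert df == 1
        assert p > 0.75

    def test_identical_row_proportions_give_zero(self):
        stat, _, p = chi2_2x2([[10, 20], [5, 10]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_perfect_association(self):
        stat, _, _ = chi2_2x2([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            table = rng.integers(1, 40, size=(2, 2))
            stat, _, _ = chi2_2x2(table)
            assert stat == pytest.approx(_brute_force_chi2(table), abs=1e-10)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi2_2x2([[0, 0], [5, 5]])


def _mini_cohort():
    """Six subjects with hand-computable medians (one item per scale shown)."""
    rows = []
    data = [
        ("s1", "sham", "DEP1", 4, 2),    # improvement +2
        ("s2", "sham", "DEP2", 3, 3),    # improvement 0
        ("s3", "sham", "DEP1", 5, 4),    # improvement +1 -> sham median 1
        ("s4", "active", "DEP1", 4, 0),  # improvement +4
        ("s5", "active", "DEP2", 2, 4),  # improvement -2
        ("s6", "active", "DEP2", 6, 1),  # improvement +5
    ]
    for sid, arm, sub, b, f in data:
        row = {"subject_id": sid, "treatment": arm, "subtype": sub,
               "age": 30, "sex": "F", "madrs1_base": b, "madrs1_fu": f}
        rows.append(row)
    return pd.DataFrame(rows)


class TestChangeScores:
    def test_hand_computed_medians(self):
        change, vs_sham = change_scores(_mini_cohort())
        assert change["madrs1"].tolist() == [-2, 0, -1, -4, 2, -5]
        # improvement = -change; sham median improvement = median(2, 0, 1) = 1
        assert vs_sham["madrs1"].tolist() == [1, -1, 0, 3, -3, 4]

    def test_all_sham_cohort_self_references_to_zero_median(self):
        df = _mini_cohort()
        df["treatment"] = "sham"
        _, vs_sham = change_scores(df)
        assert np.median(vs_sham["madrs1"]) == pytest.approx(0.0)

    def test_missing_cells_dropped_per_item(self):
        df = _mini_cohort()
        df.loc[0, "madrs1_fu"] = np.nan
        change, _ = change_scores(df)
        assert np.isnan(change["madrs1"].iloc[0])
        assert not change["madrs1"].iloc[1:].isna().any()

    def test_out_of_range_scores_rejected(self):
        df = _mini_cohort()
        df.loc[0, "madrs1_base"] = 7  # items run 0..6
        with pytest.raises(ValueError):
            change_scores(df)


class TestBalancedBootstrap:
    def _cohort(self, sizes):
        rows = []
        k = 0
        for (arm, sub), n in sizes.items():
            for _ in range(n):
                rows.append({"subject_id": f"s{k:03d}", "treatment": arm,
                             "subtype": sub, "age": 30, "sex": "M"})
                k += 1
        return pd.DataFrame(rows)

    def test_trial_cell_sizes_balance_upward(self):
        df = self._cohort({("sham", "DEP1"): 10, ("sham", "DEP2"): 10,
                           ("active", "DEP1"): 10, ("active", "DEP2"): 12})
        out = balanced_bootstrap(df, seed=1)
        sizes = out.groupby(["treatment", "subtype"]).size()
        assert sizes[("sham", "DEP1")] == 10 and sizes[("sham", "DEP2")] == 10
        assert sizes[("active", "DEP1")] == 12 and sizes[("active", "DEP2")] == 12

    def test_balanced_cohort_unchanged_in_size(self):
        df = self._cohort({("sham", "DEP1"): 5, ("sham", "DEP2"): 5,
                           ("active", "DEP1"): 6, ("active", "DEP2"): 6})
        out = balanced_bootstrap(df, seed=2)
        assert len(out) == len(df)

    def test_resampled_ids_stay_within_cell(self):
        df = self._cohort({("sham", "DEP1"): 3, ("sham", "DEP2"): 8,
                           ("active", "DEP1"): 4, ("active", "DEP2"): 4})
        out = balanced_bootstrap(df, seed=3)
        for (arm, sub), cell in out.groupby(["treatment", "subtype"]):
            orig = set(df[(df.treatment == arm) & (df.subtype == sub)].subject_id)
            assert set(cell.subject_id) <= orig

    def test_empty_cell_rejected(self):
        df = self._cohort({("sham", "DEP1"): 5, ("active", "DEP1"): 5,
                           ("active", "DEP2"): 5})
        with pytest.raises(ValueError):
            balanced_bootstrap(df, seed=4)

    def test_deterministic_given_seed(self):
        df = self._cohort({("sham", "DEP1"): 3, ("sham", "DEP2"): 7,
                           ("active", "DEP1"): 5, ("active", "DEP2"): 4})
        a = balanced_bootstrap(df, seed=5)
        b = balanced_bootstrap(df, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestLogisticBootstrap:
    def test_recovers_known_log_odds(self):
        # single strong predictor with generative log-odds 1.0 at n=500
        rng = np.random.default_rng(6)
        x = rng.standard_normal(500)
        p = 1 / (1 + np.exp(-(0.2 + 1.0 * x)))
        y = (rng.random(500) < p).astype(float)
        (res,) = fit_logistic_bootstrap(pd.DataFrame({"x": x}), y,
                                        n_boot=50, seed=7)
        assert abs(np.log(res.estimate) - 1.0) < 0.2

    def test_null_predictor_interval_covers_one(self):
        rng = np.random.default_rng(8)
        hits = 0
        for rep in range(20):
            x = rng.standard_normal(200)
            y = (rng.random(200) < 0.5).astype(float)
            (res,) = fit_logistic_bootstrap(pd.DataFrame({"x": x}), y,
                                            n_boot=200, seed=rep)
            hits += res.ci_low <= 1.0 <= res.ci_high
        assert hits >= 17  # ~95% nominal coverage

    def test_complete_separation_rejected_on_full_sample(self):
        y = np.array([0.0] * 10 + [1.0] * 10)
        with pytest.raises(ValueError):
            fit_logistic_bootstrap(pd.DataFrame({"x": y.copy()}), y,
                                   n_boot=10, seed=9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic_bootstrap(pd.DataFrame({"x": np.arange(5.0)}),
                                   np.ones(5), n_boot=10, seed=10)


class TestLinearBootstrap:
    def _covs(self, n, rng):
        return {
            "treatment": np.where(rng.random(n) < 0.5, "active", "sham"),
            "subtype": np.where(rng.random(n) < 0.5, "DEP1", "DEP2"),
            "baseline": rng.normal(30, 5, n),
            "age": rng.normal(30, 9, n),
            "sex": np.where(rng.random(n) < 0.5, "F", "M"),
        }

    def test_constant_outcome_gives_zero_slopes(self):
        rng = np.random.default_rng(11)
        c = self._covs(60, rng)
        res = fit_linear_bootstrap(np.full(60, 4.0), c["treatment"], c["subtype"],
                                   c["baseline"], c["age"], c["sex"],
                                   n_boot=50, seed=12)
        assert res.estimate == pytest.approx(0.0, abs=1e-10)

    def test_injected_interaction_detected(self):
        # effect 2.0 on the change score at trial-like n and noise
        hits = 0
        for rep in range(20):
            spec = SyntheticCohortSpec(seed=900 + rep).null_effects()
            spec.interaction_shifts = {"madrs1": 2.0}
            df = generate_behavior_only(spec)
            change = (df["madrs1_fu"] - df["madrs1_base"]).to_numpy()
            res = fit_linear_bootstrap(
                change, df["treatment"].to_numpy(), df["subtype"].to_numpy(),
                df["madrs1_base"].to_numpy(), df["age"].to_numpy(),
                df["sex"].to_numpy(), n_boot=300, seed=rep)
            hits += not (res.ci_low <= 0.0 <= res.ci_high)
        assert hits >= 16  # >= 80% power

    def test_null_interval_usually_covers_zero(self):
        hits = 0
        for rep in range(30):
            spec = SyntheticCohortSpec(seed=700 + rep).null_effects()
            df = generate_behavior_only(spec)
            change = (df["tmt_a_fu"] - df["tmt_a_base"]).to_numpy()
            res = fit_linear_bootstrap(
                change, df["treatment"].to_numpy(), df["subtype"].to_numpy(),
                df["tmt_a_base"].to_numpy(), df["age"].to_numpy(),
                df["sex"].to_numpy(), n_boot=300, seed=rep)
            hits += res.ci_low <= 0.0 <= res.ci_high
        assert hits >= 24

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(13)
        c = self._covs(40, rng)
        c["subtype"] = np.array(["DEP1"] * 40)  # subtype column constant
        with pytest.raises(ValueError, match="rank"):
            fit_linear_bootstrap(rng.normal(size=40), c["treatment"], c["subtype"],
                                 c["baseline"], c["age"], c["sex"],
                                 n_boot=10, seed=14)


class TestNestedAnova:
    def _data(self, n_per_cell, effect, noise_sd, seed):
        rng = np.random.default_rng(seed)
        rows = {"treatment": [], "subtype": [], "y": []}
        for arm in ("sham", "active"):
            for sub in ("DEP1", "DEP2"):
                mu = effect if (arm == "active" and sub == "DEP2") else 0.0
                rows["treatment"] += [arm] * n_per_cell
                rows["subtype"] += [sub] * n_per_cell
                rows["y"] += list(mu + noise_sd * rng.standard_normal(n_per_cell))
        n = 4 * n_per_cell
        return (np.array(rows["y"]), np.array(rows["treatment"]),
                np.array(rows["subtype"]), rng.normal(30, 5, n),
                np.where(rng.random(n) < 0.5, "F", "M"))

    def test_strong_within_arm_difference_detected(self):
        y, t, s, age, sex = self._data(20, effect=5.0, noise_sd=0.1, seed=15)
        F, df1, df2, p = nested_anova(y, t, s, age, sex)
        assert F > 100
        assert p < 1e-10

    def test_nested_term_has_two_degrees_of_freedom(self):
        y, t, s, age, sex = self._data(6, effect=0.0, noise_sd=1.0, seed=16)
        _, df1, df2, _ = nested_anova(y, t, s, age, sex)
        assert df1 == 2
        assert df2 == 24 - 6  # n minus full-model parameters

    def test_missing_subtype_in_arm_rejected(self):
        y, t, s, age, sex = self._data(6, effect=0.0, noise_sd=1.0, seed=17)
        s[t == "sham"] = "DEP1"
        with pytest.raises(ValueError, match="both subtypes"):
            nested_anova(y, t, s, age, sex)
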