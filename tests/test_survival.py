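"""Lifetime construction, Cox fits, Kaplan-Meier, and cluster prognosis."""

import numpy as np
import pandas as pd
import pytest

from mosbm import PlantedModel, generate_survival
from mosbm.survival import (
    BreslowCoxPH,
    build_survival_table,
    clean_stage,
    cluster_prognosis,
    compute_lifetime,
    cox_fit,
    kaplan_meier,
    upregulation_feature,
)


class TestComputeLifetime:
    def test_alive_uses_follow_up_censored(self):
        out = compute_lifetime(
            pd.Series(["Alive"]), pd.Series([400.0]), pd.Series([np.nan])
        )
        assert out.iloc[0].tolist() == [400.0, 0]

    def test_dead_uses_days_to_death_event(self):
        out = compute_lifetime(
            pd.Series(["Dead"]), pd.Series([np.nan]), pd.Series([250.0])
        )
        assert out.iloc[0].tolist() == [250.0, 1]

    def test_missing_required_field_dropped(self):
        with pytest.warns(UserWarning, match="dropped"):
            out = compute_lifetime(
                pd.Series(["Dead", "Alive"], index=["p1", "p2"]),
                pd.Series([100.0, 300.0], index=["p1", "p2"]),
                pd.Series([np.nan, np.nan], index=["p1", "p2"]),
            )
        assert out.index.tolist() == ["p2"]
        assert out.attrs["dropped"] == ["p1"]

    def test_nonpositive_lifetime_dropped(self):
        with pytest.warns(UserWarning):
            out = compute_lifetime(
                pd.Series(["Dead"]), pd.Series([np.nan]), pd.Series([0.0])
            )
        assert len(out) == 0


class TestCleanStage:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("stage ia", "stage i"),
            ("stage iii", "stage iii"),
            ("Stage IIB", "stage ii"),
            ("stage iv", "stage iv"),
            ("stage x", None),
            ("not reported", None),
        ],
    )
    def test_canonicalization(self, raw, expected):
        got = clean_stage(raw)
        if expected is None:
            assert got is np.nan or (isinstance(got, float) and np.isnan(got))
        else:
            assert got == expected

    def test_gdc_aliases_accepted(self):
        clinical = pd.DataFrame(
            {
                "demographic.vital_status": ["Alive", "Dead"],
                "demographic.days_to_last_follow_up": [500.0, np.nan],
                "demographic.days_to_death": [np.nan, 200.0],
                "diagnoses.ajcc_pathologic_stage": ["Stage IA", "Stage III"],
                "demographic.gender": ["female", "female"],
            },
            index=["p1", "p2"],
        )
        table = build_survival_table(clinical)
        assert table.loc["p1", "stage"] == "stage i"
        assert table.loc["p2", "event"] == 1


class TestUpregulationFeature:
    def test_interpolated_percentile_flags_65_of_100(self):
        weights = np.arange(1, 101) / 100.0
        flags = upregulation_feature(weights)
        # 35th percentile by linear interpolation is 0.3565; strictly above
        # are 0.36 .. 1.00, i.e. 65 samples
        assert flags.sum() == 65

    def test_constant_weights_flag_nobody(self):
        with pytest.warns(UserWarning, match="constant"):
            flags = upregulation_feature(np.full(10, 0.25))
        assert flags.sum() == 0

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(0)
        w = rng.random(57)
        np.testing.assert_array_equal(
            upregulation_feature(w), upregulation_feature(np.exp(3 * w))
        )


class TestCox:
    def test_three_subject_closed_form(self):
        """Events at t=1 (x=1), t=2 (x=0), t=3 (x=1): HR solves 1 − 2u² = 0."""
        model = BreslowCoxPH().fit(pd.DataFrame({"x": [1, 0, 1]}), [1, 2, 3], [1, 1, 1])
        assert model.hazard_ratios_[0] == pytest.approx(1 / np.sqrt(2), abs=1e-6)

    def test_agrees_with_lifelines_without_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(1)
        n = 150
        x = rng.integers(0, 2, n)
        age = rng.normal(0, 1, n)
        life = rng.exponential(800 / (1 + x)) + rng.random(n) * 1e-6
        event = (rng.random(n) > 0.25).astype(int)
        df = pd.DataFrame({"lifetime": life, "event": event, "x": x, "age": age})
        ours = cox_fit(df, ["x", "age"])
        ref = CoxPHFitter().fit(df, duration_col="lifetime", event_col="event")
        np.testing.assert_allclose(ours["coef"], ref.params_.to_numpy(), atol=1e-4)
        np.testing.assert_allclose(ours["se(coef)"], ref.standard_errors_.to_numpy(), atol=1e-4)

    def test_null_recovery_hr_near_one(self):
        rng = np.random.default_rng(2)
        x = np.repeat([0, 1], 200)
        life = rng.exponential(1000, 400)
        df = pd.DataFrame({"lifetime": life, "event": 1, "x": x})
        hr = cox_fit(df, ["x"])["exp(coef)"].iloc[0]
        assert 0.8 <= hr <= 1.25

    def test_recovers_true_hazard_ratio_two(self):
        hrs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = np.repeat([0, 1], 250)
            life = rng.exponential(np.where(x, 500.0, 1000.0))
            ctime = rng.uniform(0, 3500.0, 500)  # independent, ~20% censored
            obs = np.minimum(life, ctime)
            df = pd.DataFrame({"lifetime": obs, "event": (life <= ctime).astype(int), "x": x})
            hrs.append(cox_fit(df, ["x"])["exp(coef)"].iloc[0])
        assert np.mean(hrs) == pytest.approx(2.0, rel=0.1)

    def test_time_shift_and_rescale_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, 100)
        life = rng.exponential(100 / (1 + x))
        df = pd.DataFrame({"lifetime": life, "event": 1, "x": x})
        base = cox_fit(df, ["x"])["coef"].iloc[0]
        shifted = df.assign(lifetime=df["lifetime"] + 77.0)
        scaled = df.assign(lifetime=df["lifetime"] * 365.25)
        assert cox_fit(shifted, ["x"])["coef"].iloc[0] == pytest.approx(base, abs=1e-8)
        assert cox_fit(scaled, ["x"])["coef"].iloc[0] == pytest.approx(base, abs=1e-8)

    def test_separation_raises_naming_covariate(self):
        # flagged subjects all die first: monotone likelihood
        df = pd.DataFrame(
            {"lifetime": [1, 2, 3, 10, 11, 12], "event": 1, "bad": [1, 1, 1, 0, 0, 0]}
        )
        with pytest.raises(RuntimeError, match="bad"):
            cox_fit(df, ["bad"])

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"lifetime": [1, 2, 3], "event": 1, "c": [1, 1, 1]})
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, ["c"])


class TestKaplanMeier:
    def test_no_censoring_steps(self):
        df = pd.DataFrame({"lifetime": [1.0, 2.0, 3.0, 4.0], "event": 1})
        curve = kaplan_meier(df)["all"]
        surv = dict(zip(curve["time"], curve["survival"]))
        assert surv[1.0] == pytest.approx(0.75)
        assert surv[2.0] == pytest.approx(0.50)
        assert surv[3.0] == pytest.approx(0.25)
        assert surv[4.0] == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        df = pd.DataFrame({"lifetime": [5.0, 6.0, 7.0], "event": 0})
        curve = kaplan_meier(df)["all"]
        np.testing.assert_allclose(curve["survival"], 1.0)

    def test_mixed_toy_matches_hand_product_limit(self):
        # deaths at 2 (1/5 at risk→4/5), censor at 3, deaths at 5 (3 at risk),
        # censor at 7, death at 9 (1 at risk)
        df = pd.DataFrame(
            {"lifetime": [2.0, 3.0, 5.0, 7.0, 9.0, 1.0], "event": [1, 0, 1, 0, 1, 0]}
        )
        curve = kaplan_meier(df)["all"]
        surv = dict(zip(curve["time"], curve["survival"]))
        assert surv[2.0] == pytest.approx(4 / 5)
        assert surv[5.0] == pytest.approx(4 / 5 * 2 / 3)
        assert surv[9.0] == pytest.approx(0.0)

    def test_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(4)
        life = np.round(rng.exponential(100, 50), 3)
        df = pd.DataFrame({"lifetime": life, "event": 1})
        curve = kaplan_meier(df)["all"]
        for t, s in zip(curve["time"], curve["survival"]):
            if t > 0:
                assert s == pytest.approx((life > t).mean())


class TestClusterPrognosis:
    def _table(self, seed=0, n=300, multipliers=(1.0, 1.0, 4.0)):
        sizes = (n // 3, n // 3, n - 2 * (n // 3))
        model = PlantedModel(
            n_samples=n, cluster_sizes=sizes, hazard_multipliers=multipliers, seed=seed
        )
        labels = pd.Series(model.cluster_labels, index=[f"s{i}" for i in range(n)])
        return generate_survival(model, labels, seed=seed), labels

    def test_planted_poor_prognosis_cluster_strongly_negative(self):
        table, labels = self._table(seed=1)
        prog = cluster_prognosis(table, labels, seed=1)
        assert prog.loc[2, "z_score"] < -3

    def test_random_cluster_z_small(self):
        table, labels = self._table(seed=2, multipliers=(1.0, 1.0, 1.0))
        rng = np.random.default_rng(2)
        random_labels = pd.Series(rng.integers(0, 3, len(table)), index=table.index)
        prog = cluster_prognosis(table, random_labels, seed=2)
        assert (prog["z_score"].abs() < 2.5).all()

    def test_whole_cohort_z_zero(self):
        table, labels = self._table(seed=3)
        whole = pd.Series("all", index=table.index)
        prog = cluster_prognosis(table, whole, seed=3)
        assert prog.loc["all", "z_score"] == 0.0

    def test_censored_before_horizon_excluded(self):
        table = pd.DataFrame(
            {
                "lifetime": [100.0, 2000.0, 500.0, 1200.0],
                "event": [0, 0, 1, 1],
            },
            index=list("abcd"),
        )
        prog = cluster_prognosis(table, pd.Series("g", index=table.index), seed=0)
        # subject a (censored at 100 < 1095) is not evaluable
        assert prog.loc["g", "n_evaluable"] == 3
        assert prog.loc["g", "fraction_surviving"] == pytest.approx(2 / 3)
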