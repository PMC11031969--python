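import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from ceatrial.config import GeneratorConfig
from ceatrial.simulate import (
    DatasetValidationError,
    generate_trial,
    missingness_mask,
    read_dataset,
    snap_to_state,
    write_dataset,
)

from conftest import small_config


class TestGenerateTrial:
    def test_default_design_facts(self, default_dataset):
        """20 practices randomised 1:1; 58 + 315 + 671 = 1,044 patients."""
        df = default_dataset
        assert len(df) == 1044
        assert df["practice_id"].nunique() == 20
        arms = df.groupby("practice_id")["arm"].first()
        assert (arms == "intervention").sum() == 10
        assert df["cohort"].value_counts().to_dict() == {
            "older": 671, "adult": 315, "child": 58,
        }

    def test_practice_nested_in_arm(self, default_dataset):
        assert (default_dataset.groupby("practice_id")["arm"].nunique() == 1).all()

    def test_determinism(self, au_set):
        cfg = small_config(seed=11)
        a = generate_trial(cfg, au_set)
        b = generate_trial(small_config(seed=11), au_set)
        assert a.equals(b)

    def test_seed_changes_output(self, au_set):
        a = generate_trial(small_config(seed=1), au_set)
        b = generate_trial(small_config(seed=2), au_set)
        assert not a.equals(b)

    def test_certain_death(self, au_set):
        cfg = small_config(seed=5, death_prob={"child": 1.0, "adult": 1.0, "older": 1.0})
        assert generate_trial(cfg, au_set)["dead_by_24"].all()

    def test_state_codes_valid(self, default_dataset):
        observed = default_dataset["state_12"].dropna()
        for code in pd.concat([default_dataset["state_0"], observed]).unique():
            assert len(code) == 5 and set(code) <= set("12345")

    def test_config_errors(self):
        with pytest.raises(ValueError, match="practices"):
            GeneratorConfig(n_practices=50, cohort_sizes={"adult": 10}).validate()
        with pytest.raises(ValueError, match="positive"):
            GeneratorConfig(cohort_sizes={"adult": 0, "older": 0, "child": 0}).validate()
        with pytest.raises(TypeError, match="seed"):
            GeneratorConfig(seed="one").validate()


class TestStatisticalStructure:
    def test_marginal_count_means(self, au_set):
        """Empirical cohort means sit within 3 MC SEs of the configured rates
        (practice-level SE, since counts are clustered)."""
        cfg = GeneratorConfig(
            seed=21, n_practices=100,
            cohort_sizes={"child": 0, "adult": 15000, "older": 0},
        )
        df = generate_trial(cfg, au_set)
        for outcome, rate in (("ed", 0.60), ("adm", 0.40), ("spec", 30.0)):
            means = df.groupby("practice_id")[f"count_{outcome}_p0"].mean()
            se = means.std(ddof=1) / np.sqrt(len(means))
            assert abs(means.mean() - rate) < 3 * se

    def test_overdispersion(self, default_dataset):
        for outcome in ("ed", "adm", "nights", "spec", "pharm"):
            col = default_dataset[f"count_{outcome}_p0"]
            assert col.var() > col.mean()

    def test_costs_track_hospital_use(self, default_dataset):
        df = default_dataset
        r = np.corrcoef(df["count_nights_p0"], df["cost_hospital_p0"])[0, 1]
        assert r > 0.8

    def test_mar_mask_reproducible_from_baseline_utility(self, au_set):
        """The missingness mask is a function of (u0, seed) alone."""
        cfg = small_config(seed=9)
        df = generate_trial(cfg, au_set)
        u0 = df["state_0"].map(au_set.utilities).to_numpy(dtype=float)
        mask = missingness_mask(u0, cfg.missing_prob_coefs, cfg.seed)
        assert np.array_equal(df["state_12"].isna().to_numpy(), mask)
        # disabling missingness changes nothing else
        cfg_nomiss = small_config(seed=9, missing_prob_coefs=(-np.inf, 0.0))
        df_full = generate_trial(cfg_nomiss, au_set)
        assert df_full["state_12"].notna().all()
        assert df.drop(columns="state_12").equals(df_full.drop(columns="state_12"))

    def test_missingness_rate_follows_logistic_rule(self, au_set):
        cfg = GeneratorConfig(seed=33, cohort_sizes={"child": 0, "adult": 20000, "older": 0})
        df = generate_trial(cfg, au_set)
        u0 = df["state_0"].map(au_set.utilities).astype(float)
        a, b = cfg.missing_prob_coefs
        expected = expit(a + b * u0).mean()
        observed = df["state_12"].isna().mean()
        assert abs(observed - expected) < 3 * np.sqrt(expected * (1 - expected) / len(df))


class TestSnap:
    def test_snap_returns_nearest_state(self, toy_set):
        codes, utils = snap_to_state(np.array([0.97, 0.2, -5.0, 5.0]), toy_set)
        assert utils[0] == pytest.approx(0.95)  # nearest representable to 0.97
        assert utils[2] == 0.0  # truncated to the worst state
        assert codes[3] == "11111" and utils[3] == 1.0


class TestRoundTrip:
    def test_write_read_identity(self, small_dataset, tmp_path):
        path = tmp_path / "trial.csv"
        write_dataset(small_dataset, path)
        assert read_dataset(path).equals(small_dataset)

    def test_missing_state_round_trips_as_missing(self, small_dataset, tmp_path):
        path = tmp_path / "trial.csv"
        write_dataset(small_dataset, path)
        back = read_dataset(path)
        assert small_dataset["state_12"].isna().sum() > 0
        assert back["state_12"].isna().sum() == small_dataset["state_12"].isna().sum()

    def test_invalid_state_level_rejected(self, small_dataset, tmp_path):
        bad = small_dataset.copy()
        bad.loc[bad.index[2], "state_0"] = "61111"
        path = tmp_path / "bad.csv"
        bad_out = bad.copy()
        bad_out["dead_by_24"] = bad_out["dead_by_24"].astype(int)
        bad_out.to_csv(path, index=False)
        with pytest.raises(DatasetValidationError, match="state_0.*61111|61111"):
            read_dataset(path)

    def test_negative_cost_rejected_naming_row_and_field(self, small_dataset, tmp_path):
        bad = small_dataset.copy()
        bad.loc[bad.index[0], "cost_hospital_p1"] = -5.0
        path = tmp_path / "bad.csv"
        bad_out = bad.copy()
        bad_out["dead_by_24"] = bad_out["dead_by_24"].astype(int)
        bad_out.to_csv(path, index=False)
        with pytest.raises(DatasetValidationError, match="cost_hospital_p1"):
            read_dataset(path)

    def test_mixed_arm_practice_rejected(self, small_dataset):
        bad = small_dataset.copy()
        practice = bad["practice_id"].iloc[0]
        row = bad[bad["practice_id"] == practice].index[0]
        bad.loc[row, "arm"] = (
            "control" if bad.loc[row, "arm"] == "intervention" else "intervention"
        )
        with pytest.raises(DatasetValidationError, match="arm"):
            write_dataset(bad, "/dev/null")
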