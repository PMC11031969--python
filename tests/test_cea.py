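import json
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ceatrial.cea import (
    DOMINANT,
    DOMINATED,
    UNDEFINED,
    adjusted_qaly_gain,
    analyse,
    bootstrap_cea,
    build_analysis_table,
    ceac,
    cep_summary,
    default_wtp_grid,
    icer,
    run_scenarios,
)
from ceatrial.config import GeneratorConfig
from ceatrial.simulate import generate_trial

from conftest import null_irr, small_config


class TestIcer:
    def test_ratio(self):
        assert icer(1000.0, 0.05) == pytest.approx(20_000.0)

    def test_dominant_cheaper_and_more_effective(self):
        # e.g. −A$540 with +0.080 QALYs: intervention dominates usual care
        assert icer(-540.0, 0.080) == DOMINANT

    def test_dominated(self):
        assert icer(500.0, -0.01) == DOMINATED

    def test_zero_effect_undefined(self):
        assert icer(100.0, 0.0) == UNDEFINED

    def test_same_negative_signs_give_ratio(self):
        assert icer(-1000.0, -0.05) == pytest.approx(20_000.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            icer(float("nan"), 0.1)


class TestCepSummary:
    def test_all_northeast(self):
        reps = np.array([[10.0, 0.1]] * 5)
        assert cep_summary(reps)["NE"] == 1.0

    def test_four_sign_combinations(self):
        reps = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float)
        props = cep_summary(reps)
        assert props == {"NE": 0.25, "NW": 0.25, "SE": 0.25, "SW": 0.25}

    def test_higher_cost_higher_effect_is_northeast(self):
        assert cep_summary(np.array([[1237.0, 0.073]]))["NE"] == 1.0

    @given(
        st.lists(
            st.tuples(st.floats(-1e4, 1e4), st.floats(-1, 1)), min_size=1, max_size=50
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_proportions_sum_to_exactly_one(self, pairs):
        props = cep_summary(np.array(pairs, dtype=float))
        assert sum(props.values()) == 1.0


class TestCeac:
    def test_all_dominant_probability_one(self):
        reps = np.array([[-100.0, 0.05]] * 10)
        curve = ceac(reps, default_wtp_grid())
        assert np.all(curve.probability == 1.0)

    def test_symmetric_cloud_gives_half_at_threshold(self):
        # replicates symmetric around the λ=50,000 NMB boundary
        de = 0.02
        offsets = np.array([-300.0, -100.0, 100.0, 300.0])
        reps = np.column_stack([50_000 * de + offsets, np.full(4, de)])
        curve = ceac(reps, default_wtp_grid())
        assert curve.at(50_000.0) == 0.5

    def test_probability_at_zero_is_share_of_cost_saving(self, rng):
        reps = np.column_stack([rng.normal(0, 1000, 500), rng.normal(0.05, 0.02, 500)])
        curve = ceac(reps, default_wtp_grid())
        assert curve.probability[0] == (reps[:, 0] < 0).mean()

    def test_monotone_when_all_effects_positive(self, rng):
        reps = np.column_stack(
            [rng.normal(500, 1000, 400), rng.uniform(0.01, 0.1, 400)]
        )
        curve = ceac(reps, default_wtp_grid())
        assert np.all(np.diff(curve.probability) >= 0)

    def test_limits(self, rng):
        reps = np.column_stack([rng.normal(0, 1000, 500), rng.normal(0.0, 0.05, 500)])
        curve = ceac(reps, np.array([0.0, 1e9]))
        assert curve.probability[0] == (reps[:, 0] < 0).mean()
        assert curve.probability[-1] == pytest.approx((reps[:, 1] > 0).mean(), abs=0.01)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            ceac(np.array([[1.0, 1.0]]), np.array([]))

    def test_grid_contains_threshold(self):
        assert 50_000.0 in default_wtp_grid()
        assert 50_000.0 in default_wtp_grid(stop=99_500.0, step=3_000.0)


class TestBootstrap:
    def test_determinism(self, au_set, small_dataset):
        table = build_analysis_table(small_dataset, au_set)
        a = bootstrap_cea(table, B=50, seed=7)
        b = bootstrap_cea(table, B=50, seed=7)
        assert np.array_equal(a, b)
        c = bootstrap_cea(table, B=50, seed=8)
        assert not np.array_equal(a, c)

    def test_single_patient_per_arm_replicates_point_estimate(self, au_set):
        cfg = small_config(seed=2, missing_prob_coefs=(-np.inf, 0.0))
        df = generate_trial(cfg, au_set)
        pair = pd.concat(
            [
                df[(df["arm"] == a) & (df["cohort"] == "adult")].iloc[:1]
                for a in ("control", "intervention")
            ]
        )
        table = build_analysis_table(pair, au_set)
        reps = bootstrap_cea(table, B=1, seed=0)
        point_dc = (
            table.loc[table["arm"] == "intervention", "total_cost"].mean()
            - table.loc[table["arm"] == "control", "total_cost"].mean()
        )
        assert reps[0, 0] == pytest.approx(point_dc)

    def test_replicate_mean_consistent_with_point_estimate(self, au_set, default_dataset):
        table = build_analysis_table(default_dataset, au_set, payment=1000)
        res = analyse(table, B=400, seed=3)
        boot_se = res.replicates[:, 0].std(ddof=1) / np.sqrt(res.B)
        assert abs(res.replicates[:, 0].mean() - res.delta_cost) < 3 * boot_se


class TestAdjustedQalyGain:
    def test_constant_baseline_reduces_to_mean_difference(self, au_set):
        cfg = small_config(seed=6, missing_prob_coefs=(-np.inf, 0.0))
        df = generate_trial(cfg, au_set)
        table = build_analysis_table(df, au_set)
        table["u0"] = 0.5
        with pytest.warns(UserWarning):
            est, _ = adjusted_qaly_gain(table)
        unadjusted = (
            table.loc[table["arm"] == "intervention", "qaly"].mean()
            - table.loc[table["arm"] == "control", "qaly"].mean()
        )
        # up to random-effect shrinkage the estimate is the raw arm difference
        assert est == pytest.approx(unadjusted, abs=0.02)

    def test_too_few_practices_rejected(self, au_set, default_dataset):
        one_practice = default_dataset[
            default_dataset["practice_id"].isin(["PR01", "PR02"])
        ]
        table = build_analysis_table(one_practice, au_set)
        with pytest.raises(ValueError, match="practices"):
            adjusted_qaly_gain(table)

    def test_agrees_with_reml_oracle(self, tmp_path):
        """statsmodels MixedLM matches an independent lme4 REML fit."""
        rng = np.random.default_rng(42)
        n_prac, per = 12, 30
        prac = np.repeat(np.arange(n_prac), per)
        treat = (prac % 2).astype(float)
        effects = rng.normal(0, 0.1, n_prac)[prac]
        u0 = rng.normal(0.6, 0.2, n_prac * per)
        qaly = 0.5 + 0.1 * treat + 0.8 * u0 + effects + rng.normal(0, 0.2, n_prac * per)
        table = pd.DataFrame(
            {
                "practice_id": [f"PR{j:02d}" for j in prac],
                "arm": np.where(treat == 1, "intervention", "control"),
                "u0": u0,
                "qaly": qaly,
            }
        )
        est, _ = adjusted_qaly_gain(table)
        csv = tmp_path / "lmm.csv"
        table.assign(treat=treat).to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- lmer(qaly ~ treat + u0 + (1|practice_id), data=d, REML=TRUE)\n"
            f"cat(unname(fixef(m)['treat']), file='{tmp_path}/out.txt')\n"
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        oracle = float((tmp_path / "out.txt").read_text())
        assert est == pytest.approx(oracle, abs=1e-6)


class TestScenarios:
    @pytest.fixture(scope="class")
    def scenario_results(self, au_set):
        cfg = small_config(seed=13, true_irr=null_irr())
        df = generate_trial(cfg, au_set)
        return run_scenarios(
            df, au_set, decays=(0.0, 0.05, 0.15), B=100, seed=5, index_factor=1.026
        )

    def test_costs_identical_across_scenarios(self, scenario_results):
        base = scenario_results[0.0][0]
        for decay in (0.05, 0.15):
            res = scenario_results[decay][0]
            assert res.delta_cost == base.delta_cost
            assert np.array_equal(res.replicates[:, 0], base.replicates[:, 0])

    def test_effect_non_increasing_in_decay(self, scenario_results):
        gains = [scenario_results[d][0].delta_qaly for d in (0.0, 0.05, 0.15)]
        assert gains[0] >= gains[1] >= gains[2]

    def test_full_decay_still_runs(self, au_set):
        cfg = small_config(seed=14, true_irr=null_irr())
        df = generate_trial(cfg, au_set)
        results = run_scenarios(df, au_set, decays=(1.0,), B=20, seed=1)
        res = results[1.0][0]
        assert np.isfinite(res.delta_qaly)
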