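"""Generator correctness: determinism, stated models, ground-truth recovery."""

import numpy as np
import pandas as pd
import pytest

from chronofood.synthetic_data import (
    CohortConfig,
    WeightParams,
    generate_cohort,
    generate_food_log,
    generate_weight_series,
    regression_table,
    write_cohort,
)
from chronofood.eating_window import hours_since_anchor


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, named_field",
        [
            ({"n_participants": 1}, "n_participants"),
            ({"days": 0}, "days"),
            ({"typo_rate": 1.5}, "typo_rate"),
            ({"noise_sd": -1.0}, "noise_sd"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, named_field):
        with pytest.raises(ValueError, match=named_field):
            CohortConfig(**kwargs)


class TestDeterminism:
    def test_same_seed_same_cohort(self):
        cfg = dict(n_participants=8, days=4, seed=21, intervention_days=4)
        a = generate_cohort(CohortConfig(**cfg))
        b = generate_cohort(CohortConfig(**cfg))
        pd.testing.assert_frame_equal(a.participants, b.participants)
        pd.testing.assert_frame_equal(a.food_log, b.food_log)
        pd.testing.assert_frame_equal(a.outcomes, b.outcomes)
        pd.testing.assert_frame_equal(a.weights, b.weights)

    def test_different_seed_differs(self):
        a = generate_cohort(CohortConfig(n_participants=8, days=4, seed=1, simulate_trial=False))
        b = generate_cohort(CohortConfig(n_participants=8, days=4, seed=2, simulate_trial=False))
        assert not a.outcomes["bmi"].equals(b.outcomes["bmi"])


class TestOutcomeModel:
    def test_null_model_has_no_correlations(self):
        n = 400
        cohort = generate_cohort(
            CohortConfig(
                n_participants=n, days=3, seed=5, true_beta={}, noise_sd=1.0,
                simulate_trial=False,
            )
        )
        z = np.asarray(cohort.truth["design_standardized"]["age"])
        for d in ("bmi", "glucose", "hdl"):
            loc, scale = cohort.truth["outcome_log_scales"][d]
            y_std = (np.log(cohort.outcomes[d].to_numpy()) - loc) / scale
            r = np.corrcoef(z, y_std)[0, 1]
            assert abs(r) < 3 / np.sqrt(n)

    def test_ols_recovers_true_coefficient(self):
        """Least-squares on the generator's own output recovers the planted
        standardized age effect on BMI."""
        n = 500
        cohort = generate_cohort(
            CohortConfig(
                n_participants=n, days=3, seed=8,
                true_beta={"bmi": {"age": 0.5}}, noise_sd=1.0,
                simulate_trial=False,
            )
        )
        loc, scale = cohort.truth["outcome_log_scales"]["bmi"]
        y_std = (np.log(cohort.outcomes["bmi"].to_numpy()) - loc) / scale
        z = np.asarray(cohort.truth["design_standardized"]["age"])
        beta_hat = float(z @ y_std / (z @ z))
        assert beta_hat == pytest.approx(0.5, abs=0.1)

    def test_recovery_within_three_standard_errors_across_seeds(self):
        hits = 0
        n, beta = 300, 0.4
        for seed in range(10):
            cohort = generate_cohort(
                CohortConfig(
                    n_participants=n, days=2, seed=100 + seed,
                    true_beta={"glucose": {"age": beta}}, noise_sd=1.0,
                    simulate_trial=False,
                )
            )
            loc, scale = cohort.truth["outcome_log_scales"]["glucose"]
            y_std = (np.log(cohort.outcomes["glucose"].to_numpy()) - loc) / scale
            z = np.asarray(cohort.truth["design_standardized"]["age"])
            bhat = float(z @ y_std / (z @ z))
            se = float(np.std(y_std - bhat * z) / np.sqrt(z @ z))
            hits += abs(bhat - beta) <= 3 * se
        assert hits >= 9


class TestFoodLog:
    def test_clean_log_matches_lexicon_exactly(self, lexicon):
        log = generate_food_log(
            "P0", days=5, window_start=8, window_duration=12, events_per_day=6,
            lexicon=lexicon, typo_rate=0.0, seed=1, outlier_fraction=0.0,
        )
        for text in log["text"]:
            for item in text.split(", "):
                assert item in lexicon

    def test_clock_times_inside_window(self, lexicon):
        log = generate_food_log(
            "P0", days=30, window_start=8, window_duration=12, events_per_day=8,
            lexicon=lexicon, typo_rate=0.0, seed=2, outlier_fraction=0.0,
        )
        hours = [hours_since_anchor(pd.Timestamp(ts), anchor=0.0) for ts in log["timestamp"]]
        assert min(hours) >= 8.0
        assert max(hours) < 20.0

    def test_timestamps_strictly_ordered_per_day(self, lexicon):
        log = generate_food_log(
            "P0", days=20, window_start=8, window_duration=12, events_per_day=10,
            lexicon=lexicon, typo_rate=0.0, seed=3, outlier_fraction=0.0,
        )
        stamps = pd.to_datetime(log["timestamp"])
        assert stamps.is_monotonic_increasing
        assert stamps.is_unique

    def test_full_typo_rate_gives_distance_exactly_one(self, lexicon):
        from tests_support_distance import dp_levenshtein  # local oracle

        log = generate_food_log(
            "P0", days=10, window_start=8, window_duration=12, events_per_day=6,
            lexicon=lexicon, typo_rate=1.0, seed=4, outlier_fraction=0.0,
            special_rate=0.0, multi_item_rate=0.0,
        )
        for text, truth in zip(log["text"], log["true_items"]):
            assert dp_levenshtein(text, truth) == 1

    def test_empty_lexicon_rejected(self):
        with pytest.raises(ValueError):
            generate_food_log(
                "P0", days=1, window_start=8, window_duration=12, events_per_day=5,
                lexicon=[], typo_rate=0.0, seed=1,
            )

    def test_invalid_window_duration_rejected(self, lexicon):
        with pytest.raises(ValueError):
            generate_food_log(
                "P0", days=1, window_start=8, window_duration=25, events_per_day=5,
                lexicon=lexicon, typo_rate=0.0, seed=1,
            )


class TestWeightSeries:
    def test_noiseless_constant(self):
        s = generate_weight_series(80.0, 0.0, 0.0, 0.0, seed=0)
        assert np.allclose(s.weights, 80.0)

    def test_noiseless_linear_decline(self):
        s = generate_weight_series(80.0, -0.5, 0.0, 0.0, visit_times=(0, 6), seed=0)
        assert s.weights[-1] == pytest.approx(77.0)

    def test_monte_carlo_mean_matches_closed_form(self):
        """a=80, b=-0.5, c=0.02 gives E[y(6)] = 80 - 3 + 0.72 = 77.72."""
        ss = np.random.SeedSequence(99).spawn(1000)
        finals = [
            generate_weight_series(80.0, -0.5, 0.02, 0.5, seed=s).weights[-1] for s in ss
        ]
        assert np.mean(finals) == pytest.approx(77.72, abs=0.05)

    def test_non_positive_start_weight_rejected(self):
        with pytest.raises(ValueError):
            generate_weight_series(0.0, 0.0, 0.0, 0.1, seed=0)


class TestCohortIntegrity:
    def test_ids_consistent_across_tables(self, small_cohort):
        pids = set(small_cohort.participants["participant_id"])
        assert set(small_cohort.food_log["participant_id"]) <= pids
        assert set(small_cohort.outcomes["participant_id"]) == pids
        assert set(small_cohort.weights["participant_id"]) == pids

    def test_regression_table_codes_sex_numerically(self, small_cohort):
        tbl = regression_table(small_cohort)
        assert set(tbl["sex"].unique()) <= {0.0, 1.0}
        assert "bmi" in tbl.columns and "n_NOVA1" in tbl.columns

    def test_round_trip_to_disk(self, small_cohort, tmp_path):
        paths = write_cohort(small_cohort, tmp_path)
        from chronofood.io import read_event_log

        jsonl = read_event_log(paths["food_log_jsonl"])
        csv = read_event_log(paths["food_log_csv"])
        assert len(jsonl) == len(small_cohort.food_log)
        pd.testing.assert_frame_equal(jsonl, csv)
        assert paths["truth"].exists()
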