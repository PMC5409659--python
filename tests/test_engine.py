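"""Intake engine: sampling, event arithmetic, per-subject simulation, oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bioactive_intake import (
    EngineConfig,
    event_intake,
    implied_consumption,
    sample_concentration,
    subject_daily_intakes,
    summarize_intakes,
    weighted_mean,
)
from bioactive_intake.composition import ConcentrationDistribution


def dist(values, plant="Apple", compound="Epicatechin"):
    values = np.asarray(values, dtype=float)
    return ConcentrationDistribution(
        plant, compound, values, tuple(f"R{i}" for i in range(values.size))
    )


def subjects_frame(rows):
    return pd.DataFrame(rows, columns=["subject_id", "survey_weight", "n_survey_days"])


def mapped(rows):
    frame = pd.DataFrame(rows, columns=["subject_id", "day", "plant", "amount_g"])
    frame["provenance"] = "direct"
    return frame


class TestSampling:
    def test_point_mass_always_returns_the_value(self, rng):
        d = dist([640.0])
        assert all(sample_concentration(d, rng) == 640.0 for _ in range(20))

    def test_uniform_over_records_empirical_mean(self, rng):
        d = dist([100.0, 200.0, 300.0])
        draws = np.array([sample_concentration(d, rng) for _ in range(100_000)])
        se = d.values.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - 200.0) <= 3 * se

    def test_draws_are_elements_of_the_distribution(self, rng):
        d = dist([1.5, 2.5, 9.0])
        assert {sample_concentration(d, rng) for _ in range(200)} <= {1.5, 2.5, 9.0}


class TestEventIntake:
    @pytest.mark.parametrize(
        "grams, conc, mg",
        [(100.0, 640.0, 64.0), (0.0, 999.0, 0.0), (21.0, 147.0, 3.087)],
    )
    def test_unit_arithmetic(self, grams, conc, mg):
        assert event_intake(grams, conc) == pytest.approx(mg)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            event_intake(-1.0, 100.0)
        with pytest.raises(ValueError):
            event_intake(1.0, -100.0)


class TestImpliedConsumption:
    def test_cross_database_check_rounds_to_56(self):
        assert round(implied_consumption(16.0, 287.0)) == 56
        assert implied_consumption(16.0, 287.0) == pytest.approx(55.75, abs=0.005)

    def test_zero_intake_and_inverse_of_event_intake(self):
        assert implied_consumption(0.0, 287.0) == 0.0
        assert implied_consumption(64.0, 640.0) == pytest.approx(100.0)

    def test_zero_concentration_rejected(self):
        with pytest.raises(ValueError):
            implied_consumption(16.0, 0.0)


class TestSubjectDailyIntakes:
    def test_point_mass_closed_form(self):
        subjects = subjects_frame([("S1", 1.0, 4)])
        events = mapped([("S1", 1, "Apple", 100.0)])
        result = subject_daily_intakes(
            subjects, events, {("Apple", "Epicatechin"): dist([147.0])}
        )
        value = result.compound_intakes("Epicatechin")["S1"]
        assert value == pytest.approx(14.7 / 4)  # 3.675 mg/day over 4 diary days

    def test_subject_without_events_gets_zero(self):
        subjects = subjects_frame([("S1", 1.0, 4), ("S2", 1.0, 4)])
        events = mapped([("S1", 1, "Apple", 100.0)])
        result = subject_daily_intakes(
            subjects, events, {("Apple", "Epicatechin"): dist([147.0])}
        )
        assert result.compound_intakes("Epicatechin")["S2"] == 0.0

    def test_all_zero_consumption_yields_zero(self):
        subjects = subjects_frame([("S1", 1.0, 4)])
        events = mapped([("S1", 1, "Apple", 0.0)])
        result = subject_daily_intakes(
            subjects, events, {("Apple", "Epicatechin"): dist([147.0])}
        )
        assert result.compound_intakes("Epicatechin")["S1"] == 0.0

    def _three_subject_fixture(self):
        subjects = subjects_frame([("S1", 1.0, 4), ("S2", 2.0, 4), ("S3", 1.0, 4)])
        events = mapped(
            [("S1", 1, "Apple", 100.0), ("S2", 1, "Apple", 50.0), ("S2", 2, "Apple", 200.0)]
        )
        return subjects, events, {("Apple", "Epicatechin"): dist([100.0, 300.0])}

    def test_monte_carlo_matches_full_enumeration(self):
        """Enumerate every combination of concentration draws as the oracle."""
        subjects, events, dists = self._three_subject_fixture()
        values = dists[("Apple", "Epicatechin")].values
        weights = subjects["survey_weight"].to_numpy(dtype=float)

        grams = events["amount_g"].to_numpy()
        owner = events["subject_id"].to_numpy()
        pop_means = []
        for combo in itertools.product(values, repeat=len(events)):
            per_subject = {s: 0.0 for s in subjects["subject_id"]}
            for g, c, s in zip(grams, combo, owner):
                per_subject[s] += g * c / 1000.0 / 4.0
            pop_means.append(
                weighted_mean(list(per_subject.values()), weights)
            )
        enumerated = float(np.mean(pop_means))

        config = EngineConfig(seed=5, n_iterations=10_000, keep_iteration_draws=True)
        result = subject_daily_intakes(subjects, events, dists, config)
        draws = result.draws["Epicatechin"]  # (n_iter, n_subjects) mg/day
        per_iter_pop_mean = draws @ weights / weights.sum()
        mc = per_iter_pop_mean.mean()
        mc_se = per_iter_pop_mean.std(ddof=1) / np.sqrt(per_iter_pop_mean.size)
        assert abs(mc - enumerated) <= 3 * mc_se

    def test_linearity_in_concentrations_and_amounts(self):
        subjects, events, dists = self._three_subject_fixture()
        base = subject_daily_intakes(subjects, events, dists, EngineConfig(seed=11))
        scaled_dists = {
            key: dist(3.0 * d.values, d.plant_name, d.compound)
            for key, d in dists.items()
        }
        scaled = subject_daily_intakes(subjects, events, scaled_dists, EngineConfig(seed=11))
        np.testing.assert_allclose(
            scaled.per_subject["intake_mg_day"], 3.0 * base.per_subject["intake_mg_day"]
        )
        events2 = events.copy()
        events2["amount_g"] *= 3.0
        scaled_amounts = subject_daily_intakes(subjects, events2, dists, EngineConfig(seed=11))
        np.testing.assert_allclose(
            scaled_amounts.per_subject["intake_mg_day"],
            3.0 * base.per_subject["intake_mg_day"],
        )

    def test_total_population_mean_factorizes_over_consumers(self):
        subjects, events, dists = self._three_subject_fixture()
        result = subject_daily_intakes(subjects, events, dists, EngineConfig(seed=2))
        values = (
            result.compound_intakes("Epicatechin")
            .reindex(subjects["subject_id"])
            .to_numpy()
        )
        weights = subjects["survey_weight"].to_numpy(dtype=float)
        consumers = values > 0
        total_mean = weighted_mean(values, weights)
        consumer_mean = weighted_mean(values[consumers], weights[consumers])
        consumer_fraction = weights[consumers].sum() / weights.sum()
        assert total_mean == pytest.approx(consumer_mean * consumer_fraction)

    def test_same_seed_reproduces_bit_identical_tables(self):
        subjects, events, dists = self._three_subject_fixture()
        a = subject_daily_intakes(subjects, events, dists, EngineConfig(seed=31))
        b = subject_daily_intakes(subjects, events, dists, EngineConfig(seed=31))
        pd.testing.assert_frame_equal(a.per_subject, b.per_subject)
        pd.testing.assert_frame_equal(a.per_subject_food, b.per_subject_food)

    def test_per_day_and_per_event_modes_agree_on_point_mass(self):
        subjects, events, _ = self._three_subject_fixture()
        dists = {("Apple", "Epicatechin"): dist([147.0])}
        by_event = subject_daily_intakes(
            subjects, events, dists, EngineConfig(seed=1, draw_mode="event")
        )
        by_day = subject_daily_intakes(
            subjects, events, dists, EngineConfig(seed=1, draw_mode="day")
        )
        pd.testing.assert_frame_equal(by_event.per_subject, by_day.per_subject)

    def test_per_day_mode_shares_one_draw_within_a_day(self):
        # two same-day events of the same plant must use a common concentration
        subjects = subjects_frame([("S1", 1.0, 1)])
        events = mapped([("S1", 1, "Apple", 100.0), ("S1", 1, "Apple", 100.0)])
        d = {("Apple", "Epicatechin"): dist([0.0, 1000.0])}
        config = EngineConfig(seed=0, n_iterations=400, keep_iteration_draws=True)
        result = subject_daily_intakes(subjects, events, d, config, rng=np.random.default_rng(4))
        per_event = result.draws["Epicatechin"].ravel()
        config_day = EngineConfig(seed=0, n_iterations=400, draw_mode="day",
                                  keep_iteration_draws=True)
        result_day = subject_daily_intakes(
            subjects, events, d, config_day, rng=np.random.default_rng(4)
        )
        per_day = result_day.draws["Epicatechin"].ravel()
        # shared draw: totals are 0 or 200 mg only; independent draws also hit 100
        assert set(np.round(per_day, 6)) <= {0.0, 200.0}
        assert 100.0 in set(np.round(per_event, 6))


class TestSummarize:
    def test_consumers_scope_drops_zero_subjects(self):
        subjects = subjects_frame([("S1", 1.0, 1), ("S2", 1.0, 1)])
        events = mapped([("S1", 1, "Apple", 100.0)])
        dists = {("Apple", "Epicatechin"): dist([100.0])}
        result = subject_daily_intakes(subjects, events, dists, EngineConfig(seed=0))
        total = summarize_intakes(
            result, subjects, EngineConfig(seed=0, population="total"), with_se=False
        )
        consumers = summarize_intakes(
            result, subjects, EngineConfig(seed=0, population="consumers"), with_se=False
        )

        def mean_of(frame):
            sel = (frame["compound"] == "Epicatechin") & (frame["statistic"] == "mean")
            return frame.loc[sel & (frame["food"] == "(all)"), "value"].iloc[0]

        assert mean_of(total) == pytest.approx(5.0)  # (10 + 0) / 2
        assert mean_of(consumers) == pytest.approx(10.0)
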