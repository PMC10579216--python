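"""Rank-sum scoring, the end-to-end evaluation report, group signal ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import urimex as ux
from urimex.ranking import Direction

from conftest import make_table


def _scores(criterion, direction, values: dict[str, float]):
    return [
        ux.CriterionScore(m, criterion, v, direction)
        for m, v in values.items()
    ]


class TestRankCriterion:
    def test_published_repeatability_ordering(self):
        # % of compounds below the CV threshold per method, higher better
        values = {"Method 5": 82.4, "Method 3": 62.1, "Method 4": 61.9,
                  "Method 1": 54.6, "Method 2": 36.4}
        ranks = ux.rank_criterion(
            _scores("repeatability", Direction.HIGHER_BETTER, values)
        )
        assert ranks == {"Method 5": 1, "Method 3": 2, "Method 4": 3,
                         "Method 1": 4, "Method 2": 5}

    def test_competition_rank_on_ties(self):
        ranks = ux.rank_criterion(
            _scores("recovery", Direction.HIGHER_BETTER,
                    {"A": 10.0, "B": 10.0, "C": 5.0})
        )
        assert ranks == {"A": 1, "B": 1, "C": 3}

    def test_lower_better_direction(self):
        ranks = ux.rank_criterion(
            _scores("coverage", Direction.LOWER_BETTER,
                    {"A": 26.4, "B": 51.4, "C": 66.4})
        )
        assert ranks == {"A": 1, "B": 2, "C": 3}

    @given(st.integers(0, 2**31 - 1))
    def test_matches_sort_based_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"M{i}" for i in range(6)]
        values = dict(zip(labels, rng.uniform(0, 100, 6).round(3)))
        ranks = ux.rank_criterion(
            _scores("recovery", Direction.HIGHER_BETTER, values)
        )
        ordered = sorted(labels, key=lambda m: -values[m])
        for m in labels:
            # competition rank: 1 + number of strictly better methods
            assert ranks[m] == 1 + sum(values[o] > values[m] for o in labels)
        assert ranks[ordered[0]] == 1

    @given(st.permutations(list("ABCDE")))
    def test_invariant_to_input_order(self, order):
        values = {"A": 9.0, "B": 3.0, "C": 7.0, "D": 1.0, "E": 5.0}
        scores = [
            ux.CriterionScore(m, "recovery", values[m], Direction.HIGHER_BETTER)
            for m in order
        ]
        assert ux.rank_criterion(scores) == {"A": 1, "C": 2, "E": 3, "B": 4,
                                             "D": 5}

    def test_duplicate_labels_rejected(self):
        scores = _scores("recovery", Direction.HIGHER_BETTER, {"A": 1.0})
        with pytest.raises(ux.UrimexError, match="duplicate"):
            ux.rank_criterion(scores + scores)

    def test_fixed_criterion_direction_enforced(self):
        with pytest.raises(ux.UrimexError, match="lower_better"):
            ux.CriterionScore("A", "coverage", 10.0, Direction.HIGHER_BETTER)


class TestCumulativeScore:
    @pytest.mark.parametrize(
        "ranks, expected",
        [((1, 1, 1), 3), ((4, 5, 4), 13), ((4, 4, 4), 12)],
    )
    def test_rank_sums(self, ranks, expected):
        df = pd.DataFrame([ranks, (2, 2, 2)], index=["X", "Y"],
                          columns=["repeatability", "coverage", "recovery"])
        assert ux.cumulative_score(df)["X"] == expected

    @pytest.mark.parametrize(
        "fixture_name", ["table3_ranks", "table4_ranks", "table5_ranks"]
    )
    def test_published_rank_matrices_reproduce_printed_sums(self, fixture_name):
        fx = ux.load_fixture(fixture_name)
        assert ux.cumulative_score(fx.ranks) == fx.printed_cumulative

    def test_missing_cell_rejected(self):
        df = pd.DataFrame({"a": [1, 2], "b": [np.nan, 1]}, index=["X", "Y"])
        with pytest.raises(ux.UrimexError, match="missing"):
            ux.cumulative_score(df)


class TestBuildRanking:
    def test_dominant_method_scores_minimum(self):
        by_criterion = {
            "repeatability": _scores("repeatability", Direction.HIGHER_BETTER,
                                     {"A": 90.0, "B": 60.0, "C": 40.0}),
            "coverage": _scores("coverage", Direction.LOWER_BETTER,
                                {"A": 10.0, "B": 40.0, "C": 60.0}),
            "recovery": _scores("recovery", Direction.HIGHER_BETTER,
                                {"A": 80.0, "B": 50.0, "C": 30.0}),
        }
        ranking = ux.build_ranking(by_criterion)
        assert ranking.cumulative["A"] == 3
        assert ranking.ordering[0] == "A"
        assert not ranking.ties_present

    def test_adding_dominated_method_keeps_relative_order(self):
        base = {
            "repeatability": {"A": 90.0, "B": 60.0},
            "coverage": {"A": 10.0, "B": 40.0},
            "recovery": {"A": 80.0, "B": 50.0},
        }
        def rank_of(values):
            by_criterion = {
                c: _scores(c, ux.CRITERION_DIRECTIONS[c], v)
                for c, v in values.items()
            }
            order = ux.build_ranking(by_criterion).ordering
            return {m: order.index(m) for m in order}

        before = rank_of(base)
        worse = {
            "repeatability": {**base["repeatability"], "Z": 1.0},
            "coverage": {**base["coverage"], "Z": 99.0},
            "recovery": {**base["recovery"], "Z": 0.5},
        }
        after = rank_of(worse)
        assert (before["A"] < before["B"]) == (after["A"] < after["B"])
        assert after["Z"] == 2


class TestEvaluateDesign:
    def test_simulated_dominant_profile_ranks_first(self):
        strong = ux.MethodProfile(
            "Strong", {"organic_acid": 0.9, "amino_acid": 0.8, "fatty_acid": 0.9},
            default_recovery=0.9, detection_probability=0.95, replicate_cv=0.1,
        )
        weak = ux.MethodProfile(
            "Weak", {"organic_acid": 0.3, "amino_acid": 0.1, "fatty_acid": 0.3},
            default_recovery=0.2, detection_probability=0.4, replicate_cv=0.6,
        )
        middling = ux.MethodProfile(
            "Mid", {"organic_acid": 0.6, "amino_acid": 0.4, "fatty_acid": 0.6},
            default_recovery=0.5, detection_probability=0.7, replicate_cv=0.3,
        )
        cfg = ux.SimulationConfig(
            profiles=(strong, weak, middling), seed=101,
            n_compounds_per_class={"organic_acid": 30, "amino_acid": 20,
                                   "other": 20},
        )
        sim = ux.simulate_study(cfg)
        report = ux.evaluate_design(sim.table, sim.meta, cfg.spike)
        assert report.best == "Strong"
        assert report.ranking.cumulative["Strong"] == 3

    def test_fewer_than_two_arms_rejected(self, small_study):
        table, meta = small_study
        with pytest.raises(ux.UrimexError, match="2 arms"):
            ux.evaluate_design(table, meta, ux.default_spike_mixture(),
                               arms=["Method A"])

    def test_recovery_dropped_when_arm_lacks_spike_groups(self, small_study):
        table, meta = small_study
        # strip arm B's spike groups: a drying-style comparison arm
        meta = [
            m if m.method_label == "Method A"
            else ux.SampleMeta(m.sample_id, m.method_label, ux.SpikeGroup.NONE,
                               m.replicate, m.treatment_tags, m.creatinine_value)
            for m in meta
        ]
        spike = ux.SpikeMixture((
            ux.SpikeEntry("Citric acid", ux.CompoundClass.ORGANIC_ACID, 50.0),
        ))
        report = ux.evaluate_design(table, meta, spike)
        assert "recovery" not in report.criteria_used
        assert set(report.criteria_used) == {"repeatability", "coverage"}
        assert any("not assessed" in w for w in report.warnings_)

    def test_report_round_trips_to_json(self, tmp_path, small_study):
        table, meta = small_study
        spike = ux.SpikeMixture((
            ux.SpikeEntry("Citric acid", ux.CompoundClass.ORGANIC_ACID, 50.0),
        ))
        report = ux.evaluate_design(table, meta, spike)
        p = report.write_json(tmp_path / "report.json")
        import json
        payload = json.loads(p.read_text())
        assert payload["cumulative"] == {
            a: report.ranking.cumulative[a] for a in report.arms
        }


class TestGroupMeanRatio:
    def _table(self, a_vals, b_vals):
        values = [[v] for v in a_vals + b_vals]
        table = make_table(values, compounds=["Urea"])
        meta = [
            ux.SampleMeta(s, "A" if i < len(a_vals) else "B",
                          ux.SpikeGroup.NONE, i + 1)
            for i, s in enumerate(table.sample_ids)
        ]
        return table, meta

    def test_identical_groups_give_one(self):
        table, meta = self._table([2.0, 4.0], [2.0, 4.0])
        assert ux.group_mean_ratio(table, meta, "Urea", "A", "B").value == 1.0

    def test_zero_numerator(self):
        table, meta = self._table([0.0, 0.0], [2.0, 4.0])
        assert ux.group_mean_ratio(table, meta, "Urea", "A", "B").value == 0.0

    def test_zero_denominator_flagged_infinite(self):
        table, meta = self._table([1.0], [0.0])
        res = ux.group_mean_ratio(table, meta, "Urea", "A", "B")
        assert res.infinite and np.isinf(res.value)

    def test_unknown_compound_rejected(self):
        table, meta = self._table([1.0], [1.0])
        with pytest.raises(ux.UrimexError, match="not present"):
            ux.group_mean_ratio(table, meta, "Glucose", "A", "B")

    def test_noise_free_urease_attenuation_recovered(self):
        treated = ux.MethodProfile(
            "UT", {"urea": 1.0}, default_recovery=1.0,
            detection_probability=1.0, replicate_cv=0.0, urea_attenuation=0.1,
        )
        untreated = ux.MethodProfile(
            "NT", {"urea": 1.0}, default_recovery=1.0,
            detection_probability=1.0, replicate_cv=0.0,
        )
        cfg = ux.SimulationConfig(
            profiles=(treated, untreated), seed=3,
            n_compounds_per_class={"other": 3}, creatinine_sigma=0.0,
        )
        sim = ux.simulate_study(cfg)
        res = ux.group_mean_ratio(sim.table, sim.meta, "Urea", "UT", "NT")
        assert res.value == pytest.approx(0.1, abs=1e-12)

    def test_noisy_ratio_within_monte_carlo_band(self):
        """Seeded noisy studies: the urea ratio concentrates near the
        configured attenuation (Monte-Carlo interval from 500 draws)."""
        ratios = []
        for seed in range(500):
            rng = np.random.default_rng(seed)
            sigma = np.sqrt(np.log1p(0.3**2))
            noise = lambda n: np.exp(sigma * rng.standard_normal(n) - sigma**2 / 2)
            treated = 50.0 * 0.1 * noise(6)
            untreated = 50.0 * noise(6)
            ratios.append(treated.mean() / untreated.mean())
        lo, hi = np.quantile(ratios, [0.005, 0.995])
        # one pipeline run must fall inside the oracle's 99% interval
        treated = ux.MethodProfile(
            "UT", {"urea": 1.0}, default_recovery=1.0,
            detection_probability=1.0, replicate_cv=0.3, urea_attenuation=0.1,
        )
        untreated = ux.MethodProfile(
            "NT", {"urea": 1.0}, default_recovery=1.0,
            detection_probability=1.0, replicate_cv=0.3,
        )
        cfg = ux.SimulationConfig(
            profiles=(treated, untreated), seed=42,
            n_compounds_per_class={"other": 3},
        )
        sim = ux.simulate_study(cfg)
        value = ux.group_mean_ratio(sim.table, sim.meta, "Urea", "UT", "NT").value
        assert lo <= value <= hi
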