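"""ROC curves, AUC inference and fate-group comparisons."""

import numpy as np
import pytest
from scipy import stats

from tsp1apop.population import PopulationResult
from tsp1apop.roc import (
    auc_ci,
    build_feature_table,
    compare_fate_distributions,
    rank_predictors,
    roc,
)
from tsp1apop.simulation import Protocol


def pair_counting_auc(scores, labels):
    """Exhaustive positive/negative pair comparison; ties count one half."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (pos.size * neg.size)


def synthetic_population(features, labels):
    """Wrap a feature frame + labels as a minimal PopulationResult."""
    n = len(labels)
    times = np.array([0.0, 1440.0])
    cparp = np.column_stack([np.zeros(n), np.where(labels, 2.0, 0.0)])
    return PopulationResult(
        n_cells=n, ic_matrix=features, times=times, cparp_at=cparp,
        fate=np.asarray(labels, bool),
        t_threshold=np.where(labels, 700.0, np.nan),
        max_cparp=cparp[:, -1], threshold=1.05, seed=0,
        protocol=Protocol(tsp1_dose=1e-2, horizon=1440.0),
    )


class TestRocCurve:
    def test_agrees_with_pair_counting_oracle(self, rng):
        for _ in range(1000):
            n = rng.integers(6, 50)
            scores = np.round(rng.normal(size=n), 1)  # force ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert roc(scores, labels).auc == pytest.approx(
                pair_counting_auc(scores, labels), abs=1e-10
            )

    def test_perfect_separation_gives_unit_auc(self):
        scores = np.r_[np.zeros(10), np.ones(10)]
        labels = np.r_[np.zeros(10, bool), np.ones(10, bool)]
        curve = roc(scores, labels)
        assert curve.auc == 1.0
        assert curve.fpr[0] == 0.0 and curve.tpr[-1] == 1.0

    def test_independent_scores_near_half(self, rng):
        scores = rng.normal(size=20_000)
        labels = rng.random(20_000) < 0.5
        assert roc(scores, labels).auc == pytest.approx(0.5, abs=0.02)

    def test_score_negation_complements_auc(self, rng):
        scores = rng.normal(size=200)  # continuous: tie-free
        labels = rng.random(200) < 0.4
        a = roc(scores, labels).auc
        b = roc(-scores, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_auto_orientation_never_below_half(self, rng):
        for _ in range(50):
            scores = rng.normal(size=60)
            labels = rng.random(60) < 0.5
            if labels.all() or not labels.any():
                continue
            assert roc(scores, labels, orient=True).auc >= 0.5

    def test_constant_scores_flagged_degenerate(self):
        labels = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        curve = roc(np.ones(10), labels)
        assert curve.degenerate and curve.auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc(np.arange(5.0), np.ones(5, bool))


class TestAucInference:
    def test_bootstrap_ci_contains_point_estimate(self, rng):
        scores = np.r_[rng.normal(1, 1, 80), rng.normal(0, 1, 80)]
        labels = np.r_[np.ones(80, bool), np.zeros(80, bool)]
        out = auc_ci(scores, labels, seed=0)
        assert out["ci"][0] <= out["auc"] <= out["ci"][1]
        assert out["p_vs_half"] < 1e-3

    def test_perfect_separation_ci_pins_at_one(self):
        scores = np.r_[np.arange(100.0), 200.0 + np.arange(100.0)]
        labels = np.r_[np.zeros(100, bool), np.ones(100, bool)]
        out = auc_ci(scores, labels, seed=1)
        assert out["ci"][1] == 1.0
        assert out["ci"][0] > 0.99

    def test_hanley_matches_bootstrap_roughly(self, rng):
        scores = np.r_[rng.normal(0.8, 1, 150), rng.normal(0, 1, 150)]
        labels = np.r_[np.ones(150, bool), np.zeros(150, bool)]
        b = auc_ci(scores, labels, method="bootstrap", seed=2)
        h = auc_ci(scores, labels, method="hanley")
        assert b["ci"][0] == pytest.approx(h["ci"][0], abs=0.03)
        assert b["ci"][1] == pytest.approx(h["ci"][1], abs=0.03)

    def test_ci_width_shrinks_with_sample_size(self, rng):
        widths = []
        for n in (100, 400, 1600):
            scores = np.r_[rng.normal(0.5, 1, n), rng.normal(0, 1, n)]
            labels = np.r_[np.ones(n, bool), np.zeros(n, bool)]
            out = auc_ci(scores, labels, n_boot=500, seed=3)
            widths.append(out["ci"][1] - out["ci"][0])
        # roughly 1/sqrt(n): each quadrupling should halve the width
        assert widths[1] < 0.75 * widths[0]
        assert widths[2] < 0.75 * widths[1]


class TestFeatureTable:
    @pytest.fixture()
    def population(self, model, rng):
        from tsp1apop.population import sample_initial_conditions

        ics = sample_initial_conditions(model, 300, seed=21)
        parp = ics["PARP"].to_numpy()
        xiap = ics["XIAP"].to_numpy()
        labels = np.abs(parp - xiap) > np.median(np.abs(parp - xiap))
        times = np.array([0.0, 1440.0])
        cparp = np.column_stack(
            [np.zeros(300), np.where(labels, 2.0, 0.1)]
        )
        return PopulationResult(
            n_cells=300, ic_matrix=ics, times=times, cparp_at=cparp,
            fate=labels, t_threshold=np.where(labels, 600.0, np.nan),
            max_cparp=cparp[:, -1], threshold=1.05, seed=21,
            protocol=Protocol(tsp1_dose=1e-2, horizon=1440.0),
        )

    def test_nineteen_predictors(self, population):
        table = build_feature_table(population)
        assert len(table.predictor_names) == 19
        assert np.array_equal(table.labels, population.fate)

    def test_difference_feature_is_rowwise_absolute_difference(self, population):
        table = build_feature_table(population)
        expected = np.abs(
            population.ic_matrix["PARP"] - population.ic_matrix["XIAP"]
        )
        assert np.allclose(table.features["|PARP-XIAP|"], expected)

    def test_single_fate_population_rejected(self, population):
        population.fate = np.ones(population.n_cells, bool)
        with pytest.raises(ValueError):
            build_feature_table(population)

    def test_generating_feature_ranks_first(self, population):
        table = build_feature_table(population)
        ranking = rank_predictors(table, method="hanley")
        assert ranking["predictor"].iloc[0] == "|PARP-XIAP|"
        assert ranking["auc"].iloc[0] > 0.95
        noise = ranking.set_index("predictor").loc["CD36"]
        assert noise["ci_lo"] < 0.5 < noise["ci_hi"]


class TestFateComparisons:
    def test_identical_groups_not_significant(self):
        import pandas as pd

        vals = np.tile(np.linspace(0.1, 1.0, 50), 2)
        labels = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        pop = synthetic_population(pd.DataFrame({"XIAP": vals}), labels)
        out = compare_fate_distributions(pop, ["XIAP"])
        assert out["p_value"].iloc[0] > 0.9

    def test_two_sd_location_shift_detected(self, rng):
        import pandas as pd

        a = rng.gamma(5.5, 0.3 / 5.5, 500)
        b = rng.gamma(5.5, 0.3 / 5.5, 500) + 2 * 0.3 / np.sqrt(5.5)
        labels = np.r_[np.ones(500, bool), np.zeros(500, bool)]
        pop = synthetic_population(
            pd.DataFrame({"XIAP": np.r_[a, b]}), labels
        )
        out = compare_fate_distributions(pop, ["XIAP"])
        assert out["p_value"].iloc[0] < 1e-6
        welch = compare_fate_distributions(pop, ["XIAP"], test="welch")
        assert welch["p_value"].iloc[0] < 1e-6


class TestRocProperties:
    """Derandomized property checks over generated score/label instances."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    @given(
        scores=st.lists(
            st.integers(min_value=-5, max_value=5), min_size=4, max_size=30
        ),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_auc_matches_pair_counting_for_any_tied_scores(scores, seed):
        scores = np.asarray(scores, float)
        labels = np.random.default_rng(seed).random(len(scores)) < 0.5
        if labels.all() or not labels.any():
            return
        assert roc(scores, labels).auc == pytest.approx(
            pair_counting_auc(scores, labels), abs=1e-10
        )

    @staticmethod
    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_orientation_complement_identity(seed):
        rng_ = np.random.default_rng(seed)
        scores = rng_.normal(size=50)
        labels = rng_.random(50) < 0.5
        if labels.all() or not labels.any():
            return
        assert roc(scores, labels).auc + roc(-scores, labels).auc == (
            pytest.approx(1.0, abs=1e-12)
        )
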