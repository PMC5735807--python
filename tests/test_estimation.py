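"""WSSR objective, multi-start fitting and the step-wise pipeline."""

import numpy as np
import pytest

from tsp1apop.estimation import (
    Observable,
    TrainingDataset,
    TrainingSeries,
    fit,
    stepwise_pipeline,
    validate_p38_inhibition,
    wssr,
)
from tsp1apop.simulation import Protocol, simulate
from tsp1apop.synthetic import SyntheticSpec, generate_training_dataset

#: short sampling designs so every objective evaluation needs only two
#: sub-hour simulations
FAST_GRIDS = (
    ("complex", (0.0, 5.0, 10.0, 20.0, 30.0)),
    ("pp59", (0.0, 5.0, 10.0, 20.0, 30.0)),
    ("pp38", (0.0, 10.0, 20.0, 40.0, 60.0)),
)


@pytest.fixture(scope="module")
def noiseless_dataset(model):
    return generate_training_dataset(
        model, SyntheticSpec(cv=0.0, grids=FAST_GRIDS, seed=0)
    )


class TestWssr:
    def test_truth_parameters_give_zero_residual(self, model, noiseless_dataset):
        assert wssr(model, {}, noiseless_dataset) == pytest.approx(0.0, abs=1e-16)

    def test_unit_residual_arithmetic(self, model, noiseless_dataset):
        # shift one observed point by +1: WSSR must be exactly 1
        shifted = []
        for s in noiseless_dataset.series:
            if s.observable == "pp38":
                vals = list(s.values)
                vals[-1] += 1.0
                s = TrainingSeries(s.observable, s.times, tuple(vals))
            shifted.append(s)
        ds = TrainingDataset(shifted, noiseless_dataset.observables)
        assert wssr(model, {}, ds) == pytest.approx(1.0, abs=1e-10)

    def test_doubling_weights_doubles_objective(self, model, noiseless_dataset):
        def with_weights(w):
            series = [
                TrainingSeries(
                    s.observable, s.times,
                    tuple(v + 0.1 for v in s.values),
                    tuple(w for _ in s.times),
                )
                for s in noiseless_dataset.series
            ]
            return TrainingDataset(series, noiseless_dataset.observables)

        a = wssr(model, {}, with_weights(1.0))
        b = wssr(model, {}, with_weights(2.0))
        assert b == pytest.approx(2.0 * a, rel=1e-12)

    def test_series_order_does_not_matter(self, model, noiseless_dataset):
        ds = TrainingDataset(
            list(reversed(noiseless_dataset.series)),
            noiseless_dataset.observables,
        )
        assert wssr(model, {}, ds) == pytest.approx(
            wssr(model, {}, noiseless_dataset), abs=1e-12
        )

    def test_series_validation(self):
        with pytest.raises(ValueError):
            TrainingSeries("x", (10.0, 5.0), (1.0, 1.0))
        with pytest.raises(ValueError):
            TrainingSeries("x", (0.0, 5.0), (1.0, -1.0))
        with pytest.raises(ValueError):
            TrainingSeries("x", (0.0, 5.0), (1.0, 1.0), (0.0, 1.0))


class TestFit:
    def test_recovers_decay_rate_of_linear_cascade(self, toys):
        m, _ = toys["cascade"]
        proto = Protocol(
            tsp1_dose=0.0, horizon=100.0,
            output_times=tuple(np.linspace(0, 100, 41)),
        )
        obs = Observable("X1", (("X1", 1.0),), proto)
        truth = m.parameters["k1"]
        times = (0.0, 10.0, 30.0, 60.0, 100.0)
        values = tuple(np.exp(-truth * np.asarray(times)))
        ds = TrainingDataset(
            [TrainingSeries("X1", times, values)], {"X1": obs}
        )
        result = fit(
            m, ds, ["k1"], bounds={"k1": (1e-3, 5.0)}, n_starts=4, seed=0,
            ensemble_size=3,
        )
        assert result.best["k1"] == pytest.approx(truth, rel=1e-4)
        assert result.wssr < 1e-10

    def test_bounds_respected_and_ensemble_sorted(self, toys):
        m, _ = toys["cascade"]
        proto = Protocol(tsp1_dose=0.0, horizon=50.0,
                         output_times=(0.0, 25.0, 50.0))
        obs = Observable("X1", (("X1", 1.0),), proto)
        ds = TrainingDataset(
            [TrainingSeries("X1", (0.0, 25.0, 50.0), (1.0, 0.5, 0.25))],
            {"X1": obs},
        )
        result = fit(m, ds, ["k1"], bounds={"k1": (1e-3, 1.0)}, n_starts=6,
                     seed=1)
        for params, w in result.ensemble:
            assert 1e-3 <= params["k1"] <= 1.0
        ws = [w for _, w in result.ensemble]
        assert ws == sorted(ws)
        assert result.wssr <= np.nanmin(
            np.where(np.isfinite(result.start_wssr), result.start_wssr, np.nan)
        ) + 1e-12

    def test_unknown_free_parameter_rejected(self, model, noiseless_dataset):
        with pytest.raises(KeyError):
            fit(model, noiseless_dataset, ["not_a_rate"], n_starts=1)


class TestStepwisePipeline:
    @pytest.fixture(scope="class")
    def recovery(self, model):
        truth = model  # data generated at the bundled baseline
        dataset = generate_training_dataset(
            truth, SyntheticSpec(cv=0.1, grids=FAST_GRIDS, seed=7)
        )
        start = model.copy()
        start.set_parameter("k_phos_fyn", model.parameters["k_phos_fyn"] * 5)
        start.set_parameter("k_deg_pFyn", model.parameters["k_deg_pFyn"] * 0.3)
        result = stepwise_pipeline(
            start, dataset,
            candidate_params=["k_phos_fyn", "k_deg_pFyn", "kon_dephos_fyn"],
            n_iterations=2, n_starts=6, seed=3, ensemble_size=4,
            efast_samples=65, efast_resamples=3,
        )
        return model, dataset, result

    def test_history_records_every_iteration(self, recovery):
        _, _, result = recovery
        assert len(result.history) == 2

    def test_refinement_is_monotone(self, recovery):
        _, _, result = recovery
        assert result.wssr <= result.history[0]["wssr"] + 1e-12

    def test_influential_parameters_recovered_within_factor_three(self, recovery):
        truth, _, result = recovery
        for name, value in result.best.items():
            ratio = value / truth.parameters[name]
            assert 1 / 3 <= ratio <= 3, (name, ratio)

    def test_ensemble_summary_reports_spread(self, recovery):
        _, _, result = recovery
        summary = result.summary()
        assert set(summary.columns) == {"mean", "sd"}
        assert (summary["mean"] > 0).all()


class TestP38Validation:
    def test_inhibition_lowers_activity_for_every_member(self, model, toys):
        base = dict(model.parameters)
        jitter = dict(base)
        jitter["kon_c3_parp"] *= 1.15
        from tsp1apop.estimation import FitResult

        fr = FitResult(
            best=base, wssr=0.0,
            ensemble=[(base, 0.0), (jitter, 0.1)],
            start_wssr=np.array([0.0, 0.1]), bounds={},
        )
        band = validate_p38_inhibition(model, fr)
        end = band.iloc[-1]
        assert end["inhibited_mean"] < end["control_mean"]
        # band brackets the mean at all times
        assert (band["inhibited_lo"] <= band["inhibited_mean"] + 1e-12).all()
        assert (band["inhibited_hi"] >= band["inhibited_mean"] - 1e-12).all()

    def test_identical_members_collapse_the_band(self, model):
        base = dict(model.parameters)
        from tsp1apop.estimation import FitResult

        fr = FitResult(
            best=base, wssr=0.0, ensemble=[(base, 0.0), (dict(base), 0.0)],
            start_wssr=np.array([0.0, 0.0]), bounds={},
        )
        band = validate_p38_inhibition(model, fr)
        width = band["inhibited_hi"] - band["inhibited_lo"]
        assert width.abs().max() < 1e-9

    def test_requires_an_ensemble(self, model):
        from tsp1apop.estimation import FitResult

        fr = FitResult(
            best={}, wssr=0.0, ensemble=[({}, 0.0)],
            start_wssr=np.array([0.0]), bounds={},
        )
        with pytest.raises(ValueError):
            validate_p38_inhibition(model, fr)
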