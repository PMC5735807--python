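"""Network assembly, rate-law primitives and structural invariants."""

import numpy as np
import pytest

from tsp1apop.network import (
    CYTOSOL,
    NUCLEUS,
    NUCLEAR_VOLUME_FRACTION,
    Compartment,
    KineticModel,
    NetworkAssemblyError,
    RateLaw,
    RateLawKind,
    Reaction,
    Species,
    fasl_transcription_rate,
    procaspase_synthesis_rate,
    receptors_to_concentration,
)
from tsp1apop.simulation import Protocol, simulate


class TestAssembly:
    def test_network_size(self, model):
        assert model.n_species == 53
        assert set(model.compartments) == {CYTOSOL, NUCLEUS}
        assert model.compartments[NUCLEUS].relative_volume == pytest.approx(
            NUCLEAR_VOLUME_FRACTION
        )

    def test_sixteen_species_start_nonzero(self, model):
        assert len(model.nonzero_ic_species()) == 16

    def test_tsp1_cd36_on_rate_from_affinity(self, model):
        # k_on = k_off / K_d with K_d = 230 nM and k_off = 1.2e-2 / min
        assert model.parameters["kon_tsp1_cd36"] == pytest.approx(
            1.2e-2 / 0.23, rel=1e-12
        )

    def test_fasl_fas_on_rate_from_affinity(self, model):
        # K_d = 0.4 nM -> k_on = 1.2e-2 / 4e-4 = 30 per uM per min
        assert model.parameters["kon_fasl_fas"] == pytest.approx(30.0)

    def test_receptor_initial_concentrations_from_counts(self, model):
        cd36 = model.species[model.species_index("CD36")].initial_concentration
        fas = model.species[model.species_index("Fas")].initial_concentration
        assert cd36 == pytest.approx(receptors_to_concentration(24372), rel=1e-3)
        assert fas == pytest.approx(receptors_to_concentration(7860), rel=1e-3)

    def test_every_rate_parameter_resolves(self, model):
        for r in model.reactions:
            for p in r.rate_law.parameters:
                assert p in model.parameters

    def test_unknown_species_reference_raises_with_symbol(self, model):
        bad = Reaction(
            "bad", (("NotASpecies", 1),), (), (),
            RateLaw(RateLawKind.DEGRADATION, ("k_deg_default",)),
        )
        with pytest.raises(NetworkAssemblyError, match="NotASpecies"):
            KineticModel(
                model.species, model.reactions + [bad],
                model.compartments.values(), model.parameters,
            )

    def test_unknown_parameter_reference_raises_with_symbol(self, model):
        bad = Reaction(
            "bad", (("TSP1", 1),), (), (),
            RateLaw(RateLawKind.DEGRADATION, ("k_missing",)),
        )
        with pytest.raises(NetworkAssemblyError, match="k_missing"):
            KineticModel(
                model.species, model.reactions + [bad],
                model.compartments.values(), model.parameters,
            )

    def test_negative_ic_rejected(self):
        with pytest.raises(NetworkAssemblyError):
            Species("X", CYTOSOL, -1.0)


class TestRateLawPrimitives:
    def test_fasl_transcription_saturation_curve(self):
        v, km = 0.4, 0.05
        assert fasl_transcription_rate(0.0, v, km) == 0.0
        assert fasl_transcription_rate(km, v, km) == pytest.approx(v / 2)
        assert fasl_transcription_rate(1e6 * km, v, km) == pytest.approx(
            v, rel=1e-5
        )
        # monotone increasing
        xs = np.linspace(0, 1, 50)
        ys = [fasl_transcription_rate(x, v, km) for x in xs]
        assert np.all(np.diff(ys) > 0)

    def test_fasl_transcription_zero_over_zero_raises(self):
        with pytest.raises(ZeroDivisionError):
            fasl_transcription_rate(0.0, 1.0, 0.0)

    def test_procaspase_synthesis_affine_in_disc(self):
        assert procaspase_synthesis_rate(0.0, 0.5, 1e-4) == pytest.approx(1e-4)
        assert procaspase_synthesis_rate(0.3, 0.0, 7e-4) == pytest.approx(7e-4)
        d, f = 0.002, 0.05
        assert procaspase_synthesis_rate(2 * d, f, 0.0) == pytest.approx(
            2 * f * d
        )
        with pytest.raises(ValueError):
            procaspase_synthesis_rate(-1.0, f, 1e-4)

    @pytest.mark.parametrize(
        "count,expected",
        [(24372, 4.047e-2), (7860, 1.305e-2), (0, 0.0)],
    )
    def test_receptor_count_to_concentration(self, count, expected):
        assert receptors_to_concentration(count, 1e-12) == pytest.approx(
            expected, rel=1e-3, abs=1e-12
        )

    def test_receptor_conversion_rejects_bad_volume(self):
        with pytest.raises(ValueError):
            receptors_to_concentration(100, 0.0)
        with pytest.raises(ValueError):
            receptors_to_concentration(-1, 1e-12)


class TestConservationAndVolumes:
    def test_receptor_totals_conserved_along_trajectory(self, model):
        traj = simulate(model, Protocol(tsp1_dose=1e-2, horizon=1440.0))
        for pool in ("CD36_total", "Fas_total"):
            tot = np.array([
                model.conserved_total(pool, traj.concentrations[:, j])
                for j in range(traj.times.size)
            ])
            assert np.ptp(tot) < 1e-8 * tot[0] + 1e-12

    def test_transport_conserves_mass_across_compartments(self):
        # X (cytosol) -> Y (nucleus): concentration*volume must be conserved
        m = KineticModel(
            [
                Species("TSP1", CYTOSOL, 0.0),
                Species("X", CYTOSOL, 1.0),
                Species("Y", NUCLEUS, 0.0),
            ],
            [
                Reaction("t", (("X", 1),), (("Y", 1),), (),
                         RateLaw(RateLawKind.TRANSPORT, ("k",))),
                Reaction("d", (("TSP1", 1),), (), (),
                         RateLaw(RateLawKind.DEGRADATION, ("z",))),
            ],
            [Compartment(CYTOSOL, 1.0), Compartment(NUCLEUS, NUCLEAR_VOLUME_FRACTION)],
            {"k": 0.05, "z": 0.0},
        )
        traj = simulate(m, Protocol(tsp1_dose=0.0, horizon=200.0))
        mass = traj["X"] * 1.0 + traj["Y"] * NUCLEAR_VOLUME_FRACTION
        assert np.ptp(mass) < 1e-8
        # and the nuclear concentration exceeds what the cytosol lost
        assert traj["Y"][-1] > (1.0 - traj["X"][-1])

    def test_isolated_binding_reaches_equilibrium_at_kd(self, toys):
        m, ref = toys["binding"]
        traj = simulate(m, Protocol(tsp1_dose=0.0, horizon=20000.0))
        kd = ref()["Kd"]
        ratio = traj["A"][-1] * traj["B"][-1] / traj["C"][-1]
        assert ratio == pytest.approx(kd, rel=0.01)

    def test_nonnegative_concentrations(self, model):
        traj = simulate(model, Protocol(tsp1_dose=1e-2, horizon=1440.0))
        assert traj.concentrations.min() >= -1e-8  # ~solver atol

    def test_perturbation_free_model_untouched_by_copy_edits(self, model):
        clone = model.copy()
        clone.set_parameter("K_trsp", 99.0)
        clone.set_initial_concentration("XIAP", 9.0)
        assert model.parameters["K_trsp"] != 99.0
        assert model.species[model.species_index("XIAP")].initial_concentration != 9.0
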