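"""Synthetic-data generators.

The immunoblot measurements the model was originally trained on exist only
as digitized figures, so this module provides stand-ins generated from a
known ground truth: fold-change time courses with multiplicative lognormal
noise on the study's sampling grids, fixture populations with a
controllable true AUC for exercising the ROC machinery, and small toy
networks with closed-form behavior used as integration oracles.  All
generators are deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimation import (
    TrainingDataset,
    TrainingSeries,
    default_observables,
)
from .network import (
    CYTOSOL,
    Compartment,
    KineticModel,
    RateLaw,
    RateLawKind,
    Reaction,
    Species,
)
from .simulation import simulate

__all__ = [
    "SyntheticSpec",
    "generate_training_dataset",
    "generate_fate_population",
    "toy_models",
]

#: sampling grids (minutes) emulating the study's designs per observable
DEFAULT_GRIDS = {
    "complex": (0.0, 2.0, 5.0, 10.0, 20.0, 30.0),
    "pp59": (0.0, 2.0, 5.0, 10.0, 20.0, 30.0),
    "pp38": (0.0, 5.0, 10.0, 20.0, 40.0, 60.0),
    "casp3_5nM": (0.0, 60.0, 120.0, 180.0, 240.0, 300.0),
    "casp3_0.388nM": (0.0, 120.0, 240.0, 360.0, 480.0, 600.0, 720.0),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic training dataset.

    ``truth_params`` overrides model parameters before simulating the
    ground truth; ``cv`` is the coefficient of variation of the
    multiplicative lognormal measurement noise (densitometry noise is
    proportional, hence multiplicative); grids are per-observable time
    points in minutes.
    """

    truth_params: tuple = ()  # ((name, value), ...)
    cv: float = 0.15
    grids: tuple = tuple(DEFAULT_GRIDS.items())
    seed: int = 0

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("cv must be >= 0")


def generate_training_dataset(
    model: KineticModel, spec: SyntheticSpec
) -> TrainingDataset:
    """Simulate the truth, sample on the grids, apply multiplicative noise.

    Fold changes are computed exactly as the fitting code computes them,
    then multiplied by exp(N(0, sigma)) with sigma = cv; the t = 0 point
    is the normalization reference and is kept at exactly 1.
    """
    observables = default_observables()
    mm = model.copy()
    for name, value in spec.truth_params:
        mm.set_parameter(name, value)
    rng = np.random.default_rng(spec.seed)
    series = []
    for obs_name, grid in spec.grids:
        obs = observables[obs_name]
        traj = simulate(mm, obs.protocol)
        fc = np.interp(grid, traj.times, obs.fold_change(traj))
        noise = np.exp(rng.normal(0.0, spec.cv, size=len(grid)))
        noisy = fc * noise
        noisy[np.asarray(grid) == 0.0] = 1.0  # normalization reference
        series.append(
            TrainingSeries(
                observable=obs_name,
                times=tuple(grid),
                values=tuple(np.maximum(noisy, 1e-12)),
            )
        )
    return TrainingDataset(series=series, observables=observables)


def generate_fate_population(
    n: int,
    auc_target: float = 0.97,
    shape: float = 5.5,
    mean_parp: float = 1.25,
    mean_xiap: float = 0.3,
    seed: int = 0,
):
    """Gamma-sampled (PARP, XIAP) fixture with a tunable true AUC.

    Fate is assigned by a median split of |PARP - XIAP| plus Gaussian
    label noise on the latent score; the noise scale is calibrated by
    bisection (deterministic under the seed) so that the |PARP - XIAP|
    feature attains ``auc_target`` on the generated sample.  Returns
    (features DataFrame with PARP, XIAP, |PARP-XIAP| columns, labels).
    """
    import pandas as pd
    from scipy import stats

    if n < 100:
        raise ValueError("n must be >= 100")
    if not 0.5 < auc_target <= 1.0:
        raise ValueError("auc_target must be in (0.5, 1]")
    rng = np.random.default_rng(seed)
    parp = rng.gamma(shape, mean_parp / shape, n)
    xiap = rng.gamma(shape, mean_xiap / shape, n)
    feature = np.abs(parp - xiap)
    z = (feature - feature.mean()) / feature.std()
    eps = rng.standard_normal(n)

    def auc_at(s):
        latent = z + s * eps
        labels = latent > np.median(latent)
        u = stats.mannwhitneyu(feature[labels], feature[~labels]).statistic
        return u / (labels.sum() * (~labels).sum()), labels

    a0, labels = auc_at(0.0)
    if auc_target > a0 + 1e-9:
        raise ValueError(
            f"auc_target {auc_target} infeasible (max {a0:.3f} at zero noise)"
        )
    if auc_target < a0:
        # AUC decreases monotonically in the noise scale: bisect
        lo, hi = 0.0, 50.0
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            a, labels = auc_at(mid)
            if a > auc_target:
                lo = mid
            else:
                hi = mid
        _, labels = auc_at(0.5 * (lo + hi))
    feats = pd.DataFrame(
        {"PARP": parp, "XIAP": xiap, "|PARP-XIAP|": feature}
    )
    return feats, labels


def _toy(species, reactions, parameters):
    return KineticModel(
        species, reactions, [Compartment(CYTOSOL, 1.0)], parameters
    )


def toy_models() -> dict:
    """Small closed-form networks used as integration oracles.

    Returns a dict of (model, reference) pairs:

    ``binding``
        A + B <-> C with kon, koff; reference gives the equilibrium state.
    ``synthdeg``
        0 -> X -> 0 at the study's default rates; steady state
        k_syn/k_deg = 0.1 uM.
    ``cascade``
        X1 -> X2 -> X3 linear chain; reference is the matrix-exponential
        solution.
    """
    out = {}

    kon, koff = 5.0, 0.012
    a0, b0 = 0.05, 0.03
    binding = _toy(
        [
            Species("TSP1", CYTOSOL, 0.0),  # placeholder ligand slot
            Species("A", CYTOSOL, a0),
            Species("B", CYTOSOL, b0),
            Species("C", CYTOSOL, 0.0),
        ],
        [
            Reaction(
                "bind", (("A", 1), ("B", 1)), (("C", 1),), (),
                RateLaw(RateLawKind.MASS_ACTION_REV, ("kon", "koff")),
            ),
            Reaction(
                "t_dummy", (("TSP1", 1),), (), (),
                RateLaw(RateLawKind.DEGRADATION, ("k_zero",)),
            ),
        ],
        {"kon": kon, "koff": koff, "k_zero": 0.0},
    )

    def binding_equilibrium():
        kd = koff / kon
        # C solves (a0-C)(b0-C) = kd*C
        coeffs = [1.0, -(a0 + b0 + kd), a0 * b0]
        c = min(np.roots(coeffs).real)
        return {"A": a0 - c, "B": b0 - c, "C": c, "Kd": kd}

    out["binding"] = (binding, binding_equilibrium)

    synthdeg = _toy(
        [
            Species("TSP1", CYTOSOL, 0.0),
            Species("X", CYTOSOL, 0.0),
        ],
        [
            Reaction(
                "syn", (), (("X", 1),), (),
                RateLaw(RateLawKind.SYNTHESIS_BASAL, ("k_syn",)),
            ),
            Reaction(
                "deg", (("X", 1),), (), (),
                RateLaw(RateLawKind.DEGRADATION, ("k_deg",)),
            ),
            Reaction(
                "t_dummy", (("TSP1", 1),), (), (),
                RateLaw(RateLawKind.DEGRADATION, ("k_zero",)),
            ),
        ],
        {"k_syn": 1e-4, "k_deg": 1e-3, "k_zero": 0.0},
    )
    out["synthdeg"] = (synthdeg, lambda: {"X": 1e-4 / 1e-3})

    k1, k2 = 0.05, 0.02
    cascade = _toy(
        [
            Species("TSP1", CYTOSOL, 0.0),
            Species("X1", CYTOSOL, 1.0),
            Species("X2", CYTOSOL, 0.0),
            Species("X3", CYTOSOL, 0.0),
        ],
        [
            Reaction(
                "s1", (("X1", 1),), (("X2", 1),), (),
                RateLaw(RateLawKind.MASS_ACTION_IRREV, ("k1",)),
            ),
            Reaction(
                "s2", (("X2", 1),), (("X3", 1),), (),
                RateLaw(RateLawKind.MASS_ACTION_IRREV, ("k2",)),
            ),
            Reaction(
                "t_dummy", (("TSP1", 1),), (), (),
                RateLaw(RateLawKind.DEGRADATION, ("k_zero",)),
            ),
        ],
        {"k1": k1, "k2": k2, "k_zero": 0.0},
    )

    def cascade_solution(t):
        from scipy.linalg import expm

        a = np.array([[-k1, 0, 0], [k1, -k2, 0], [0, k2, 0]])
        y0 = np.array([1.0, 0.0, 0.0])
        t = np.atleast_1d(np.asarray(t, float))
        return np.stack([expm(a * ti) @ y0 for ti in t], axis=1)

    out["cascade"] = (cascade, cascade_solution)
    return out
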