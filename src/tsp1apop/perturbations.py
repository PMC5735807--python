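"""Declarative network perturbations and the seven intervention strategies.

A :class:`PerturbationSpec` is an edit set applied to a copy of the model:
multiplicative factors on initial concentrations, multiplicative factors on
rate constants, and rate constants set to zero.  The built-in specs encode
the seven strategies studied with the population model plus the
p38MAPK-inhibition scenario used for validation:

========  ==========================================================
XIAP      XIAP downregulation: initial XIAP x 0.5
DXR       low-dose doxorubicin: initial Fas x 3, Ksyn_all x 10
Ptase     phosphatase inhibition: K_on_dephos x 0.1, K_dephos x 0.1
Kp        kinase promoter: phosphorylation rates of p59fyn, p38MAPK
          and IkB x 10
pro3      procaspase-3 upregulation: initial procaspase-3 x 3
Fas       Fas upregulation: initial Fas x 3
Ktrsp     faster nuclear translocation: K_trsp x 10
p38i      p38MAPK inhibition: rate of NF-kB phosphorylation by pp38 = 0
========  ==========================================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import KineticModel
from .population import (
    APOPTOSIS_THRESHOLD_UM,
    run_population,
)
from .simulation import Protocol, simulate

__all__ = [
    "PerturbationSpec",
    "BUILTIN_SPECS",
    "PHOSPHORYLATION_RATE_PARAMS",
    "apply_perturbation",
    "ic_scan",
    "strategy_comparison",
]

#: parameters counted as "phosphorylation rates" for the kinase-promoter spec
PHOSPHORYLATION_RATE_PARAMS = ("k_phos_fyn", "k_phos_p38", "k_phos_ikb")


@dataclass(frozen=True)
class PerturbationSpec:
    """A declarative, invertible model edit."""

    name: str
    ic_multipliers: tuple = ()  # ((species, factor), ...)
    param_multipliers: tuple = ()  # ((parameter, factor), ...)
    param_zeroed: tuple = ()  # parameter names set to 0

    def __post_init__(self):
        for _, f in self.ic_multipliers + self.param_multipliers:
            if f <= 0:
                raise ValueError(f"{self.name}: multipliers must be > 0")
        mult_names = {k for k, _ in self.param_multipliers}
        if mult_names & set(self.param_zeroed):
            raise ValueError(
                f"{self.name}: a parameter cannot be both zeroed and multiplied"
            )

    def inverse(self) -> "PerturbationSpec":
        """Reciprocal spec; undefined for specs that zero parameters."""
        if self.param_zeroed:
            raise ValueError("zeroing is not invertible")
        return PerturbationSpec(
            name=f"{self.name}_inverse",
            ic_multipliers=tuple((k, 1.0 / f) for k, f in self.ic_multipliers),
            param_multipliers=tuple(
                (k, 1.0 / f) for k, f in self.param_multipliers
            ),
        )

    def to_dict(self) -> dict:
        return {
            "ic": dict(self.ic_multipliers),
            "params": dict(self.param_multipliers),
            "zero": list(self.param_zeroed),
        }

    @classmethod
    def from_dict(cls, name: str, d: dict) -> "PerturbationSpec":
        return cls(
            name=name,
            ic_multipliers=tuple(d.get("ic", {}).items()),
            param_multipliers=tuple(d.get("params", {}).items()),
            param_zeroed=tuple(d.get("zero", ())),
        )


BUILTIN_SPECS = {
    "baseline": PerturbationSpec("baseline"),
    "XIAP": PerturbationSpec("XIAP", ic_multipliers=(("XIAP", 0.5),)),
    "DXR": PerturbationSpec(
        "DXR",
        ic_multipliers=(("Fas", 3.0),),
        param_multipliers=(("Ksyn_all", 10.0),),
    ),
    "Ptase": PerturbationSpec(
        "Ptase",
        param_multipliers=(("K_on_dephos", 0.1), ("K_dephos", 0.1)),
    ),
    "Kp": PerturbationSpec(
        "Kp",
        param_multipliers=tuple((k, 10.0) for k in PHOSPHORYLATION_RATE_PARAMS),
    ),
    "pro3": PerturbationSpec("pro3", ic_multipliers=(("pro3", 3.0),)),
    "Fas": PerturbationSpec("Fas", ic_multipliers=(("Fas", 3.0),)),
    "Ktrsp": PerturbationSpec(
        "Ktrsp", param_multipliers=(("K_trsp", 10.0),)
    ),
    "p38i": PerturbationSpec("p38i", param_zeroed=("k_phos_nfkb",)),
}


def apply_perturbation(model: KineticModel, spec: PerturbationSpec) -> KineticModel:
    """Return an edited copy of ``model``; the original is untouched."""
    edited = model.copy()
    for name, factor in spec.ic_multipliers:
        i = edited.species_index(name)  # raises on unknown species
        edited.set_initial_concentration(
            name, edited.species[i].initial_concentration * factor
        )
    for name, factor in spec.param_multipliers:
        if name not in edited.parameters:
            raise KeyError(f"unknown parameter {name!r} in spec {spec.name!r}")
        edited.set_parameter(name, edited.parameters[name] * factor)
    for name in spec.param_zeroed:
        if name not in edited.parameters:
            raise KeyError(f"unknown parameter {name!r} in spec {spec.name!r}")
        edited.set_parameter(name, 0.0)
    return edited


#: species eligible for the 10-fold initial-condition scans
SCAN_SPECIES = ("CD36", "Fas", "pro3", "XIAP", "PARP")


def ic_scan(
    model: KineticModel,
    species: str,
    parameter_sets: list | None = None,
    factors: tuple = (0.1, 1.0, 10.0),
    doses: tuple = (1e-4, 1e-3, 1e-2, 1e-1),
    times_h: tuple = tuple(range(2, 25, 2)),
) -> pd.DataFrame:
    """Mean-cell cPARP under 10-fold up/down scans of one initial condition.

    For each (factor, dose, time) cell the deterministic model is solved for
    every parameter set in the ensemble (default: the baseline set only) and
    the mean and sd of cPARP across the ensemble are reported.
    """
    if species not in SCAN_SPECIES:
        raise ValueError(
            f"{species!r} is not a scan species; choose from {SCAN_SPECIES}"
        )
    if parameter_sets is None:
        parameter_sets = [dict(model.parameters)]
    rows = []
    out_times = tuple(60.0 * h for h in times_h)
    for factor in factors:
        spec = PerturbationSpec("scan", ic_multipliers=((species, factor),))
        edited = apply_perturbation(model, spec)
        for dose in doses:
            values = np.empty((len(parameter_sets), len(out_times)))
            for k, pset in enumerate(parameter_sets):
                mm = edited.copy()
                for pname, pval in pset.items():
                    mm.set_parameter(pname, pval)
                traj = simulate(
                    mm,
                    Protocol(
                        tsp1_dose=dose, horizon=out_times[-1],
                        output_times=(0.0,) + out_times,
                    ),
                )
                values[k] = traj["cPARP"][1:]
            for j, t in enumerate(out_times):
                rows.append(
                    {
                        "species": species,
                        "factor": factor,
                        "dose_uM": dose,
                        "time_min": t,
                        "cparp_mean": values[:, j].mean(),
                        "cparp_sd": values[:, j].std(ddof=1)
                        if len(parameter_sets) > 1
                        else 0.0,
                    }
                )
    return pd.DataFrame(rows)


def strategy_comparison(
    model: KineticModel,
    specs: list | None = None,
    doses: tuple = (1e-4, 1e-2),
    n: int = 2000,
    seed: int = 0,
    threshold: float = APOPTOSIS_THRESHOLD_UM,
    relative: bool = True,
) -> pd.DataFrame:
    """Population response per strategy with comparison against baseline.

    For each dose and spec, simulates an ``n``-cell population and reports
    the apoptotic percentage at 24 h, its change versus baseline (relative
    change of the fraction by default, absolute difference otherwise), and
    one-way ANOVA p-values against baseline for max-cPARP (all cells) and
    T_t (apoptotic cells only; NaN with a warning when either group is
    empty).
    """
    if specs is None:
        specs = [
            BUILTIN_SPECS[k]
            for k in ("XIAP", "DXR", "Ptase", "Kp", "pro3", "Fas", "Ktrsp")
        ]
    rows = []
    for dose in doses:
        protocol = Protocol(
            tsp1_dose=dose, horizon=1440.0,
            output_times=tuple(np.arange(0.0, 1441.0, 120.0)),
        )
        base = run_population(
            model, protocol, n=n, seed=seed, threshold=threshold
        )
        groups = {"baseline": base}
        for spec in specs:
            edited = apply_perturbation(model, spec)
            groups[spec.name] = run_population(
                edited, protocol, n=n, seed=seed, threshold=threshold
            )
        p_base = groups["baseline"].apoptotic_fraction
        for name, pop in groups.items():
            p = pop.apoptotic_fraction
            if name == "baseline":
                change = 0.0
            elif relative:
                change = (p - p_base) / p_base if p_base > 0 else np.inf
            else:
                change = p - p_base
            p_max = stats.f_oneway(base.max_cparp, pop.max_cparp).pvalue
            tt_b = base.t_threshold[np.isfinite(base.t_threshold)]
            tt_s = pop.t_threshold[np.isfinite(pop.t_threshold)]
            if name == "baseline":
                p_max, p_tt = 1.0, 1.0
            elif tt_b.size and tt_s.size:
                p_tt = stats.f_oneway(tt_b, tt_s).pvalue
            else:
                import warnings

                warnings.warn(
                    f"{name}: empty apoptotic group, T_t comparison skipped",
                    RuntimeWarning,
                )
                p_tt = np.nan
            rows.append(
                {
                    "dose_uM": dose,
                    "strategy": name,
                    "apoptotic_pct": 100.0 * p,
                    "change_vs_baseline": change,
                    "median_max_cparp": float(np.median(pop.max_cparp)),
                    "median_t_threshold": float(np.median(tt_s))
                    if tt_s.size
                    else np.nan,
                    "p_max_cparp": p_max,
                    "p_t_threshold": p_tt,
                }
            )
    return pd.DataFrame(rows)
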