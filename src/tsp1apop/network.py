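"""Declarative reaction network for TSP1/CD36-mediated apoptosis signaling.

The model describes extrinsic apoptosis of endothelial cells triggered by
thrombospondin-1 (TSP1) ligating the CD36 receptor: p59fyn recruitment and
activation, p38MAPK phosphorylation, nuclear translocation of pp38 and NF-kB,
NF-kB-driven FasL transcription, DISC assembly on ligated Fas, the
caspase-8 -> caspase-3 cascade with caspase-3 -> caspase-8 feedback, XIAP
inhibition of caspase-3, and cleavage of PARP into cPARP, the apoptosis
readout.  Two well-mixed compartments are modeled (cytosol and nucleus, the
nucleus at 14.32% of the cytosolic volume); concentrations are in uM and
time in minutes throughout.

The network is shipped as three plain-text tables (``species.csv``,
``reactions.csv``, ``parameters.csv``) bundled with the package; each row
carries a ``provenance`` field so reconstructed reactions can be audited
separately from quantities with direct literature support.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AVOGADRO",
    "CYTOSOL",
    "NUCLEUS",
    "NUCLEAR_VOLUME_FRACTION",
    "Compartment",
    "Species",
    "RateLawKind",
    "RateLaw",
    "Reaction",
    "KineticModel",
    "NetworkAssemblyError",
    "assemble_network",
    "fasl_transcription_rate",
    "procaspase_synthesis_rate",
    "receptors_to_concentration",
]

AVOGADRO = 6.02214076e23
CYTOSOL = "cytosol"
NUCLEUS = "nucleus"
#: nuclear volume as a fraction of the cytosolic volume
NUCLEAR_VOLUME_FRACTION = 0.1432


class NetworkAssemblyError(ValueError):
    """Raised when a model table references an unknown symbol or is malformed."""


@dataclass(frozen=True)
class Compartment:
    name: str
    relative_volume: float

    def __post_init__(self) -> None:
        if self.relative_volume <= 0:
            raise NetworkAssemblyError(
                f"compartment {self.name!r} has non-positive volume"
            )


@dataclass(frozen=True)
class Species:
    name: str
    compartment: str
    initial_concentration: float  # uM
    tags: frozenset = frozenset()
    provenance: str = "reconstructed"

    def __post_init__(self) -> None:
        if self.initial_concentration < 0:
            raise NetworkAssemblyError(
                f"species {self.name!r} has negative initial concentration"
            )


class RateLawKind(str, Enum):
    MASS_ACTION_IRREV = "mass_action_irrev"
    MASS_ACTION_REV = "mass_action_rev"
    MICHAELIS_MENTEN = "michaelis_menten"
    SYNTHESIS_BASAL = "synthesis_basal"
    SYNTHESIS_DISC_DEPENDENT = "synthesis_disc_dependent"
    DEGRADATION = "degradation"
    TRANSPORT = "transport"


#: number of named parameters each rate-law kind requires
_RATE_LAW_ARITY = {
    RateLawKind.MASS_ACTION_IRREV: 1,
    RateLawKind.MASS_ACTION_REV: 2,
    RateLawKind.MICHAELIS_MENTEN: 2,
    RateLawKind.SYNTHESIS_BASAL: 1,
    RateLawKind.SYNTHESIS_DISC_DEPENDENT: 2,
    RateLawKind.DEGRADATION: 1,
    RateLawKind.TRANSPORT: 1,
}


@dataclass(frozen=True)
class RateLaw:
    kind: RateLawKind
    parameters: tuple  # parameter names, in the kind's canonical order

    def __post_init__(self) -> None:
        expected = _RATE_LAW_ARITY[self.kind]
        if len(self.parameters) != expected:
            raise NetworkAssemblyError(
                f"rate law {self.kind.value} expects {expected} parameter(s), "
                f"got {self.parameters!r}"
            )


@dataclass(frozen=True)
class Reaction:
    rid: str
    reactants: tuple  # ((species, stoichiometry), ...)
    products: tuple
    modifiers: tuple  # species names acting catalytically (e.g. NFkB_p)
    rate_law: RateLaw
    provenance: str = "reconstructed"

    @property
    def reversible(self) -> bool:
        return self.rate_law.kind is RateLawKind.MASS_ACTION_REV

    def __post_init__(self) -> None:
        for name, stoich in self.reactants + self.products:
            if not (isinstance(stoich, int) and stoich > 0):
                raise NetworkAssemblyError(
                    f"reaction {self.rid!r}: stoichiometry of {name!r} must be "
                    "a positive integer"
                )


class KineticModel:
    """An executable kinetic model: species, reactions and parameter values.

    The model owns a generated right-hand-side function (see :meth:`rhs`)
    compiled from the reaction list; parameter *values* can be edited without
    recompiling, while structural edits require reassembly.
    """

    def __init__(
        self,
        species: Iterable[Species],
        reactions: Iterable[Reaction],
        compartments: Iterable[Compartment],
        parameters: Mapping[str, float],
        conserved_totals: Mapping[str, tuple] | None = None,
        parameter_tags: Mapping[str, frozenset] | None = None,
    ) -> None:
        self.species = list(species)
        self.reactions = list(reactions)
        self.compartments = {c.name: c for c in compartments}
        self.parameters = dict(parameters)
        self.conserved_totals = dict(conserved_totals or {})
        self.parameter_tags = dict(parameter_tags or {})
        self._index = {s.name: i for i, s in enumerate(self.species)}
        if len(self._index) != len(self.species):
            raise NetworkAssemblyError("species names are not unique")
        self._param_order = list(self.parameters)
        self._rhs_fn = None
        self.validate()

    # -- basic queries ---------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise NetworkAssemblyError(f"unknown species {name!r}") from None

    def species_names(self) -> list:
        return [s.name for s in self.species]

    def nonzero_ic_species(self) -> list:
        return [s.name for s in self.species if s.initial_concentration > 0]

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.species])

    def volume(self, species_name: str) -> float:
        sp = self.species[self.species_index(species_name)]
        return self.compartments[sp.compartment].relative_volume

    def parameter_vector(self) -> np.ndarray:
        return np.array([self.parameters[k] for k in self._param_order])

    def model_hash(self) -> str:
        h = hashlib.sha256()
        for s in self.species:
            h.update(f"{s.name}:{s.compartment}:{s.initial_concentration!r};".encode())
        for k in self._param_order:
            h.update(f"{k}={self.parameters[k]!r};".encode())
        for r in self.reactions:
            h.update(f"{r.rid};".encode())
        return h.hexdigest()[:16]

    # -- editing ---------------------------------------------------------
    def copy(self) -> "KineticModel":
        clone = KineticModel(
            list(self.species),
            list(self.reactions),
            list(self.compartments.values()),
            dict(self.parameters),
            {k: tuple(v) for k, v in self.conserved_totals.items()},
            dict(self.parameter_tags),
        )
        # structure is identical, so the compiled RHS can be shared
        clone._rhs_fn = self._rhs_fn
        return clone

    def set_parameter(self, name: str, value: float) -> None:
        if name not in self.parameters:
            raise NetworkAssemblyError(f"unknown parameter {name!r}")
        if value < 0:
            raise NetworkAssemblyError(f"parameter {name!r} must be >= 0")
        self.parameters[name] = float(value)

    def set_initial_concentration(self, name: str, value: float) -> None:
        i = self.species_index(name)
        self.species[i] = replace(self.species[i], initial_concentration=float(value))

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        names = set(self._index)
        used = set()
        for r in self.reactions:
            refs = (
                [n for n, _ in r.reactants]
                + [n for n, _ in r.products]
                + list(r.modifiers)
            )
            for n in refs:
                if n not in names:
                    raise NetworkAssemblyError(
                        f"reaction {r.rid!r} references unknown species {n!r}"
                    )
            used.update(refs)
            for p in r.rate_law.parameters:
                if p not in self.parameters:
                    raise NetworkAssemblyError(
                        f"reaction {r.rid!r} references unknown parameter {p!r}"
                    )
            if r.rate_law.kind is RateLawKind.TRANSPORT:
                if len(r.reactants) != 1 or len(r.products) != 1:
                    raise NetworkAssemblyError(
                        f"transport reaction {r.rid!r} must move exactly one species"
                    )
        orphans = names - used
        if orphans:
            raise NetworkAssemblyError(
                f"species appear in no reaction: {sorted(orphans)}"
            )
        for s in self.species:
            if s.compartment not in self.compartments:
                raise NetworkAssemblyError(
                    f"species {s.name!r} references unknown compartment "
                    f"{s.compartment!r}"
                )
        for total_name, members in self.conserved_totals.items():
            for n, _w in members:
                if n not in names:
                    raise NetworkAssemblyError(
                        f"conserved total {total_name!r} references unknown "
                        f"species {n!r}"
                    )

    def conserved_total(self, name: str, state: np.ndarray) -> float:
        """Weighted sum of a declared conserved pool at a state vector."""
        members = self.conserved_totals[name]
        return float(
            sum(w * state[self.species_index(n)] for n, w in members)
        )

    # -- compiled right-hand side ---------------------------------------
    def rhs(self):
        """Return ``f(t, y, p) -> dy/dt`` generated from the reaction list.

        Negative concentrations are clipped to zero inside rate evaluation
        only (the state itself is never clipped), and cross-compartment
        fluxes are scaled by the volume ratio so that mass is conserved
        across the nuclear membrane.
        """
        if self._rhs_fn is None:
            self._rhs_fn = _compile_rhs(self)
        return self._rhs_fn


# -- rate-law primitives -------------------------------------------------

def fasl_transcription_rate(nfkb_p: float, vmax: float, km: float) -> float:
    """FasL transcription rate, V = vmax * NFkB_p / (km + NFkB_p) in uM/min.

    Saturating Michaelis-Menten dependence on activated nuclear NF-kB.
    """
    if nfkb_p < 0 or vmax < 0 or km < 0:
        raise ValueError("arguments must be non-negative")
    denom = km + nfkb_p
    if denom == 0:
        raise ZeroDivisionError("km and nfkb_p are both zero (0/0)")
    return vmax * nfkb_p / denom


def procaspase_synthesis_rate(disc: float, f: float, k_syn_all: float) -> float:
    """Procaspase-8/-3 synthesis rate, V = F * DISC + Ksyn_all in uM/min."""
    if disc < 0 or f < 0 or k_syn_all < 0:
        raise ValueError("arguments must be non-negative")
    return f * disc + k_syn_all


def receptors_to_concentration(count: float, cell_volume: float = 1e-12) -> float:
    """Convert receptors/cell to uM given the cell volume in liters.

    The default volume is 1 picoliter.
    """
    if count < 0:
        raise ValueError("receptor count must be >= 0")
    if cell_volume <= 0:
        raise ValueError("cell volume must be > 0")
    return count / (AVOGADRO * cell_volume) * 1e6


# -- assembly from the bundled tables ------------------------------------

def _read_table(name: str) -> pd.DataFrame:
    with resources.files("tsp1apop.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, keep_default_na=False)


def _parse_side(cell: str) -> tuple:
    """Parse 'A;B*2' into ((A,1),(B,2))."""
    out = []
    if not cell:
        return ()
    for tok in cell.split(";"):
        if "*" in tok:
            n, s = tok.split("*")
            out.append((n.strip(), int(s)))
        else:
            out.append((tok.strip(), 1))
    return tuple(out)


#: species pools whose weighted totals are conserved by construction
_CONSERVED = {
    "CD36_total": (
        ("CD36", 1.0),
        ("TSP1_CD36", 1.0),
        ("TSP1_CD36_Fyn", 1.0),
        ("CD36_i", 1.0),
    ),
    "Fas_total": (
        ("Fas", 1.0),
        ("FasL_Fas", 1.0),
        ("DISC", 1.0),
        ("DISC_FL", 1.0),
        ("DISC_pro8", 1.0),
        ("DISC_FL_pro8", 1.0),
        ("Fas_i", 1.0),
    ),
}


def assemble_network() -> KineticModel:
    """Assemble the bundled 53-species, two-compartment signaling model.

    Reads the packaged species/reaction/parameter tables, resolves every
    symbol and returns a validated :class:`KineticModel` with the receptor
    conservation pools declared.
    """
    sp_tab = _read_table("species.csv")
    rx_tab = _read_table("reactions.csv")
    pm_tab = _read_table("parameters.csv")

    compartments = [
        Compartment(CYTOSOL, 1.0),
        Compartment(NUCLEUS, NUCLEAR_VOLUME_FRACTION),
    ]
    species = [
        Species(
            name=row["name"],
            compartment=row["compartment"],
            initial_concentration=float(row["initial_uM"]),
            tags=frozenset(t for t in str(row["tags"]).split(";") if t),
            provenance=row["provenance"],
        )
        for _, row in sp_tab.iterrows()
    ]
    parameters = {}
    parameter_tags = {}
    for _, row in pm_tab.iterrows():
        val = float(row["value"])
        if val < 0:
            raise NetworkAssemblyError(f"parameter {row['name']!r} is negative")
        parameters[row["name"]] = val
        parameter_tags[row["name"]] = frozenset(
            t for t in str(row["tags"]).split(";") if t
        )
    reactions = []
    for _, row in rx_tab.iterrows():
        kind = RateLawKind(row["rate_law_kind"])
        params = tuple(p.strip() for p in row["parameters"].split(";") if p.strip())
        reactions.append(
            Reaction(
                rid=row["id"],
                reactants=_parse_side(row["reactants"]),
                products=_parse_side(row["products"]),
                modifiers=tuple(
                    m.strip() for m in row["modifiers"].split(";") if m.strip()
                ),
                rate_law=RateLaw(kind, params),
                provenance=row["provenance"],
            )
        )
    return KineticModel(
        species, reactions, compartments, parameters, _CONSERVED, parameter_tags
    )


# -- RHS code generation -------------------------------------------------

def _home_compartment(model: KineticModel, r: Reaction) -> str:
    """Compartment whose volume defines the reaction's flux units."""
    if r.reactants:
        return model.species[model.species_index(r.reactants[0][0])].compartment
    if r.products:
        return model.species[model.species_index(r.products[0][0])].compartment
    raise NetworkAssemblyError(f"reaction {r.rid!r} has no participants")


def _compile_rhs(model: KineticModel):
    """Generate a specialized python RHS function for this model structure.

    Emits one scalar expression per reaction flux and one accumulation per
    species, then ``exec``s the source.  This is several times faster than a
    generic interpreted evaluation loop for a ~50-species network and keeps
    the kinetic laws auditable (the source is attached as ``__rhs_source__``).
    """
    pidx = {k: i for i, k in enumerate(model._param_order)}
    lines = ["def _rhs(t, y, p):"]
    used_species = sorted(
        {
            model.species_index(n)
            for r in model.reactions
            for n, _ in list(r.reactants) + list(r.products)
        }
        | {
            model.species_index(n)
            for r in model.reactions
            for n in r.modifiers
        }
    )
    for i in used_species:
        lines.append(f"    c{i} = y[{i}] if y[{i}] > 0.0 else 0.0")
    contrib: dict[int, list[str]] = {}

    def add(sp_i: int, term: str) -> None:
        contrib.setdefault(sp_i, []).append(term)

    for k, r in enumerate(model.reactions):
        kind = r.rate_law.kind
        par = [f"p[{pidx[p]}]" for p in r.rate_law.parameters]
        home = _home_compartment(model, r)
        v_home = model.compartments[home].relative_volume

        def conc_product(side):
            toks = []
            for n, s in side:
                i = model.species_index(n)
                toks.extend([f"c{i}"] * s)
            return "*".join(toks) if toks else "1.0"

        if kind is RateLawKind.MASS_ACTION_IRREV:
            expr = f"{par[0]}*{conc_product(r.reactants)}"
        elif kind is RateLawKind.MASS_ACTION_REV:
            expr = (
                f"{par[0]}*{conc_product(r.reactants)}"
                f" - {par[1]}*{conc_product(r.products)}"
            )
        elif kind is RateLawKind.MICHAELIS_MENTEN:
            m = model.species_index(r.modifiers[0])
            expr = f"{par[0]}*c{m}/({par[1]} + c{m})"
        elif kind is RateLawKind.SYNTHESIS_BASAL:
            expr = f"{par[0]}"
        elif kind is RateLawKind.SYNTHESIS_DISC_DEPENDENT:
            m = model.species_index(r.modifiers[0])
            expr = f"{par[0]}*c{m} + {par[1]}"
        elif kind is RateLawKind.DEGRADATION:
            expr = f"{par[0]}*{conc_product(r.reactants)}"
        elif kind is RateLawKind.TRANSPORT:
            expr = f"{par[0]}*{conc_product(r.reactants)}"
        else:  # pragma: no cover
            raise NetworkAssemblyError(f"unhandled rate law {kind}")
        lines.append(f"    v{k} = {expr}")

        for n, s in r.reactants:
            i = model.species_index(n)
            add(i, f"- {s}*v{k}" if s != 1 else f"- v{k}")
        for n, s in r.products:
            i = model.species_index(n)
            v_sp = model.volume(n)
            scale = v_home / v_sp
            if abs(scale - 1.0) < 1e-15:
                add(i, f"+ {s}*v{k}" if s != 1 else f"+ v{k}")
            else:
                add(i, f"+ {s * scale!r}*v{k}")

    terms = []
    for i in range(model.n_species):
        if i in contrib:
            expr = " ".join(contrib[i])
            terms.append(expr[2:] if expr.startswith("+ ") else expr)
        else:
            terms.append("0.0")
    body = ",\n        ".join(terms)
    lines.append(f"    return np.array([\n        {body}\n    ])")
    src = "\n".join(lines)
    ns = {"np": np}
    exec(src, ns)
    fn = ns["_rhs"]
    fn.__rhs_source__ = src
    return fn
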