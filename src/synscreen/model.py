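"""Kinetic network data model and rate-law library.

A :class:`NetworkModel` is a set of species (metabolites and enzyme pools)
connected by irreversible single-substrate reactions.  Five rate-law families
cover the enzyme chemistry of small metabolic/inflammatory networks:

``michaelis_menten``
    v = K_cat [E_t] [S] / (K_m + [S])
``competitive_inhibition``
    v = K_cat [E_t] [S] / (K_m (1 + [I]/K_i) + [S])
``irreversible_inactivation``
    d[E]/dt = -K [E] [I]    (an inhibitor permanently destroys the enzyme)
``activation``
    v = K_cat (1 + [A]/KI) [E_t] [S] / (K_m + [S])
``transcription_upregulation``
    d[E]/dt = k_max [g]^2 / ([g]^2 + k_half^2)   (metabolite g induces
    synthesis of the enzyme with Hill coefficient 2)

The catalytic families (MM, competitive inhibition, activation) are applied
with -v to the substrate and +v to the product; inactivation removes enzyme
pool, upregulation adds it.  The printed MM form has a positive d[S]/dt; here
the expression is treated as the flux magnitude and the substrate sign is
negative, since substrates are consumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Species",
    "KineticLaw",
    "Reaction",
    "NetworkModel",
    "ModelValidationError",
    "rate",
    "assemble_rhs",
    "validate_model",
    "load_model",
    "save_model",
]

#: constants required by each law kind
LAW_CONSTANTS: dict[str, tuple[str, ...]] = {
    "michaelis_menten": ("K_cat", "K_m"),
    "competitive_inhibition": ("K_cat", "K_m", "K_i"),
    "irreversible_inactivation": ("K",),
    "activation": ("K_cat", "K_m", "KI"),
    "transcription_upregulation": ("k_max", "k_half"),
}

#: modifier roles required by each law kind
LAW_MODIFIERS: dict[str, tuple[str, ...]] = {
    "michaelis_menten": (),
    "competitive_inhibition": ("inhibitor",),
    "irreversible_inactivation": ("inhibitor",),
    "activation": ("activator",),
    "transcription_upregulation": ("transcription_signal",),
}

#: law kinds that act on the enzyme pool itself rather than substrate->product
ENZYME_DYNAMICS_LAWS = frozenset(
    {"irreversible_inactivation", "transcription_upregulation"}
)


class ModelValidationError(ValueError):
    """Raised when a model (or a rate-law evaluation) is inconsistent."""


@dataclass(frozen=True)
class Species:
    """A chemical species: a metabolite or an enzyme pool."""

    id: str
    initial_concentration: float
    role: str = "metabolite"  # "metabolite" | "enzyme_pool"

    def __post_init__(self) -> None:
        if self.initial_concentration < 0:
            raise ModelValidationError(
                f"species {self.id!r}: initial concentration must be >= 0"
            )
        if self.role not in ("metabolite", "enzyme_pool"):
            raise ModelValidationError(f"species {self.id!r}: unknown role {self.role!r}")


@dataclass(frozen=True)
class KineticLaw:
    """A rate-law kind plus exactly the constants that kind requires."""

    law_kind: str
    constants: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.law_kind not in LAW_CONSTANTS:
            raise ModelValidationError(f"unknown law kind {self.law_kind!r}")
        required = set(LAW_CONSTANTS[self.law_kind])
        got = set(self.constants)
        if got != required:
            raise ModelValidationError(
                f"{self.law_kind}: constants must be exactly {sorted(required)}, "
                f"got {sorted(got)}"
            )
        for name, value in self.constants.items():
            if not value > 0:
                raise ModelValidationError(
                    f"{self.law_kind}: constant {name} must be strictly positive"
                )


@dataclass(frozen=True)
class Reaction:
    """One irreversible reaction step.

    For catalytic laws ``substrate`` is consumed 1:1 into ``product`` (which
    may be absent for a terminal degradation step).  For
    ``irreversible_inactivation`` and ``transcription_upregulation`` the law
    acts on the ``enzyme`` pool itself and ``substrate``/``product`` are
    unused.
    """

    id: str
    law: KineticLaw
    enzyme: str
    substrate: str | None = None
    product: str | None = None
    modifiers: Mapping[str, str] = field(default_factory=dict)


@dataclass
class NetworkModel:
    """A full kinetic network: species, reactions, targets, readout, horizon."""

    species: list[Species]
    reactions: list[Reaction]
    targets: list[str]
    readout: str
    horizon: float = 3600.0

    def species_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def species_by_id(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.species], float)

    def n_kinetic_constants(self) -> int:
        return sum(len(r.law.constants) for r in self.reactions)


# ---------------------------------------------------------------------------
# rate evaluation
# ---------------------------------------------------------------------------

def rate(law: KineticLaw, concentrations: Mapping[str, float]) -> float:
    """Instantaneous reaction velocity (flux magnitude) of one rate law.

    ``concentrations`` maps the role names the law reads ("S", "E_t", "I",
    "A", "g", "E") to non-negative values.  The sign convention (what the
    velocity is applied to) is decided by :func:`assemble_rhs`.
    """
    c = law.constants
    kind = law.law_kind

    def get(key: str) -> float:
        try:
            v = concentrations[key]
        except KeyError:
            raise ModelValidationError(
                f"{kind}: missing concentration {key!r}"
            ) from None
        return max(v, 0.0)

    if kind == "michaelis_menten":
        s = get("S")
        return c["K_cat"] * get("E_t") * s / (c["K_m"] + s)
    if kind == "competitive_inhibition":
        s = get("S")
        return c["K_cat"] * get("E_t") * s / (c["K_m"] * (1.0 + get("I") / c["K_i"]) + s)
    if kind == "irreversible_inactivation":
        return c["K"] * get("E") * get("I")
    if kind == "activation":
        s = get("S")
        return c["K_cat"] * (1.0 + get("A") / c["KI"]) * get("E_t") * s / (c["K_m"] + s)
    if kind == "transcription_upregulation":
        g = get("g")
        g2 = g * g
        return c["k_max"] * g2 / (g2 + c["k_half"] ** 2)
    raise ModelValidationError(f"unknown law kind {kind!r}")


def _law_inputs(rxn: Reaction, idx: dict[str, int]) -> dict[str, int]:
    """Map rate-law role names to state-vector indices for one reaction."""
    kind = rxn.law.law_kind
    roles: dict[str, int] = {}
    if kind in ("michaelis_menten", "competitive_inhibition", "activation"):
        roles["S"] = idx[rxn.substrate]
        roles["E_t"] = idx[rxn.enzyme]
        if kind == "competitive_inhibition":
            roles["I"] = idx[rxn.modifiers["inhibitor"]]
        if kind == "activation":
            roles["A"] = idx[rxn.modifiers["activator"]]
    elif kind == "irreversible_inactivation":
        roles["E"] = idx[rxn.enzyme]
        roles["I"] = idx[rxn.modifiers["inhibitor"]]
    elif kind == "transcription_upregulation":
        roles["g"] = idx[rxn.modifiers["transcription_signal"]]
    return roles


def assemble_rhs(
    model: NetworkModel,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Build the time-derivative function d(state)/dt of a validated model.

    The state vector follows the declared species order.  Concentrations are
    clipped at zero for flux evaluation, the standard positivity safeguard
    when an adaptive integrator steps slightly negative.
    """
    violations = validate_model(model)
    if violations:
        raise ModelValidationError("; ".join(violations))

    idx = model.species_index()
    n = len(model.species)
    # precompile: (law, role->index map, signed stoichiometry list)
    compiled: list[tuple[KineticLaw, dict[str, int], list[tuple[int, float]]]] = []
    for rxn in model.reactions:
        roles = _law_inputs(rxn, idx)
        stoich: list[tuple[int, float]] = []
        kind = rxn.law.law_kind
        if kind in ("michaelis_menten", "competitive_inhibition", "activation"):
            stoich.append((idx[rxn.substrate], -1.0))
            if rxn.product is not None:
                stoich.append((idx[rxn.product], +1.0))
        elif kind == "irreversible_inactivation":
            stoich.append((idx[rxn.enzyme], -1.0))
        elif kind == "transcription_upregulation":
            stoich.append((idx[rxn.enzyme], +1.0))
        compiled.append((rxn.law, roles, stoich))

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros(n)
        yc = np.maximum(y[:n], 0.0)
        for law, roles, stoich in compiled:
            v = rate(law, {k: yc[i] for k, i in roles.items()})
            for i, sign in stoich:
                dy[i] += sign * v
        return dy

    return rhs


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_model(model: NetworkModel) -> list[str]:
    """Collect every invariant violation; an empty list means valid.

    Never raises on invalid input: violations are data.
    """
    out: list[str] = []
    seen: set[str] = set()
    for s in model.species:
        if s.id in seen:
            out.append(f"species {s.id!r}: duplicate id")
        seen.add(s.id)
        if s.initial_concentration < 0:
            out.append(f"species {s.id!r}: negative initial concentration")
    ids = {s.id for s in model.species}

    for rxn in model.reactions:
        kind = rxn.law.law_kind
        where = f"reaction {rxn.id!r}"
        if rxn.enzyme not in ids:
            out.append(f"{where}: enzyme {rxn.enzyme!r} is not a declared species")
        if kind in ("michaelis_menten", "competitive_inhibition", "activation"):
            if rxn.substrate is None:
                out.append(f"{where}: {kind} requires a substrate")
            elif rxn.substrate not in ids:
                out.append(f"{where}: substrate {rxn.substrate!r} is not a declared species")
            if rxn.product is not None and rxn.product not in ids:
                out.append(f"{where}: product {rxn.product!r} is not a declared species")
        required_mods = LAW_MODIFIERS[kind]
        for role in required_mods:
            if role not in rxn.modifiers:
                out.append(f"{where}: {kind} requires a {role} modifier")
        for role, sid in rxn.modifiers.items():
            if role not in required_mods:
                out.append(f"{where}: modifier {role!r} not used by {kind}")
            elif sid not in ids:
                out.append(f"{where}: modifier {role}={sid!r} is not a declared species")

    if model.readout not in ids:
        out.append(f"readout {model.readout!r} is not a declared species")
    else:
        touches = any(
            model.readout in (r.substrate, r.product, r.enzyme) for r in model.reactions
        )
        if model.reactions and not touches:
            out.append(f"readout {model.readout!r} is not produced or consumed by any reaction")
    for t in model.targets:
        if t not in ids:
            out.append(f"target {t!r} is not a declared species")
        else:
            sp = model.species_by_id(t)
            if sp.role != "enzyme_pool":
                out.append(f"target {t!r} is not an enzyme_pool")
    if not model.horizon > 0:
        out.append("horizon must be > 0")
    return out


# ---------------------------------------------------------------------------
# YAML schema I/O
# ---------------------------------------------------------------------------

def model_to_dict(model: NetworkModel) -> dict:
    doc: dict = {
        "species": [
            {"id": s.id, "initial": s.initial_concentration, "role": s.role}
            for s in model.species
        ],
        "reactions": [],
        "targets": list(model.targets),
        "readout": model.readout,
        "horizon_seconds": model.horizon,
    }
    for r in model.reactions:
        entry: dict = {
            "id": r.id,
            "law_kind": r.law.law_kind,
            "enzyme": r.enzyme,
            "constants": {k: float(v) for k, v in r.law.constants.items()},
        }
        if r.substrate is not None:
            entry["substrate"] = r.substrate
        if r.product is not None:
            entry["product"] = r.product
        if r.modifiers:
            entry["modifiers"] = dict(r.modifiers)
        doc["reactions"].append(entry)
    return doc


def model_from_dict(doc: Mapping) -> NetworkModel:
    species = [
        Species(d["id"], float(d["initial"]), d.get("role", "metabolite"))
        for d in doc["species"]
    ]
    reactions = [
        Reaction(
            id=d["id"],
            law=KineticLaw(d["law_kind"], d["constants"]),
            enzyme=d["enzyme"],
            substrate=d.get("substrate"),
            product=d.get("product"),
            modifiers=d.get("modifiers", {}),
        )
        for d in doc["reactions"]
    ]
    return NetworkModel(
        species=species,
        reactions=reactions,
        targets=list(doc.get("targets", [])),
        readout=doc["readout"],
        horizon=float(doc.get("horizon_seconds", 3600.0)),
    )


def save_model(model: NetworkModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model(path) -> NetworkModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    model = model_from_dict(doc)
    violations = validate_model(model)
    if violations:
        raise ModelValidationError(
            f"{path}: invalid model: " + "; ".join(violations)
        )
    return model
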