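"""Small networks with known dose–effect behaviour.

Every screening stage is testable on these fixtures without any external
model file.  Generation is pure: all randomness flows from the seed, and the
same (kind, size, seed) always yields the same model, bit for bit.

The additive-pair fixture deserves a note, since it is the package's Loewe
oracle.  Two enzyme pools with identical kinetics divert a shared precursor
away from the readout route; a "drug dose" is an *increase* of one pool.
Because both routes share the same Michaelis constant, the fraction of
precursor reaching the readout depends only on the *sum* of the two pools,
so Loewe additivity holds exactly by construction: every equal-effect dose
pair satisfies f1 + f2 = 1.  A decrease-direction construction cannot make
both pools individually sensitive (reaching a 10x output drop by removing
enzyme always costs more than either pool holds), which is why the doses
point upward here.  With the recommended threshold
``ADDITIVE_PAIR_THETA = 0.75`` the single-pool dose ratio is 0.8, so both
targets classify as sensitive at a = 1; the CI = 1 identity itself holds for
any threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import KineticLaw, NetworkModel, Reaction, Species

__all__ = [
    "FixtureSpec",
    "ADDITIVE_PAIR_THETA",
    "make_cascade",
    "make_additive_pair_model",
    "make_insensitive_pair_fixture",
    "random_network",
    "make_fixture",
]

#: recommended normal-state fraction for the additive-pair fixture (see module
#: docstring: derived from ratio = 2(1/theta - 1)(1 + c/d0) <= 1)
ADDITIVE_PAIR_THETA = 0.75


@dataclass(frozen=True)
class FixtureSpec:
    kind: str            # linear_cascade | additive_pair | insensitive_pair | random
    size: int = 2
    seed: int = 0
    params: dict = field(default_factory=dict)


def _mm(k_cat: float, k_m: float) -> KineticLaw:
    return KineticLaw("michaelis_menten", {"K_cat": k_cat, "K_m": k_m})


def make_cascade(
    n: int,
    s0: float = 100.0,
    k_cat: float = 1.0,
    k_m: float | Sequence[float] = 1.0,
    e0: float | Sequence[float] = 1.0,
    horizon: float = 10.0,
) -> NetworkModel:
    """Linear Michaelis–Menten chain S0 -> S1 -> ... -> Sn.

    Readout is the terminal species; every enzyme is a target.  The initial
    substrate pool is large relative to what the horizon consumes, so the
    cumulative output is rate-limited and monotone in every enzyme level.
    """
    if n < 1:
        raise ValueError("cascade needs at least one step")
    e0s = [e0] * n if np.isscalar(e0) else list(e0)
    kms = [k_m] * n if np.isscalar(k_m) else list(k_m)
    species = [Species("S0", s0)]
    species += [Species(f"S{i}", 0.0) for i in range(1, n + 1)]
    species += [Species(f"E{i}", float(e0s[i - 1]), "enzyme_pool") for i in range(1, n + 1)]
    reactions = [
        Reaction(
            id=f"r{i}",
            law=_mm(k_cat, float(kms[i - 1])),
            enzyme=f"E{i}",
            substrate=f"S{i-1}",
            product=f"S{i}",
        )
        for i in range(1, n + 1)
    ]
    return NetworkModel(
        species=species,
        reactions=reactions,
        targets=[f"E{i}" for i in range(1, n + 1)],
        readout=f"S{n}",
        horizon=horizon,
    )


def make_additive_pair_model(
    s0: float = 10.0,
    k_cat_prod: float = 1.0,
    e_prod: float = 0.2,
    k_cat_div: float = 1.0,
    e_pool: float = 0.5,
    k_m: float = 1.0,
    horizon: float = 100.0,
) -> NetworkModel:
    """Exactly-Loewe-additive pair: two diversion pools of one activity.

    S is consumed by a readout-producing route (enzyme E_prod, not a target)
    and by two waste routes through the target pools E_a and E_b.  All routes
    share K_m, so the readout fraction depends only on E_a + E_b and every
    equal-effect contour is the line f1 + f2 = 1.
    """
    species = [
        Species("S", s0),
        Species("R", 0.0),
        Species("W", 0.0),
        Species("E_prod", e_prod, "enzyme_pool"),
        Species("E_a", e_pool, "enzyme_pool"),
        Species("E_b", e_pool, "enzyme_pool"),
    ]
    reactions = [
        Reaction("produce", _mm(k_cat_prod, k_m), "E_prod", "S", "R"),
        Reaction("divert_a", _mm(k_cat_div, k_m), "E_a", "S", "W"),
        Reaction("divert_b", _mm(k_cat_div, k_m), "E_b", "S", "W"),
    ]
    return NetworkModel(
        species=species,
        reactions=reactions,
        targets=["E_a", "E_b"],
        readout="R",
        horizon=horizon,
    )


def make_insensitive_pair_fixture(
    s0: float = 100.0,
    k_cat: float = 1.0,
    k_m: float = 1.0,
    e0: float = 1.0,
    horizon: float = 10.0,
) -> NetworkModel:
    """Two saturated parallel routes to the readout.

    Each route alone supplies half the output, so no single-target
    perturbation can push the output below 10% of the disease level, but a
    joint near-knockout of both enzymes can: the canonical
    insensitive-but-jointly-feasible pair.
    """
    species = [
        Species("S_a", s0),
        Species("S_b", s0),
        Species("R", 0.0),
        Species("E_a", e0, "enzyme_pool"),
        Species("E_b", e0, "enzyme_pool"),
    ]
    reactions = [
        Reaction("route_a", _mm(k_cat, k_m), "E_a", "S_a", "R"),
        Reaction("route_b", _mm(k_cat, k_m), "E_b", "S_b", "R"),
    ]
    return NetworkModel(
        species=species,
        reactions=reactions,
        targets=["E_a", "E_b"],
        readout="R",
        horizon=horizon,
    )


def random_network(spec: FixtureSpec) -> NetworkModel:
    """Seeded random DAG of Michaelis–Menten reactions.

    A linear backbone of ``size`` metabolites guarantees a path to the
    readout; extra branch reactions and occasional competitive-inhibition or
    activation modifiers (drawn from upstream metabolites) decorate it.
    Always schema-valid.
    """
    n = max(int(spec.size), 2)
    rng = np.random.default_rng(spec.seed)
    mets = [Species("M0", float(rng.uniform(50, 150)))]
    mets += [Species(f"M{i}", 0.0) for i in range(1, n)]
    enzymes = [
        Species(f"E{i}", float(rng.uniform(0.5, 2.0)), "enzyme_pool")
        for i in range(1, n)
    ]
    reactions: list[Reaction] = []
    for i in range(1, n):
        k_cat = float(rng.uniform(0.5, 2.0))
        k_m = float(rng.uniform(0.5, 5.0))
        kind = "michaelis_menten"
        constants = {"K_cat": k_cat, "K_m": k_m}
        modifiers: dict[str, str] = {}
        if i > 1 and rng.random() < float(spec.params.get("p_modifier", 0.3)):
            upstream = f"M{int(rng.integers(0, i - 1))}"
            if rng.random() < 0.5:
                kind = "competitive_inhibition"
                constants["K_i"] = float(rng.uniform(1.0, 10.0))
                modifiers["inhibitor"] = upstream
            else:
                kind = "activation"
                constants["KI"] = float(rng.uniform(1.0, 10.0))
                modifiers["activator"] = upstream
        reactions.append(
            Reaction(
                id=f"r{i}",
                law=KineticLaw(kind, constants),
                enzyme=f"E{i}",
                substrate=f"M{i-1}",
                product=f"M{i}",
                modifiers=modifiers,
            )
        )
    return NetworkModel(
        species=mets + enzymes,
        reactions=reactions,
        targets=[e.id for e in enzymes],
        readout=f"M{n-1}",
        horizon=float(spec.params.get("horizon", 10.0)),
    )


def make_fixture(spec: FixtureSpec) -> NetworkModel:
    """Dispatch a :class:`FixtureSpec` to its generator."""
    if spec.kind == "linear_cascade":
        return make_cascade(max(spec.size - 1, 1), **spec.params)
    if spec.kind == "additive_pair":
        return make_additive_pair_model(**spec.params)
    if spec.kind == "insensitive_pair":
        return make_insensitive_pair_fixture(**spec.params)
    if spec.kind == "random":
        return random_network(spec)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")
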