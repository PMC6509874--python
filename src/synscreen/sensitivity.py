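"""Single-target sensitivity analysis.

For each candidate target enzyme the screen asks: by how much must its
concentration be changed (in either direction) so that the cumulative readout
output over the horizon drops *just below* a fraction θ of the untreated
(disease) output?  The relative perturbation ΔE/E_d — the method's dose proxy
— ranks targets, and a threshold *a* splits them into sensitive (ΔE/E_d ≤ a)
and insensitive targets.

"Just below" is operationalised by bracketing + bisection on the monotone
dose–effect curve until the achieved effect lies within ``effect_tolerance``
(relative) below θ·disease_output.  Both perturbation directions are
searched; the cheaper (smaller-ratio) feasible one is reported.  A target for
which neither direction reaches the criterion within bounds is classified
``infeasible`` rather than raising, so batch screens stay total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

from .model import ModelValidationError, NetworkModel
from .simulate import Perturbation, SimulationError, cumulative_output, simulate

__all__ = [
    "StateCriterion",
    "ScreenConfig",
    "SensitivityRecord",
    "SearchError",
    "effect",
    "is_normal",
    "disease_criterion",
    "find_effective_dose",
    "rank_and_classify",
]


class SearchError(RuntimeError):
    """Non-monotone dose–effect detected where bisection was assumed valid."""


@dataclass(frozen=True)
class StateCriterion:
    """Normal-state definition: cumulative output < theta * disease output."""

    theta: float = 0.10
    disease_output: float = float("nan")

    def __post_init__(self) -> None:
        if not 0 < self.theta < 1:
            raise ModelValidationError("theta must lie in (0, 1)")
        if not self.disease_output > 0:
            raise ModelValidationError("disease_output must be > 0")

    @property
    def threshold(self) -> float:
        return self.theta * self.disease_output


@dataclass(frozen=True)
class ScreenConfig:
    """Tunable knobs of the whole screening pipeline."""

    a: float = 1.0                 # sensitivity threshold on ΔE/E_d
    theta: float = 0.10            # normal-state fraction of the disease output
    alpha: float = 0.8             # dose-reduction factor of the mixed screen
    dose_grid_step: float = 0.1    # isobologram grid spacing in fractional dose
    effect_tolerance: float = 1e-3 # relative "just below" tolerance
    max_fold_increase: float = 1e18
    max_bisect_iter: int = 200
    readout_mode: str = "flux"
    rtol: float = 1e-8
    atol: float = 1e-12

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ModelValidationError("alpha must lie in (0, 1)")
        if not self.a > 0:
            raise ModelValidationError("a must be > 0")
        if not 0 < self.theta < 1:
            raise ModelValidationError("theta must lie in (0, 1)")


@dataclass(frozen=True)
class SensitivityRecord:
    """Outcome of the effective-dose search for one target."""

    target: str
    E_di: float
    E_hi: float
    delta_E: float
    ratio: float
    direction: str          # "decrease" | "increase"
    classification: str     # "sensitive" | "insensitive" | "infeasible"
    effect: float = float("nan")

    @staticmethod
    def from_dose(
        target: str, E_di: float, E_hi: float, a: float, effect_value: float
    ) -> "SensitivityRecord":
        delta = abs(E_di - E_hi)
        ratio = delta / E_di
        return SensitivityRecord(
            target=target,
            E_di=E_di,
            E_hi=E_hi,
            delta_E=delta,
            ratio=ratio,
            direction="decrease" if E_hi <= E_di else "increase",
            classification="sensitive" if ratio <= a else "insensitive",
            effect=effect_value,
        )

    @staticmethod
    def infeasible(target: str, E_di: float) -> "SensitivityRecord":
        return SensitivityRecord(
            target=target,
            E_di=E_di,
            E_hi=float("nan"),
            delta_E=float("nan"),
            ratio=float("inf"),
            direction="decrease",
            classification="infeasible",
        )


# ---------------------------------------------------------------------------
# effect evaluation
# ---------------------------------------------------------------------------

def effect(
    model: NetworkModel,
    perturbations: Sequence[Perturbation] = (),
    config: ScreenConfig | None = None,
) -> float:
    """Cumulative readout output under the given perturbations."""
    config = config or ScreenConfig()
    traj = simulate(
        model,
        perturbations,
        rtol=config.rtol,
        atol=config.atol,
        readout_mode=config.readout_mode,
    )
    return cumulative_output(traj, model)


def disease_criterion(
    model: NetworkModel, config: ScreenConfig | None = None
) -> StateCriterion:
    """Criterion whose baseline is the unperturbed (disease) output."""
    config = config or ScreenConfig()
    return StateCriterion(theta=config.theta, disease_output=effect(model, (), config))


def is_normal(
    model: NetworkModel,
    perturbations: Sequence[Perturbation],
    criterion: StateCriterion,
    config: ScreenConfig | None = None,
) -> bool:
    """True iff the perturbed network reaches the normal state."""
    return effect(model, perturbations, config) < criterion.threshold


# ---------------------------------------------------------------------------
# bisection machinery
# ---------------------------------------------------------------------------

def solve_just_below(
    g: Callable[[float], float],
    x_feasible: float,
    x_infeasible: float,
    g_feasible: float,
    threshold: float,
    rel_tol: float,
    max_iter: int = 200,
) -> tuple[float, float]:
    """Bisect a monotone effect curve to the "just below threshold" dose.

    ``g(x_feasible) < threshold <= g(x_infeasible)``.  Returns ``(x, g(x))``
    with ``g(x) < threshold`` and ``threshold - g(x) <= rel_tol * threshold``.

    Internally the loop aims one order of magnitude tighter than ``rel_tol``
    (still "within" it), so that dose errors stay small relative to the
    effect tolerance when doses are later compared in fractional units.
    """
    if not g_feasible < threshold:
        raise SearchError("feasible endpoint does not meet the criterion")
    xf, gf = x_feasible, g_feasible
    xi = x_infeasible
    target_gap = 0.1 * rel_tol * threshold
    for _ in range(max_iter):
        if threshold - gf <= target_gap:
            return xf, gf
        xm = 0.5 * (xf + xi)
        gm = g(xm)
        if gm < threshold:
            xf, gf = xm, gm
        else:
            xi = xm
    if threshold - gf <= rel_tol * threshold:
        return xf, gf
    raise SearchError(
        "bisection did not converge to the 'just below' tolerance; the "
        "dose-effect curve may be non-monotone — use a dense grid fallback"
    )


def _bracket_increase(
    g: Callable[[float], float],
    E_di: float,
    threshold: float,
    max_fold: float,
    grow: float = 4.0,
    g_start: float | None = None,
) -> tuple[float, float, float] | None:
    """Find an increase-direction dose whose effect falls below threshold.

    Expansion stops as soon as the effect stops improving (the monotone
    dose-effect assumption: once raising the enzyme no longer lowers the
    output, it never will) or the integrator gives up at an extreme dose.
    Returns (x_feasible, g_feasible, x_infeasible_below_it) or None.
    """
    lo = E_di if E_di > 0 else 1.0
    x = lo
    prev = lo
    prev_g = g_start
    while x <= lo * max_fold:
        x = x * grow
        try:
            gx = g(x)
        except SimulationError:
            return None
        if gx < threshold:
            return x, gx, prev
        if prev_g is not None and gx >= prev_g:
            return None
        prev, prev_g = x, gx
    return None


def find_effective_dose(
    model: NetworkModel,
    target: str,
    criterion: StateCriterion,
    config: ScreenConfig | None = None,
    base_perturbations: Sequence[Perturbation] = (),
) -> SensitivityRecord:
    """Search both directions for the cheapest dose reaching the normal state.

    ``base_perturbations`` (other targets held at fixed doses) lets the same
    search serve the combination screens.
    """
    config = config or ScreenConfig()
    if target not in model.targets:
        raise ModelValidationError(f"{target!r} is not a declared drug target")
    E_di = model.species_by_id(target).initial_concentration
    if E_di <= 0:
        raise ModelValidationError(f"target {target!r} has zero initial concentration")
    thr = criterion.threshold

    def g(conc: float) -> float:
        perts = [p for p in base_perturbations if p.target != target]
        perts.append(Perturbation(target, conc))
        return effect(model, perts, config)

    g0 = g(E_di)
    if g0 < thr:
        # criterion already met without moving this target
        return SensitivityRecord.from_dose(target, E_di, E_di, config.a, g0)

    candidates: list[SensitivityRecord] = []

    # decrease direction: [0, E_di]
    g_zero = g(0.0)
    if g_zero < thr:
        x, gx = solve_just_below(
            g, 0.0, E_di, g_zero, thr, config.effect_tolerance, config.max_bisect_iter
        )
        candidates.append(SensitivityRecord.from_dose(target, E_di, x, config.a, gx))

    # increase direction: (E_di, E_di * max_fold_increase]
    br = _bracket_increase(g, E_di, thr, config.max_fold_increase, g_start=g0)
    if br is not None:
        xf, gf, xi = br
        x, gx = solve_just_below(
            g, xf, xi, gf, thr, config.effect_tolerance, config.max_bisect_iter
        )
        candidates.append(SensitivityRecord.from_dose(target, E_di, x, config.a, gx))

    if not candidates:
        return SensitivityRecord.infeasible(target, E_di)
    return min(candidates, key=lambda r: r.ratio)


def rank_and_classify(
    model: NetworkModel,
    criterion: StateCriterion | None = None,
    config: ScreenConfig | None = None,
) -> list[SensitivityRecord]:
    """One record per declared target, sorted ascending by ΔE/E_d.

    Infeasible targets sort last (ratio = inf).  The order is invariant to
    the targets' declaration order (ties broken by target id).
    """
    config = config or ScreenConfig()
    if criterion is None:
        criterion = disease_criterion(model, config)
    if not model.targets:
        raise ModelValidationError("model declares no drug targets")
    records = [
        find_effective_dose(model, t, criterion, config) for t in model.targets
    ]
    return sorted(records, key=lambda r: (r.ratio, r.target))
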