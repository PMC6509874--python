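"""Two-target combination screening: CI isobolograms, joint-feasibility and
α-assisted dose reduction.

Three branches, chosen by the single-target classification of the pair:

* **sensitive + sensitive** — Loewe combination index.  For a pair (A, B)
  with single effective doses (Dx)_A, (Dx)_B, each grid fraction f1 of A's
  dose is held fixed and B's remaining dose is found by bisection to the same
  normal-state effect.  Every equal-effect point gives
  CI = f1 + ΔE_B/(Dx)_B; CI < 1 synergy, > 1 antagonism, = 1 additivity, and
  a pair crossing 1 across the grid is *hybrid*.

* **insensitive + insensitive** — neither target can reach the normal state
  alone with ΔE/E_d ≤ 1, but a joint perturbation may.  A common relative
  dose scalar s ∈ (0, 1] applied to both targets (each in a candidate
  direction) is bisected to the criterion, then each axis is refined
  downward.  The pair is synergistic iff a feasible joint point exists with
  both ratios ≤ 1.

* **sensitive + insensitive** — the sensitive target's dose is cut to a
  fraction α < 1 of its single effective dose and the insensitive partner
  must cover the remaining effect with ΔE/E_d ≤ 1 (drug-sparing synergy).

Graded synergism/antagonism labels follow the Chou-style CI grading table.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .model import ModelValidationError, NetworkModel
from .sensitivity import (
    ScreenConfig,
    SearchError,
    SensitivityRecord,
    StateCriterion,
    disease_criterion,
    effect,
    find_effective_dose,
    rank_and_classify,
    solve_just_below,
    _bracket_increase,
)
from .simulate import Perturbation

__all__ = [
    "GRADING_TABLE",
    "DosePoint",
    "Isobologram",
    "PairVerdict",
    "ScreenReport",
    "ScreenError",
    "grade",
    "dose_for_effect",
    "ci_isobologram",
    "screen_insensitive_pair",
    "screen_mixed_pair",
    "screen_all",
]

#: CI grading bins, left-closed right-open: (upper bound, description, symbols)
GRADING_TABLE: tuple[tuple[float, str, str], ...] = (
    (0.1, "very strong synergism", "+ + + + +"),
    (0.3, "strong synergism", "+ + + +"),
    (0.7, "synergism", "+ + +"),
    (0.85, "moderate synergism", "+ +"),
    (0.90, "slight synergism", "+"),
    (1.10, "nearly additive", "+ -"),
    (1.20, "slight antagonism", "-"),
    (1.45, "moderate antagonism", "- -"),
    (3.3, "antagonism", "- - -"),
    (10.0, "strong antagonism", "- - - -"),
    (float("inf"), "very strong antagonism", "- - - - -"),
)

#: |CI - 1| band of the "nearly additive" bin, used for the category call
ADDITIVE_BAND = 0.10


class ScreenError(RuntimeError):
    pass


def grade(ci: float) -> tuple[str, str]:
    """Graded description and symbols of a combination index value.

    Bins are left-closed/right-open, so the boundary value 1.45 grades as
    "antagonism" and 0.90 as "nearly additive".
    """
    if not ci > 0:
        raise ValueError("CI must be positive")
    for upper, description, symbols in GRADING_TABLE:
        if ci < upper:
            return description, symbols
    raise AssertionError("unreachable: bins partition (0, inf)")


@dataclass(frozen=True)
class DosePoint:
    """One equal-effect dose pair in fractional single-dose units."""

    f1: float
    f2: float

    @property
    def ci(self) -> float:
        return self.f1 + self.f2


@dataclass
class Isobologram:
    """Equal-effect contour of a sensitive pair with its CI verdict."""

    pair: tuple[str, str]
    points: list[DosePoint]
    category: str                       # synergy | antagonism | additive | hybrid
    representative_ci: list[float]      # one value, or [ci_min, ci_max] for hybrid
    grades: list[tuple[str, str]]

    @property
    def ci_min(self) -> float:
        return min(p.ci for p in self.points)

    @property
    def ci_max(self) -> float:
        return max(p.ci for p in self.points)

    @property
    def synergistic(self) -> bool:
        # a pair counts as synergistic if any dose ratio achieves CI < 1
        return self.ci_min < 1.0


@dataclass
class PairVerdict:
    pair: tuple[str, str]
    branch: str                       # sensitive | insensitive | mixed
    synergistic: bool
    evidence: dict = field(default_factory=dict)


@dataclass
class ScreenReport:
    """Full deterministic screening report over all target pairs."""

    records: list[SensitivityRecord]
    isobolograms: list[Isobologram]
    insensitive_verdicts: list[PairVerdict]
    mixed_verdicts: list[PairVerdict]

    @property
    def sensitive_synergistic(self) -> int:
        return sum(iso.synergistic for iso in self.isobolograms)

    @property
    def total_synergistic(self) -> int:
        return (
            self.sensitive_synergistic
            + sum(v.synergistic for v in self.insensitive_verdicts)
            + sum(v.synergistic for v in self.mixed_verdicts)
        )

    def to_dict(self) -> dict:
        return {
            "targets": [
                {
                    "target": r.target,
                    "E_di": r.E_di,
                    "E_hi": r.E_hi,
                    "delta_E": r.delta_E,
                    "ratio": r.ratio,
                    "direction": r.direction,
                    "classification": r.classification,
                }
                for r in self.records
            ],
            "isobolograms": [
                {
                    "pair": list(iso.pair),
                    "points": [[p.f1, p.f2, p.ci] for p in iso.points],
                    "ci_min": iso.ci_min,
                    "ci_max": iso.ci_max,
                    "category": iso.category,
                    "representative_ci": iso.representative_ci,
                    "grades": [list(g) for g in iso.grades],
                    "synergistic": iso.synergistic,
                }
                for iso in self.isobolograms
            ],
            "insensitive_pairs": [
                {"pair": list(v.pair), "synergistic": v.synergistic, **v.evidence}
                for v in self.insensitive_verdicts
            ],
            "mixed_pairs": [
                {"pair": list(v.pair), "synergistic": v.synergistic, **v.evidence}
                for v in self.mixed_verdicts
            ],
            "counts": {
                "sensitive_branch": self.sensitive_synergistic,
                "insensitive_branch": sum(
                    v.synergistic for v in self.insensitive_verdicts
                ),
                "mixed_branch": sum(v.synergistic for v in self.mixed_verdicts),
                "total_synergistic": self.total_synergistic,
            },
        }


# ---------------------------------------------------------------------------
# partner-conditioned dose search
# ---------------------------------------------------------------------------

def _perturbed_conc(E_d: float, delta: float, direction: str) -> float:
    return E_d - delta if direction == "decrease" else E_d + delta


def dose_for_effect(
    model: NetworkModel,
    target: str,
    partner_dose: Perturbation | None,
    criterion: StateCriterion,
    config: ScreenConfig | None = None,
    direction: str | None = None,
) -> float | None:
    """Dose magnitude ΔE of ``target`` that just meets the criterion while the
    partner's perturbation is held fixed.

    With ``direction=None`` both directions are searched and the smaller ΔE
    returned (with no partner this reduces to the single-target search).
    Returns 0.0 if the partner alone already meets the criterion, and None if
    the target is infeasible within bounds.
    """
    config = config or ScreenConfig()
    base = (partner_dose,) if partner_dose is not None else ()
    E_di = model.species_by_id(target).initial_concentration
    thr = criterion.threshold

    def g(conc: float) -> float:
        perts = list(base) + [Perturbation(target, conc)]
        return effect(model, perts, config)

    g0 = g(E_di)
    if g0 < thr:
        return 0.0

    doses: list[float] = []
    if direction in (None, "decrease"):
        g_zero = g(0.0)
        if g_zero < thr:
            x, _ = solve_just_below(
                g, 0.0, E_di, g_zero, thr,
                config.effect_tolerance, config.max_bisect_iter,
            )
            doses.append(E_di - x)
    if direction in (None, "increase"):
        br = _bracket_increase(g, E_di, thr, config.max_fold_increase, g_start=g0)
        if br is not None:
            xf, gf, xi = br
            x, _ = solve_just_below(
                g, xf, xi, gf, thr,
                config.effect_tolerance, config.max_bisect_iter,
            )
            doses.append(x - E_di)
    return min(doses) if doses else None


# ---------------------------------------------------------------------------
# sensitive branch: CI isobologram
# ---------------------------------------------------------------------------

def _grid(step: float) -> list[float]:
    fracs = []
    k = 1
    while (f := k * step) < 1.0 - 1e-12:
        fracs.append(round(f, 12))
        k += 1
    return fracs


def ci_isobologram(
    model: NetworkModel,
    pair: tuple[str, str],
    criterion: StateCriterion,
    config: ScreenConfig | None = None,
    records: dict[str, SensitivityRecord] | None = None,
) -> Isobologram:
    """Equal-effect isobologram and CI verdict for a sensitive pair.

    ``records`` may carry precomputed single-target doses; otherwise they are
    recomputed.  Fractional doses are measured against each target's single
    effective dose in its own cheaper direction.
    """
    config = config or ScreenConfig()
    a_id, b_id = pair
    recs = records or {}
    rec_a = recs.get(a_id) or find_effective_dose(model, a_id, criterion, config)
    rec_b = recs.get(b_id) or find_effective_dose(model, b_id, criterion, config)
    for rec in (rec_a, rec_b):
        if rec.classification == "infeasible":
            raise ScreenError(f"{rec.target}: no finite single effective dose")

    points: list[DosePoint] = []
    for f1 in _grid(config.dose_grid_step):
        conc_a = _perturbed_conc(rec_a.E_di, f1 * rec_a.delta_E, rec_a.direction)
        delta_b = dose_for_effect(
            model, b_id, Perturbation(a_id, conc_a), criterion, config,
            direction=rec_b.direction,
        )
        if delta_b is None:
            warnings.warn(
                f"isobologram {a_id}-{b_id}: grid point f1={f1:g} infeasible; dropped"
            )
            continue
        points.append(DosePoint(f1, delta_b / rec_b.delta_E))
    if not points:
        raise ScreenError(f"isobologram {a_id}-{b_id}: every grid point infeasible")

    cis = [p.ci for p in points]
    lo, hi = min(cis), max(cis)
    band_lo, band_hi = 1.0 - ADDITIVE_BAND, 1.0 + ADDITIVE_BAND
    if all(band_lo <= c <= band_hi for c in cis):
        category = "additive"
        rep = [hi if hi - 1.0 >= 1.0 - lo else lo]
    elif hi < band_lo:
        category = "synergy"
        rep = [lo]
    elif lo > band_hi:
        category = "antagonism"
        rep = [hi]
    else:
        category = "hybrid"
        rep = [lo, hi]
    return Isobologram(
        pair=pair,
        points=points,
        category=category,
        representative_ci=rep,
        grades=[grade(c) for c in rep],
    )


# ---------------------------------------------------------------------------
# insensitive branch: joint feasibility
# ---------------------------------------------------------------------------

_DIRECTION_COMBOS = tuple(itertools.product(("decrease", "increase"), repeat=2))


def screen_insensitive_pair(
    model: NetworkModel,
    pair: tuple[str, str],
    criterion: StateCriterion,
    config: ScreenConfig | None = None,
) -> PairVerdict:
    """Joint-perturbation feasibility screen for two insensitive targets.

    A common relative-dose scalar s ∈ (0, 1] is applied to both targets and
    bisected to the criterion, then each axis is refined downward while the
    other is held.  Synergistic iff a feasible point with both ΔE/E_d ≤ 1
    exists; infeasibility is a verdict, never an error.
    """
    config = config or ScreenConfig()
    t1, t2 = pair
    E1 = model.species_by_id(t1).initial_concentration
    E2 = model.species_by_id(t2).initial_concentration
    thr = criterion.threshold

    def joint_effect(r1: float, d1: str, r2: float, d2: str) -> float:
        perts = [
            Perturbation(t1, _perturbed_conc(E1, r1 * E1, d1)),
            Perturbation(t2, _perturbed_conc(E2, r2 * E2, d2)),
        ]
        return effect(model, perts, config)

    for d1, d2 in _DIRECTION_COMBOS:
        g_full = joint_effect(1.0, d1, 1.0, d2)
        if not g_full < thr:
            continue

        def g_common(s: float) -> float:
            return joint_effect(s, d1, s, d2)

        s_star, _ = solve_just_below(
            g_common, 1.0, 0.0, g_full, thr,
            config.effect_tolerance, config.max_bisect_iter,
        )
        # per-axis refinement: shrink each ratio with the other held fixed
        r1, r2 = s_star, s_star

        def g_axis1(r: float) -> float:
            return joint_effect(r, d1, r2, d2)

        g1_zero = g_axis1(0.0)
        if g1_zero < thr:
            r1 = 0.0
        else:
            r1, _ = solve_just_below(
                g_axis1, r1, 0.0, g_axis1(r1), thr,
                config.effect_tolerance, config.max_bisect_iter,
            )

        def g_axis2(r: float) -> float:
            return joint_effect(r1, d1, r, d2)

        g2_zero = g_axis2(0.0)
        if g2_zero < thr:
            r2 = 0.0
        else:
            r2, _ = solve_just_below(
                g_axis2, r2, 0.0, g_axis2(r2), thr,
                config.effect_tolerance, config.max_bisect_iter,
            )
        return PairVerdict(
            pair=pair,
            branch="insensitive",
            synergistic=True,
            evidence={
                "ratios": {t1: r1, t2: r2},
                "directions": {t1: d1, t2: d2},
            },
        )
    return PairVerdict(pair=pair, branch="insensitive", synergistic=False)


# ---------------------------------------------------------------------------
# mixed branch: α-assisted dose reduction
# ---------------------------------------------------------------------------

def screen_mixed_pair(
    model: NetworkModel,
    sensitive_record: SensitivityRecord,
    insensitive_target: str,
    criterion: StateCriterion,
    config: ScreenConfig | None = None,
) -> PairVerdict:
    """α-assisted screen: the sensitive target's dose is cut to α·(Dx) and the
    insensitive partner must cover the remainder with ΔE/E_d ≤ 1."""
    config = config or ScreenConfig()
    if sensitive_record.classification != "sensitive":
        raise ScreenError(
            f"{sensitive_record.target}: mixed screen needs a sensitive first target"
        )
    j = sensitive_record
    reduced = config.alpha * j.delta_E
    partner = Perturbation(
        j.target, _perturbed_conc(j.E_di, reduced, j.direction)
    )
    E_di = model.species_by_id(insensitive_target).initial_concentration
    delta_i = dose_for_effect(
        model, insensitive_target, partner, criterion, config
    )
    pair = (j.target, insensitive_target)
    if delta_i is None:
        return PairVerdict(
            pair=pair, branch="mixed", synergistic=False,
            evidence={"alpha": config.alpha, "insensitive_ratio": None},
        )
    ratio_i = delta_i / E_di
    return PairVerdict(
        pair=pair,
        branch="mixed",
        synergistic=ratio_i <= 1.0,
        evidence={
            "alpha": config.alpha,
            "sensitive_reduced_delta_E": reduced,
            "insensitive_delta_E": delta_i,
            "insensitive_ratio": ratio_i,
        },
    )


# ---------------------------------------------------------------------------
# full screen
# ---------------------------------------------------------------------------

def screen_all(
    model: NetworkModel,
    criterion: StateCriterion | None = None,
    config: ScreenConfig | None = None,
) -> ScreenReport:
    """Rank all targets, then run every pair through its branch.

    Errors in one pair are isolated (the pair is reported with an ``error``
    evidence field) so a batch screen always yields a total report.
    """
    config = config or ScreenConfig()
    if criterion is None:
        criterion = disease_criterion(model, config)
    records = rank_and_classify(model, criterion, config)
    by_id = {r.target: r for r in records}
    sensitive = [r for r in records if r.classification == "sensitive"]
    non_sensitive = [r for r in records if r.classification != "sensitive"]

    isobolograms: list[Isobologram] = []
    for ra, rb in itertools.combinations(sensitive, 2):
        try:
            isobolograms.append(
                ci_isobologram(model, (ra.target, rb.target), criterion, config, by_id)
            )
        except (ScreenError, SearchError) as err:
            warnings.warn(f"pair ({ra.target}, {rb.target}): {err}")

    insensitive_verdicts = [
        screen_insensitive_pair(model, (r1.target, r2.target), criterion, config)
        for r1, r2 in itertools.combinations(non_sensitive, 2)
    ]
    mixed_verdicts = [
        screen_mixed_pair(model, rj, ri.target, criterion, config)
        for rj in sensitive
        for ri in non_sensitive
    ]
    return ScreenReport(
        records=records,
        isobolograms=isobolograms,
        insensitive_verdicts=insensitive_verdicts,
        mixed_verdicts=mixed_verdicts,
    )
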