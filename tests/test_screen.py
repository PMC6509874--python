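"""Combination screening: grading, isobolograms, joint and mixed screens."""

import numpy as np
import pytest

import synscreen as ss
from synscreen import (
    KineticLaw,
    NetworkModel,
    Perturbation,
    Reaction,
    ScreenConfig,
    Species,
    ci_isobologram,
    dose_for_effect,
    effect,
    find_effective_dose,
    grade,
    is_normal,
    rank_and_classify,
    screen_all,
    screen_insensitive_pair,
    screen_mixed_pair,
)
from conftest import grid_scan_dose


# ---------------------------------------------------------------------------
# CI grading
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "ci,description,symbols",
    [
        (0.05, "very strong synergism", "+ + + + +"),
        (0.1, "strong synergism", "+ + + +"),
        (0.3, "synergism", "+ + +"),
        (0.7, "moderate synergism", "+ +"),
        (0.85, "slight synergism", "+"),
        (0.8806, "slight synergism", "+"),
        (0.90, "nearly additive", "+ -"),
        (0.91, "nearly additive", "+ -"),
        (0.92, "nearly additive", "+ -"),
        (1.0, "nearly additive", "+ -"),
        (1.0442, "nearly additive", "+ -"),
        (1.10, "slight antagonism", "-"),
        (1.1850, "slight antagonism", "-"),
        (1.20, "moderate antagonism", "- -"),
        (1.45, "antagonism", "- - -"),
        (3.3, "strong antagonism", "- - - -"),
        (10.0, "very strong antagonism", "- - - - -"),
        (25.0, "very strong antagonism", "- - - - -"),
    ],
)
def test_grading_bins(ci, description, symbols):
    assert grade(ci) == (description, symbols)


def test_grade_requires_positive_ci():
    with pytest.raises(ValueError):
        grade(0.0)


# ---------------------------------------------------------------------------
# partner-conditioned dose search
# ---------------------------------------------------------------------------

def test_dose_for_effect_without_partner_matches_single_target(
    cascade2, cascade2_criterion, cascade2_records
):
    rec = cascade2_records["E1"]
    delta = dose_for_effect(cascade2, "E1", None, cascade2_criterion)
    assert delta == pytest.approx(rec.delta_E, rel=1e-3)


def test_partner_at_full_dose_requires_zero(cascade2, cascade2_criterion,
                                            cascade2_records):
    partner = Perturbation("E2", cascade2_records["E2"].E_hi)
    delta = dose_for_effect(cascade2, "E1", partner, cascade2_criterion)
    assert delta == 0.0


def test_dose_for_effect_with_half_dosed_partner_matches_grid_oracle(
    cascade2, cascade2_criterion, cascade2_records
):
    rec2 = cascade2_records["E2"]
    partner = Perturbation("E2", rec2.E_di - 0.5 * rec2.delta_E)
    delta = dose_for_effect(
        cascade2, "E1", partner, cascade2_criterion, direction="decrease"
    )
    e_di = cascade2_records["E1"].E_di
    oracle_conc = grid_scan_dose(
        cascade2, "E1", cascade2_criterion.threshold, 0.0, e_di,
        base_perturbations=[partner],
    )
    assert e_di - delta == pytest.approx(oracle_conc, rel=1e-3, abs=1e-3 * e_di)


# ---------------------------------------------------------------------------
# sensitive branch: isobolograms
# ---------------------------------------------------------------------------

def test_additive_pair_ci_is_one_everywhere(additive_isobologram,
                                            additive_config):
    tol = 2 * additive_config.effect_tolerance
    for p in additive_isobologram.points:
        assert abs(p.ci - 1.0) <= tol
        assert p.ci == p.f1 + p.f2
    assert additive_isobologram.category == "additive"
    assert len(additive_isobologram.points) == 9


def test_additive_pools_alone_reach_the_criterion(additive_pair,
                                                  additive_criterion,
                                                  additive_config,
                                                  additive_records):
    for rec in additive_records.values():
        assert rec.classification == "sensitive"
        assert rec.direction == "increase"
        assert is_normal(
            additive_pair, [Perturbation(rec.target, rec.E_hi)],
            additive_criterion, additive_config,
        )


def test_role_symmetry_on_additive_pair(additive_pair, additive_criterion,
                                        additive_config, additive_records,
                                        additive_isobologram):
    reverse = ci_isobologram(
        additive_pair, ("E_b", "E_a"), additive_criterion, additive_config,
        additive_records,
    )
    tol = 2 * additive_config.effect_tolerance
    assert abs(reverse.ci_min - additive_isobologram.ci_min) <= tol
    assert abs(reverse.ci_max - additive_isobologram.ci_max) <= tol


def test_role_symmetry_on_cascade_pair(cascade2, cascade2_criterion,
                                       cascade2_records):
    cfg = ScreenConfig()
    fwd = ci_isobologram(cascade2, ("E1", "E2"), cascade2_criterion, cfg,
                         cascade2_records)
    rev = ci_isobologram(cascade2, ("E2", "E1"), cascade2_criterion, cfg,
                         cascade2_records)
    tol = 2 * cfg.effect_tolerance
    assert abs(fwd.ci_min - rev.ci_min) <= tol + 1e-6
    assert abs(fwd.ci_max - rev.ci_max) <= tol + 1e-6


def test_isobologram_points_resimulate_to_the_criterion(cascade2,
                                                        cascade2_criterion,
                                                        cascade2_records):
    cfg = ScreenConfig()
    iso = ci_isobologram(cascade2, ("E1", "E2"), cascade2_criterion, cfg,
                         cascade2_records)
    r1, r2 = cascade2_records["E1"], cascade2_records["E2"]
    thr = cascade2_criterion.threshold
    for p in iso.points:
        perts = [
            Perturbation("E1", r1.E_di - p.f1 * r1.delta_E),
            Perturbation("E2", r2.E_di - p.f2 * r2.delta_E),
        ]
        eff = effect(cascade2, perts, cfg)
        assert eff < thr * (1 + cfg.effect_tolerance)
        assert (thr - eff) / thr <= cfg.effect_tolerance


# ---------------------------------------------------------------------------
# insensitive branch
# ---------------------------------------------------------------------------

def test_parallel_routes_are_individually_infeasible(insensitive_pair,
                                                     insensitive_criterion):
    records = rank_and_classify(insensitive_pair, insensitive_criterion)
    assert all(r.classification == "infeasible" for r in records)


def test_joint_perturbation_rescues_the_insensitive_pair(insensitive_pair,
                                                         insensitive_criterion):
    verdict = screen_insensitive_pair(
        insensitive_pair, ("E_a", "E_b"), insensitive_criterion
    )
    assert verdict.synergistic
    ratios = verdict.evidence["ratios"]
    assert all(0 < r <= 1.0 for r in ratios.values())
    # re-simulate the found joint point
    perts = [
        Perturbation(t, insensitive_pair.species_by_id(t).initial_concentration
                     * (1 - r))
        for t, r in ratios.items()
    ]
    assert is_normal(insensitive_pair, perts, insensitive_criterion)


def test_joint_feasibility_confirmed_by_2d_grid_oracle(insensitive_pair,
                                                       insensitive_criterion):
    """Exhaustive joint knockdown grid: no single-axis point is feasible but
    joint points are, independently of the bisection search policy."""
    thr = insensitive_criterion.threshold
    n = 21
    fractions = np.linspace(0.0, 1.0, n)
    feasible = np.zeros((n, n), bool)
    e_a = insensitive_pair.species_by_id("E_a").initial_concentration
    e_b = insensitive_pair.species_by_id("E_b").initial_concentration
    for i, sa in enumerate(fractions):
        for j, sb in enumerate(fractions):
            eff = effect(
                insensitive_pair,
                [Perturbation("E_a", e_a * (1 - sa)),
                 Perturbation("E_b", e_b * (1 - sb))],
            )
            feasible[i, j] = eff < thr
    assert not feasible[:, 0].any()   # E_a alone, any knockdown
    assert not feasible[0, :].any()   # E_b alone
    assert feasible.any()             # joint rescue exists
    assert feasible[-1, -1]           # double full knockout certainly works


def test_relaxed_threshold_makes_singles_feasible(insensitive_pair):
    cfg = ScreenConfig(theta=0.99)
    criterion = ss.disease_criterion(insensitive_pair, cfg)
    for t in ("E_a", "E_b"):
        rec = find_effective_dose(insensitive_pair, t, criterion, cfg)
        assert rec.classification != "infeasible"


def test_disjoint_dead_end_branches_stay_infeasible():
    """Two targets whose products never reach the readout cannot rescue it."""
    mm = lambda: KineticLaw("michaelis_menten", {"K_cat": 1.0, "K_m": 1.0})
    species = [
        Species("S", 100.0), Species("P", 0.0),
        Species("X", 100.0), Species("W", 0.0),
        Species("Y", 100.0), Species("V", 0.0),
        Species("E0", 1.0, "enzyme_pool"),
        Species("E_x", 1.0, "enzyme_pool"),
        Species("E_y", 1.0, "enzyme_pool"),
    ]
    reactions = [
        Reaction("main", mm(), "E0", substrate="S", product="P"),
        Reaction("dead_x", mm(), "E_x", substrate="X", product="W"),
        Reaction("dead_y", mm(), "E_y", substrate="Y", product="V"),
    ]
    m = NetworkModel(species, reactions, ["E0", "E_x", "E_y"], "P", 10.0)
    criterion = ss.disease_criterion(m)
    verdict = screen_insensitive_pair(m, ("E_x", "E_y"), criterion)
    assert not verdict.synergistic


# ---------------------------------------------------------------------------
# mixed branch
# ---------------------------------------------------------------------------

def asymmetric_routes():
    """Parallel routes where E_a carries ~95% of the flux: E_a is sensitive,
    E_b is infeasible alone, and the mixed screen outcome flips with alpha."""
    mm = lambda: KineticLaw("michaelis_menten", {"K_cat": 1.0, "K_m": 1.0})
    species = [
        Species("S_a", 100.0), Species("S_b", 100.0), Species("R", 0.0),
        Species("E_a", 1.9, "enzyme_pool"),
        Species("E_b", 0.1, "enzyme_pool"),
    ]
    reactions = [
        Reaction("route_a", mm(), "E_a", substrate="S_a", product="R"),
        Reaction("route_b", mm(), "E_b", substrate="S_b", product="R"),
    ]
    return NetworkModel(species, reactions, ["E_a", "E_b"], "R", 10.0)


@pytest.fixture(scope="module")
def mixed_setup():
    model = asymmetric_routes()
    criterion = ss.disease_criterion(model)
    rec_a = find_effective_dose(model, "E_a", criterion)
    rec_b = find_effective_dose(model, "E_b", criterion)
    return model, criterion, rec_a, rec_b


def test_mixed_fixture_classifications(mixed_setup):
    _, _, rec_a, rec_b = mixed_setup
    assert rec_a.classification == "sensitive"
    assert rec_a.direction == "decrease"
    assert rec_b.classification == "infeasible"


def test_mixed_screen_near_unit_alpha_is_trivially_synergistic(mixed_setup):
    model, criterion, rec_a, _ = mixed_setup
    verdict = screen_mixed_pair(
        model, rec_a, "E_b", criterion, ScreenConfig(alpha=0.99)
    )
    assert verdict.synergistic
    assert verdict.evidence["insensitive_ratio"] <= 1.0


def test_mixed_screen_is_monotone_in_alpha(mixed_setup):
    model, criterion, rec_a, _ = mixed_setup
    outcomes = {
        alpha: screen_mixed_pair(
            model, rec_a, "E_b", criterion, ScreenConfig(alpha=alpha)
        ).synergistic
        for alpha in (0.8, 0.95, 0.99)
    }
    # once synergistic at some alpha, synergistic at every larger alpha
    seen_true = False
    for alpha in sorted(outcomes):
        if seen_true:
            assert outcomes[alpha]
        seen_true = seen_true or outcomes[alpha]
    assert outcomes[0.99]            # near-unit alpha always rescues
    assert not outcomes[0.8]         # E_b cannot cover 20% of the effect


def test_mixed_insensitive_dose_matches_grid_oracle(mixed_setup):
    model, criterion, rec_a, _ = mixed_setup
    cfg = ScreenConfig(alpha=0.95)
    verdict = screen_mixed_pair(model, rec_a, "E_b", criterion, cfg)
    assert verdict.synergistic
    partner = Perturbation("E_a", rec_a.E_di - cfg.alpha * rec_a.delta_E)
    e_b = model.species_by_id("E_b").initial_concentration
    oracle_conc = grid_scan_dose(
        model, "E_b", criterion.threshold, 0.0, e_b,
        base_perturbations=[partner],
    )
    found_conc = e_b - verdict.evidence["insensitive_delta_E"]
    assert found_conc == pytest.approx(oracle_conc, rel=1e-3, abs=1e-3 * e_b)


# ---------------------------------------------------------------------------
# full screen
# ---------------------------------------------------------------------------

def test_screen_all_composes_branch_calls(insensitive_pair,
                                          insensitive_criterion):
    report = screen_all(insensitive_pair, insensitive_criterion)
    assert len(report.records) == 2
    assert report.isobolograms == []
    assert report.mixed_verdicts == []
    assert len(report.insensitive_verdicts) == 1
    direct = screen_insensitive_pair(
        insensitive_pair, ("E_a", "E_b"), insensitive_criterion
    )
    v = report.insensitive_verdicts[0]
    assert v.synergistic == direct.synergistic
    assert v.evidence == direct.evidence
    assert report.total_synergistic == int(direct.synergistic)


def test_screen_all_single_target_has_no_pairs():
    m = ss.make_cascade(1)
    report = screen_all(m)
    assert len(report.records) == 1
    assert report.isobolograms == []
    assert report.insensitive_verdicts == []
    assert report.mixed_verdicts == []
    assert report.total_synergistic == 0


def test_report_serialization_roundtrip(insensitive_pair,
                                        insensitive_criterion):
    import json

    report = screen_all(insensitive_pair, insensitive_criterion)
    doc = json.loads(json.dumps(report.to_dict()))
    assert doc["counts"]["total_synergistic"] == report.total_synergistic
    assert {r["target"] for r in doc["targets"]} == {"E_a", "E_b"}
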