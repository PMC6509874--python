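"""Shared fixtures: small networks and (expensive) precomputed screen results.

Session scope is used for anything that integrates ODEs repeatedly, so the
bisection searches and isobolograms are computed once and shared.
"""

import numpy as np
import pytest

import synscreen as ss


@pytest.fixture(scope="session")
def cascade2():
    return ss.make_cascade(2)


@pytest.fixture(scope="session")
def cascade2_criterion(cascade2):
    return ss.disease_criterion(cascade2)


@pytest.fixture(scope="session")
def cascade2_records(cascade2, cascade2_criterion):
    recs = ss.rank_and_classify(cascade2, cascade2_criterion)
    return {r.target: r for r in recs}


@pytest.fixture(scope="session")
def additive_pair():
    return ss.make_additive_pair_model()


@pytest.fixture(scope="session")
def additive_config():
    return ss.ScreenConfig(theta=ss.ADDITIVE_PAIR_THETA)


@pytest.fixture(scope="session")
def additive_criterion(additive_pair, additive_config):
    return ss.disease_criterion(additive_pair, additive_config)


@pytest.fixture(scope="session")
def additive_records(additive_pair, additive_criterion, additive_config):
    recs = ss.rank_and_classify(additive_pair, additive_criterion, additive_config)
    return {r.target: r for r in recs}


@pytest.fixture(scope="session")
def additive_isobologram(additive_pair, additive_criterion, additive_config,
                         additive_records):
    return ss.ci_isobologram(
        additive_pair, ("E_a", "E_b"), additive_criterion, additive_config,
        additive_records,
    )


@pytest.fixture(scope="session")
def insensitive_pair():
    return ss.make_insensitive_pair_fixture()


@pytest.fixture(scope="session")
def insensitive_criterion(insensitive_pair):
    return ss.disease_criterion(insensitive_pair)


@pytest.fixture(scope="session")
def aa_model():
    return ss.load_aa_model()


@pytest.fixture(scope="session")
def aa_criterion(aa_model):
    return ss.disease_criterion(aa_model)


def grid_scan_dose(model, target, threshold, lo, hi, config=None,
                   n_coarse=256, n_fine=256, base_perturbations=()):
    """Independent dense-grid oracle for the 'just below threshold' dose.

    Scans the dose-effect curve on a coarse grid over [lo, hi] (decrease
    direction: effect rises with concentration), brackets the crossing, then
    rescans the bracket on a fine grid — effective resolution
    (hi-lo)/(n_coarse*n_fine), i.e. finer than a flat 10^4-point scan.
    Returns the concentration just below the crossing.  Deliberately avoids
    the package's bisection machinery: only `effect` is reused.
    """
    config = config or ss.ScreenConfig()

    def eff(conc):
        perts = list(base_perturbations) + [ss.Perturbation(target, conc)]
        return ss.effect(model, perts, config)

    def scan(a, b, n):
        xs = np.linspace(a, b, n)
        vals = [eff(x) for x in xs]
        below = [i for i, v in enumerate(vals) if v < threshold]
        if not below:
            return None
        i = max(below)  # last feasible point before the crossing
        return xs, vals, i

    res = scan(lo, hi, n_coarse)
    assert res is not None, "no feasible dose on coarse grid"
    xs, vals, i = res
    if i + 1 >= len(xs):
        return xs[i]
    res = scan(xs[i], xs[i + 1], n_fine)
    assert res is not None
    xs2, vals2, j = res
    return xs2[j]
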