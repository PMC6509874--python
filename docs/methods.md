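# Methods

## Model and rate laws

A network is a list of species (metabolites and enzyme pools) and
irreversible single-substrate reactions, each governed by one of five rate
laws: Michaelis–Menten `v = K_cat[E_t][S]/(K_m+[S])`; competitive inhibition
`v = K_cat[E_t][S]/(K_m(1+[I]/K_i)+[S])`; irreversible enzyme inactivation
`d[E]/dt = −K[E][I]`; activator-boosted catalysis
`v = K_cat(1+[A]/KI)[E_t][S]/(K_m+[S])`; and transcriptional upregulation
`d[E]/dt = k_max[g]²/([g]²+k_half²)` (Hill coefficient fixed at 2). The two
constants of the upregulation law are named `k_max` (maximal synthesis rate)
and `k_half` (half-saturation concentration) — the numerator multiplier and
the denominator constant of the Hill form. Catalytic fluxes are applied −v
to the substrate and +v to the product; a substrate is consumed, so the
catalytic expression is treated as a flux magnitude even where the classical
form is written with a positive d[S]/dt. Multi-substrate kinetics,
reversible laws and compartments are out of scope. Units are model-declared
and opaque to the engine; only internal consistency is required.

## Simulation and the readout

Integration uses LSODA (stiff-capable, adaptive) at `rtol = 1e−8`,
`atol = 1e−12`, with 201 evenly spaced saved points; concentrations are
clipped at zero for flux evaluation if the integrator steps slightly
negative. "Cumulative production" of the readout is the time-integral of
synthesis flux into it, carried as an auxiliary integrated state so its
accuracy is governed by the same tolerances. This choice matters: in the AA
network LTB4 is itself degraded (by CYP4F3), and a consumption-side target
can lower the readout *level* without touching its production, so flux
accounting is the interpretable dose–effect measure. `readout_mode="level"`
preserves the final-concentration reading for comparison; all defaults use
flux mode.

A drug dose is a step perturbation — the target enzyme pool's initial
concentration is replaced at t = 0. No pharmacokinetics, time-varying dosing
or event handling is modelled.

## Dose searches

The normal-state criterion is `output < θ·disease_output` (θ = 0.10 by
default). "Just below" is operationalised as bracketing + bisection on the
monotone dose–effect curve until the achieved effect is within
`effect_tolerance = 1e−3` (relative) below the threshold; internally the
loop aims an order of magnitude tighter, so that dose errors remain small
when doses are later compared in fractional units (a CI is a ratio of two
bisected doses; the tighter interior target keeps its error well inside
2×`effect_tolerance`). Both perturbation directions are searched — decrease
within [0, E_d], increase within (E_d, E_d·10¹⁸] by geometric expansion —
and the smaller-ratio feasible direction is reported. Expansion in the
increase direction stops as soon as the effect stops improving: under the
monotone dose–effect assumption that CI/isobologram methodology presumes,
further increase cannot help. A target with no feasible direction is
classified `infeasible` (a verdict, not an error), keeping batch screens
total.

## Screening branches

*Sensitive pairs.* Fractional doses are measured against each target's
single effective dose `Dx` in its own direction. For each grid fraction
`f1 ∈ {0.1, …, 0.9}` (endpoints excluded — they reduce to single-target
cases) of A's dose, B's remaining dose is bisected to the criterion with A
held fixed, giving the equal-effect point `(f1, ΔE_B/Dx_B)` and
`CI = f1 + f2`. The category call uses the "nearly additive" band
|CI − 1| ≤ 0.10: *additive* if all points are inside it, *synergy* if all
are below, *antagonism* if all above, *hybrid* otherwise. The representative
CI is the smallest CI for synergy, the largest for antagonism, the extreme
farther from 1 for additive, and both extremes (with separate grades) for
hybrid pairs. Independently of the graded category, a pair is *counted*
synergistic when any grid point achieves CI < 1 — the reading under which
"nearly additive" values just below 1 still count toward a synergy tally
while those just above do not. Grading bins are left-closed/right-open, so
CI = 1.45 grades as "antagonism" and 0.90 as "nearly additive".

*Insensitive pairs.* The acceptance condition (both `ΔE/E_d ≤ 1` at a joint
normal-state point) does not prescribe how to allocate effect between the
two targets. The implemented policy: for each direction combination
(decrease/decrease tried first), a common relative-dose scalar `s ∈ (0, 1]`
applied to both targets is bisected to the criterion, then each axis is
refined downward with the other held. A 2-D grid scan in the tests guards
this policy against non-monotone surfaces.

*Mixed pairs.* The sensitive target j is fixed at `α·Dx_j` in its
single-target direction (α = 0.8 by default: a 20% dose cut); the
insensitive partner's required dose is then bisected, both directions
allowed, and the pair is synergistic iff its ratio is ≤ 1.

## Fixtures: what they emulate and what they do not

The fixture generators produce monotone enzyme-dose → readout responses with
analytically known structure:

* `make_cascade(n)` — a linear MM chain with a large substrate pool, so
  output is rate-limited and roughly proportional to the bottleneck
  `K_cat·E`; the dose–effect curve is smooth and monotone, which is what the
  grid-scan oracles compare against.
* `make_additive_pair_model()` — the Loewe oracle. Two target pools of one
  diverting activity compete with a fixed production route for a shared
  precursor; all routes share `K_m`, so the readout fraction
  `c/(c + k_d·(E_a+E_b))` depends only on the pool sum and additivity is
  exact: the equal-effect contour is `f1 + f2 = 1` for any θ. Doses are
  concentration *increases*: a decrease-direction construction cannot make
  both pools individually sensitive, because suppressing a shared flux
  tenfold always removes more activity than either pool holds. The
  recommended θ for this fixture is 0.75, derived from the construction
  (single-dose ratio = 2(1/θ−1)(1 + c/d₀), which is ≤ 1 for a = 1 only when
  θ ≳ 0.7 at the chosen c/d₀ = 0.2); the CI = 1 identity does not depend on
  θ.
* `make_insensitive_pair_fixture()` — two parallel half-flux routes: each
  target alone strands 50% of output (infeasible at θ = 0.10), a joint ~90%
  knockdown of both reaches it.
* `random_network(spec)` — seeded random MM chains with occasional
  inhibition/activation modifiers; used for schema and determinism sweeps.

These fixtures emulate monotone, noise-free, single-pathway dose responses.
They do not emulate feedback-induced ultrasensitivity, oscillations,
measurement noise or parameter uncertainty, so passing tests certify the
screening machinery (searches, CI construction, grading, report assembly) —
not the biological fidelity of any particular network model.

## The synthetic AA network

`models/aa_pmn_synthetic.yaml` is a synthetic stand-in for a fitted kinetic
model of AA metabolism in human PMNs: 24 species (15 metabolites, 9 enzyme
pools), 45 kinetic constants, 8 candidate targets, readout LTB4, 1 h
horizon. The topology follows the canonical pathway structure — PLA2
releases AA; 5-LOX, 15-LOX, 12-LOX and COX-2 branches; LTA4H forms LTB4;
CYP4F3 degrades it; PHGPx clears the hydroperoxides — with feedback through
peroxide activation of 5-LOX, transcriptional upregulation (LTB4 → 5-LOX,
PGE2 → COX-2, 12-HETE → 12-LOX) and inactivation (15-HETE, LXA4). Every
constant is annotated `synthetic` in the provenance table: values were
chosen for plausible hour-scale dynamics and so that the model exercises all
three screening branches (PLA2, 5-LOX and LTA4H sensitive; PHGPx, 15-LOX
and 12-LOX insensitive; CYP4F3 and TXAS infeasible; one drug-sparing mixed
synergy, 5-LOX + PHGPx). Quantitative screening results on this file are
demonstrations of the method, not reproductions of any published
parameterization. The untreated baseline (disease output 0.78369) is pinned
in the test suite at 0.1% so silent edits to the model file are caught.

## Numerical choices and degenerate inputs

* Bisection caps at 200 iterations; non-convergence raises a search error
  that advises a grid fallback rather than returning a bad dose.
* A target whose unperturbed model already meets the criterion gets
  `ΔE = 0` (ratio 0, trivially sensitive); a partner that alone covers the
  criterion yields a combination dose of exactly 0.
* Infeasible isobologram grid points are dropped with a warning; a pair with
  no feasible points raises a screen error, which `screen_all` isolates
  per-pair.
* Integration failure at an extreme exploratory dose (e.g. a 10¹⁸-fold
  overexpression) is treated as infeasibility of that dose, not a crash.
* Ties in the ranking are broken by target id, making the report invariant
  to target declaration order.

## Problem sizes

The shipped fixtures are 3–6 species; the synthetic AA model is 24 species.
A full `screen --mode all` on the AA model is ~15 s on one CPU; the test
suite, including the property-based acceptance checks and all grid-scan
oracles, runs in under a minute. Oracle grids use a two-stage coarse/fine
scan (256×256 effective resolution), which is finer than a flat 10⁴-point
scan at a fraction of the simulations.

## Known limitations

Combinations of more than two targets are not screened. Only one readout
criterion is monitored; fluxes of other metabolites are ignored. Loewe
additivity is the only null model (no Bliss independence), and no
statistical uncertainty is attached to CI values. The insensitive-pair
allocation policy is one of several defensible choices; it is deliberately
factored so the 2-D grid fallback can replace it wholesale.
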