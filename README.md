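# synscreen

Screening two-target drug combinations in kinetic disease networks.

Complex diseases are rarely controllable through a single protein: biological
networks are robust, and effective therapy often needs two drugs hitting two
targets at once. `synscreen` implements a model-driven screen for such pairs.
Given an ODE model of a disease network — species, enzyme pools, and
irreversible Michaelis–Menten-family reactions — it asks, for every candidate
target enzyme, how far its concentration must be pushed to restore a *normal
state*, and then screens all target pairs for synergy. The worked disease
network is the arachidonic-acid (AA) metabolic pathway of human
polymorphonuclear leukocytes, whose readout LTB4 is a major inflammatory
mediator.

## Method

**States.** The *disease state* is the untreated network. The *normal state*
requires the cumulative production of the readout species over the horizon
(default 1 h) to fall below a fraction θ (default 10%) of the disease output.
Cumulative production is the time-integral of synthesis flux into the
readout, carried as an auxiliary state of the integration.

**Single targets.** A drug dose is a step change of one enzyme pool's
concentration, `ΔE_i = |E_di − E_hi|`, where `E_di` is the untreated
concentration and `E_hi` the concentration that *just* reaches the normal
state (found by bracketing + bisection, in whichever direction — knockdown
or overexpression — is cheaper). Targets are ranked by the relative dose
`ΔE_i / E_di`; those with `ΔE_i/E_di ≤ a` (default a = 1) are *sensitive*,
the rest *insensitive* (or *infeasible* if no dose works).

**Pairs.** Three branches:

* *sensitive + sensitive* — Loewe combination index. With single effective
  doses `(Dx)_1, (Dx)_2`, each equal-effect dose pair `((D)_1, (D)_2)` gives

      CI = (D)_1/(Dx)_1 + (D)_2/(Dx)_2,

  computed across a 9-point fractional-dose grid by holding one drug fixed
  and bisecting the other to the same effect. CI < 1 synergy, > 1
  antagonism, = 1 additivity; pairs crossing 1 are *hybrid*. Values are
  graded on the standard CI scale from "very strong synergism" (< 0.1,
  `+ + + + +`) through "nearly additive" (0.90–1.10, `+ -`) to "very strong
  antagonism" (≥ 10, `- - - - -`).
* *insensitive + insensitive* — joint feasibility: neither target can reach
  the normal state alone with `ΔE/E_d ≤ 1`, but a joint perturbation might.
  A common relative-dose scalar is bisected, then refined per axis; the pair
  is synergistic iff a feasible joint point exists with both ratios ≤ 1.
* *sensitive + insensitive* — drug sparing: the sensitive target's dose is
  cut to `α·(Dx)` (default α = 0.8, i.e. a 20% dose reduction) and the
  insensitive partner must cover the remaining effect with `ΔE/E_d ≤ 1`.

## Worked example

The package ships a **synthetic** parameterization of the AA network
(`synscreen.load_aa_model()`: 24 species, 45 kinetic constants, 8 candidate
targets, readout LTB4, 1 h horizon). Its topology follows the canonical
5-LOX / 15-LOX / COX-2 pathway structure, but the constants are
illustrative, so the numbers below demonstrate the method rather than any
published fit.

```bash
synscreen rank --model src/synscreen/models/aa_pmn_synthetic.yaml --out ranks.csv
```

```
 rank target  E_di      E_hi   delta_E     ratio direction classification
    1  5-LOX   1.0  0.287766  0.712234  0.712234  decrease      sensitive
    2   PLA2   1.0  0.110657  0.889343  0.889343  decrease      sensitive
    3  LTA4H   1.0  0.023457  0.976543  0.976543  decrease      sensitive
    4  PHGPx   1.0  8.230469  7.230469  7.230469  increase    insensitive
    5 15-LOX   0.8 12.792969 11.992969 14.991211  increase    insensitive
    6 12-LOX   0.8 45.860938 45.060938 56.326172  increase    insensitive
    7 CYP4F3   0.5       NaN       NaN       inf  decrease     infeasible
    8   TXAS   0.5       NaN       NaN       inf  decrease     infeasible
```

Reading the table: knocking 5-LOX down to 29% of its untreated level
(ratio 0.71 ≤ 1) restores the normal state, so it is a sensitive target;
PHGPx works only at an 8.2-fold overexpression (ratio 7.2 > 1, insensitive);
CYP4F3 — which degrades LTB4 but does not control its production — cannot
reach the criterion at all. The mixed screen then finds the drug-sparing
pair: with 5-LOX's dose cut by 20% (α = 0.8), a PHGPx boost with ratio
0.979 ≤ 1 covers the remainder:

```python
>>> import synscreen as ss
>>> aa = ss.load_aa_model()
>>> crit = ss.disease_criterion(aa)
>>> rec = {r.target: r for r in ss.rank_and_classify(aa, crit)}["5-LOX"]
>>> v = ss.screen_mixed_pair(aa, rec, "PHGPx", crit)
>>> v.synergistic, round(v.evidence["insensitive_ratio"], 4)
(True, 0.9791)
```

`synscreen screen --mode all --model ... --out DIR` runs every branch and
writes `isobolograms.csv`, `verdicts.csv` and `report.json` (~15 s for this
model on one CPU).

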