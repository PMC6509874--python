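# Synthetic stand-in parameterization of the arachidonic-acid (AA) metabolic
# network in human polymorphonuclear leukocytes (PMNs).
#
# Topology follows the canonical pathway structure: PLA2 releases AA from
# membrane phospholipid; AA is metabolized through the 5-LOX branch
# (5-HPETE -> LTA4 -> LTB4, with CYP4F3 degrading LTB4), the 15-LOX branch
# (15-HPETE/15-HETE, lipoxin formation) and the COX-2 branch (PGH2 -> TXA2 /
# PGE2), with PHGPx reducing the hydroperoxides and feedback through
# peroxide activation of 5-LOX, transcriptional upregulation by LTB4 / PGE2 /
# 12-HETE and inactivation by 15-HETE / LXA4.
#
# All kinetic constants are SYNTHETIC (illustrative, chosen for plausible
# hour-scale dynamics in arbitrary concentration units); they are NOT fitted
# to measurements, and quantitative screening results on this file do not
# reproduce any published parameterization. See aa_pmn_synthetic_provenance.csv.
#
# Shape: 24 species (15 metabolites + 9 enzyme pools), 45 kinetic constants,
# 8 drug targets, readout LTB4, horizon 1 h.
species:
- {id: PL, initial: 50.0, role: metabolite}
- {id: AA, initial: 0.1, role: metabolite}
- {id: 5-HPETE, initial: 0.0, role: metabolite}
- {id: 5-HETE, initial: 0.0, role: metabolite}
- {id: LTA4, initial: 0.0, role: metabolite}
- {id: LTB4, initial: 0.05, role: metabolite}
- {id: 20-OH-LTB4, initial: 0.0, role: metabolite}
- {id: 15-HPETE, initial: 0.0, role: metabolite}
- {id: 15-HETE, initial: 0.0, role: metabolite}
- {id: 12-HPETE, initial: 0.0, role: metabolite}
- {id: 12-HETE, initial: 0.0, role: metabolite}
- {id: PGH2, initial: 0.0, role: metabolite}
- {id: TXA2, initial: 0.0, role: metabolite}
- {id: PGE2, initial: 0.0, role: metabolite}
- {id: LXA4, initial: 0.0, role: metabolite}
- {id: PLA2, initial: 1.0, role: enzyme_pool}
- {id: 5-LOX, initial: 1.0, role: enzyme_pool}
- {id: 15-LOX, initial: 0.8, role: enzyme_pool}
- {id: 12-LOX, initial: 0.8, role: enzyme_pool}
- {id: COX2, initial: 0.6, role: enzyme_pool}
- {id: LTA4H, initial: 1.0, role: enzyme_pool}
- {id: TXAS, initial: 0.5, role: enzyme_pool}
- {id: CYP4F3, initial: 0.5, role: enzyme_pool}
- {id: PHGPx, initial: 1.0, role: enzyme_pool}
reactions:
- id: pla2_hydrolysis
  law_kind: michaelis_menten
  enzyme: PLA2
  substrate: PL
  product: AA
  constants: {K_cat: 2.0e-3, K_m: 10.0}
- id: 5lox_oxygenation
  law_kind: activation
  enzyme: 5-LOX
  substrate: AA
  product: 5-HPETE
  modifiers: {activator: 5-HPETE}
  constants: {K_cat: 4.0e-3, K_m: 5.0, KI: 0.15}
- id: phgpx_reduce_5hpete
  law_kind: michaelis_menten
  enzyme: PHGPx
  substrate: 5-HPETE
  product: 5-HETE
  constants: {K_cat: 8.0e-3, K_m: 2.0}
- id: 5lox_dehydration
  law_kind: michaelis_menten
  enzyme: 5-LOX
  substrate: 5-HPETE
  product: LTA4
  constants: {K_cat: 3.0e-3, K_m: 2.0}
- id: lta4h_hydrolysis
  law_kind: competitive_inhibition
  enzyme: LTA4H
  substrate: LTA4
  product: LTB4
  modifiers: {inhibitor: LXA4}
  constants: {K_cat: 5.0e-3, K_m: 1.0, K_i: 1.0}
- id: cyp4f3_omega_oxidation
  law_kind: michaelis_menten
  enzyme: CYP4F3
  substrate: LTB4
  product: 20-OH-LTB4
  constants: {K_cat: 3.0e-3, K_m: 1.0}
- id: 15lox_oxygenation
  law_kind: michaelis_menten
  enzyme: 15-LOX
  substrate: AA
  product: 15-HPETE
  constants: {K_cat: 1.5e-3, K_m: 5.0}
- id: phgpx_reduce_15hpete
  law_kind: michaelis_menten
  enzyme: PHGPx
  substrate: 15-HPETE
  product: 15-HETE
  constants: {K_cat: 8.0e-3, K_m: 2.0}
- id: 12lox_oxygenation
  law_kind: michaelis_menten
  enzyme: 12-LOX
  substrate: AA
  product: 12-HPETE
  constants: {K_cat: 1.5e-3, K_m: 5.0}
- id: phgpx_reduce_12hpete
  law_kind: michaelis_menten
  enzyme: PHGPx
  substrate: 12-HPETE
  product: 12-HETE
  constants: {K_cat: 8.0e-3, K_m: 2.0}
- id: cox2_oxygenation
  law_kind: competitive_inhibition
  enzyme: COX2
  substrate: AA
  product: PGH2
  modifiers: {inhibitor: 15-HETE}
  constants: {K_cat: 2.0e-3, K_m: 4.0, K_i: 2.0}
- id: txas_isomerization
  law_kind: michaelis_menten
  enzyme: TXAS
  substrate: PGH2
  product: TXA2
  constants: {K_cat: 4.0e-3, K_m: 1.0}
- id: pge2_synthesis
  law_kind: michaelis_menten
  enzyme: COX2
  substrate: PGH2
  product: PGE2
  constants: {K_cat: 2.0e-3, K_m: 2.0}
- id: lxa4_from_lta4
  law_kind: michaelis_menten
  enzyme: 15-LOX
  substrate: LTA4
  product: LXA4
  constants: {K_cat: 1.0e-3, K_m: 3.0}
- id: lxa4_from_15hpete
  law_kind: michaelis_menten
  enzyme: 15-LOX
  substrate: 15-HPETE
  product: LXA4
  constants: {K_cat: 1.0e-3, K_m: 3.0}
- id: 5lox_upregulation_by_ltb4
  law_kind: transcription_upregulation
  enzyme: 5-LOX
  modifiers: {transcription_signal: LTB4}
  constants: {k_max: 2.0e-4, k_half: 0.5}
- id: cox2_upregulation_by_pge2
  law_kind: transcription_upregulation
  enzyme: COX2
  modifiers: {transcription_signal: PGE2}
  constants: {k_max: 2.0e-4, k_half: 0.5}
- id: 12lox_upregulation_by_12hete
  law_kind: transcription_upregulation
  enzyme: 12-LOX
  modifiers: {transcription_signal: 12-HETE}
  constants: {k_max: 1.0e-4, k_half: 0.5}
- id: 5lox_inactivation_by_15hete
  law_kind: irreversible_inactivation
  enzyme: 5-LOX
  modifiers: {inhibitor: 15-HETE}
  constants: {K: 5.0e-4}
- id: cox2_inactivation_by_lxa4
  law_kind: irreversible_inactivation
  enzyme: COX2
  modifiers: {inhibitor: LXA4}
  constants: {K: 5.0e-4}
- id: 15lox_inactivation_by_lxa4
  law_kind: irreversible_inactivation
  enzyme: 15-LOX
  modifiers: {inhibitor: LXA4}
  constants: {K: 3.0e-4}
- id: pge2_degradation
  law_kind: michaelis_menten
  enzyme: CYP4F3
  substrate: PGE2
  constants: {K_cat: 1.0e-3, K_m: 2.0}
- id: 12lox_inactivation_by_15hete
  law_kind: irreversible_inactivation
  enzyme: 12-LOX
  modifiers: {inhibitor: 15-HETE}
  constants: {K: 2.0e-4}
targets: [PLA2, PHGPx, TXAS, CYP4F3, 5-LOX, 15-LOX, LTA4H, 12-LOX]
readout: LTB4
horizon_seconds: 3600.0
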