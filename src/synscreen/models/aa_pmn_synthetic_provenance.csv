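reaction,law_kind,constant,value,provenance
pla2_hydrolysis,michaelis_menten,K_cat,0.002,synthetic
pla2_hydrolysis,michaelis_menten,K_m,10.0,synthetic
5lox_oxygenation,activation,K_cat,0.004,synthetic
5lox_oxygenation,activation,K_m,5.0,synthetic
5lox_oxygenation,activation,KI,0.15,synthetic
phgpx_reduce_5hpete,michaelis_menten,K_cat,0.008,synthetic
phgpx_reduce_5hpete,michaelis_menten,K_m,2.0,synthetic
5lox_dehydration,michaelis_menten,K_cat,0.003,synthetic
5lox_dehydration,michaelis_menten,K_m,2.0,synthetic
lta4h_hydrolysis,competitive_inhibition,K_cat,0.005,synthetic
lta4h_hydrolysis,competitive_inhibition,K_m,1.0,synthetic
lta4h_hydrolysis,competitive_inhibition,K_i,1.0,synthetic
cyp4f3_omega_oxidation,michaelis_menten,K_cat,0.003,synthetic
cyp4f3_omega_oxidation,michaelis_menten,K_m,1.0,synthetic
15lox_oxygenation,michaelis_menten,K_cat,0.0015,synthetic
15lox_oxygenation,michaelis_menten,K_m,5.0,synthetic
phgpx_reduce_15hpete,michaelis_menten,K_cat,0.008,synthetic
phgpx_reduce_15hpete,michaelis_menten,K_m,2.0,synthetic
12lox_oxygenation,michaelis_menten,K_cat,0.0015,synthetic
12lox_oxygenation,michaelis_menten,K_m,5.0,synthetic
phgpx_reduce_12hpete,michaelis_menten,K_cat,0.008,synthetic
phgpx_reduce_12hpete,michaelis_menten,K_m,2.0,synthetic
cox2_oxygenation,competitive_inhibition,K_cat,0.002,synthetic
cox2_oxygenation,competitive_inhibition,K_m,4.0,synthetic
cox2_oxygenation,competitive_inhibition,K_i,2.0,synthetic
txas_isomerization,michaelis_menten,K_cat,0.004,synthetic
txas_isomerization,michaelis_menten,K_m,1.0,synthetic
pge2_synthesis,michaelis_menten,K_cat,0.002,synthetic
pge2_synthesis,michaelis_menten,K_m,2.0,synthetic
lxa4_from_lta4,michaelis_menten,K_cat,0.001,synthetic
lxa4_from_lta4,michaelis_menten,K_m,3.0,synthetic
lxa4_from_15hpete,michaelis_menten,K_cat,0.001,synthetic
lxa4_from_15hpete,michaelis_menten,K_m,3.0,synthetic
5lox_upregulation_by_ltb4,transcription_upregulation,k_max,0.0002,synthetic
5lox_upregulation_by_ltb4,transcription_upregulation,k_half,0.5,synthetic
cox2_upregulation_by_pge2,transcription_upregulation,k_max,0.0002,synthetic
cox2_upregulation_by_pge2,transcription_upregulation,k_half,0.5,synthetic
12lox_upregulation_by_12hete,transcription_upregulation,k_max,0.0001,synthetic
12lox_upregulation_by_12hete,transcription_upregulation,k_half,0.5,synthetic
5lox_inactivation_by_15hete,irreversible_inactivation,K,0.0005,synthetic
cox2_inactivation_by_lxa4,irreversible_inactivation,K,0.0005,synthetic
15lox_inactivation_by_lxa4,irreversible_inactivation,K,0.0003,synthetic
pge2_degradation,michaelis_menten,K_cat,0.001,synthetic
pge2_degradation,michaelis_menten,K_m,2.0,synthetic
12lox_inactivation_by_15hete,irreversible_inactivation,K,0.0002,synthetic
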