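# Default kinetic parameterisation of the circulating RAAS.
# One block per actor; units follow the conventions used throughout the
# package: concentrations in umol/L, times in min, volumes in L.
# "optimized: true" marks values obtained by parameter identification rather
# than direct measurement; these form the default free set of the
# steady-state identification workflow.

AGT:
  molecular_weight_kDa: 53.15
  plasma_concentration_umol_per_L: 0.60     # venous, pre-administration steady state
  t_half_min: {value: 11.29, optimized: true}
  k_secretion_L_per_min: {value: 7.81, optimized: true}
  plasma_only: true

renin:
  molecular_weight_kDa: 48
  plasma_concentration_umol_per_L: 3.62e-07
  kcat_per_min: {value: 3.60, optimized: true}
  km_umol_per_L: {value: 5.04e-02, optimized: true}
  t_half_min: {value: 1.44, optimized: true}
  plasma_only: true

ACE:
  molecular_weight_kDa: 180
  k_on_L_per_umol_min: 35.16        # Enaat association, from the IV enalaprilat model
  k_off_per_min: 2.15e-02           # Enaat dissociation, from the IV enalaprilat model
  kcat_per_min: {value: 4.48e-04, optimized: true}
  km_umol_per_L: {value: 4.12e-03, optimized: true}

Ang1:
  molecular_weight_kDa: 1.30
  plasma_concentration_umol_per_L: 7.91e-06
  t_half_min: {value: 0.72, optimized: true}
  plasma_only: true

Ang2:
  molecular_weight_kDa: 1.05
  plasma_concentration_umol_per_L: 4.84e-06
  log_p: -1.7
  k_inhibition_umol_per_L: {value: 1.87e-08, optimized: true}
  t_half_min: 1.54                  # literature-consistent, held fixed
  plasma_only: true

AT1:
  molecular_weight_kDa: 41
  c_ref_umol_per_L: {value: 7.69, optimized: true}
  k_on_L_per_umol_min: {value: 23.50, optimized: true}
  k_off_per_min: {value: 3.07e-02, optimized: true}

aldosterone:
  molecular_weight_kDa: 0.36
  plasma_concentration_umol_per_L: 2.07e-04
  log_p: 1.08
  protein_binding_pct: 50           # metadata only; rate laws use total plasma conc
  k_production_umol_per_min: {value: 1.51e-06, optimized: true}
  k_secretion_L_per_min: {value: 7.81, optimized: true}
  t_half_min: {value: 12.87, optimized: true}
  plasma_only: true

prorenin:
  molecular_weight_kDa: 57
  plasma_concentration_umol_per_L: 1.21e-06   # 69 pg/ml at 57 kDa
  renal_intracellular_umol_per_L: {value: 1.1e-04, optimized: true}
  vmax_kid_umol_per_min_L: {value: 1.62, optimized: true}
  km_kid_umol_per_L: {value: 4.68e-02, optimized: true}
  k_secretion_L_per_min: {value: 4.68e-02, optimized: true}
  v_kidney_L: 0.24                  # intracellular volume of the kidney
  t_half_min: {value: 5.07, optimized: true}
  plasma_only: true

carboxylesterase:
  km_liv_umol_per_L: 710
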