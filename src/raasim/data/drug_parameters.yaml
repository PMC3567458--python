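# Physicochemical and PK properties of enalapril (Ena, inactive ester
# prodrug) and enalaprilat (Enaat, active ACE inhibitor), plus the
# study-specific subject parameterisations used for the published
# concentration-time datasets.

enalapril:
  molecular_weight_g_per_mol: 376.5
  log_p: 0.07
  pka: [3.74, 4.75]
  plasma_protein_binding_pct: 50
  hepatic_clearance_ml_per_min: 354
  renal_clearance_L_per_h: 18       # metadata; simulations use study values below

enalaprilat:
  molecular_weight_g_per_mol: 348.4
  log_p: -0.74
  pka: [2.03, 4.03]
  plasma_protein_binding_pct: 50
  renal_clearance_L_per_h: [8, 9.5] # metadata; simulations use study values below

absorption:
  ka_per_min: 0.03                  # first-order gut->liver transfer
  f_abs: 0.6                        # absorbable fraction of an oral dose

# Study-specific parameters (population properties and identified values).
studies:
  Biollaz:
    n_individuals: 12
    dose_mg: 10
    fasted: true
    body_weight_kg: 70
    vmax_liv_umol_per_min_L: 184.87
    renal_clearance_ena_L_per_min_kg: 6.02e-03
    renal_clearance_enaat_L_per_min_kg: 2.99e-04
    ace_c_ref_umol_per_L: 2.59
    v_liver_L: 1.56
  Gu:
    n_individuals: 20
    dose_mg: 10
    fasted: false
    body_weight_kg: 70
    vmax_liv_umol_per_min_L: 178.18
    renal_clearance_ena_L_per_min_kg: 4.51e-03
    renal_clearance_enaat_L_per_min_kg: 8.01e-04
    ace_c_ref_umol_per_L: 1.86
    v_liver_L: 1.57
  Lee:
    n_individuals: 12
    dose_mg: 20
    fasted: false
    body_weight_kg: 70
    vmax_liv_umol_per_min_L: 131.88
    renal_clearance_ena_L_per_min_kg: 6.53e-03
    renal_clearance_enaat_L_per_min_kg: 4.99e-04
    ace_c_ref_umol_per_L: 4.32
    v_liver_L: 1.57
  Lu:
    n_individuals: 20
    dose_mg: 10                     # two 5-mg capsules administered together
    fasted: true
    body_weight_kg: 70
    vmax_liv_umol_per_min_L: 148.05
    renal_clearance_ena_L_per_min_kg: 5.02e-03
    renal_clearance_enaat_L_per_min_kg: 6.30e-04
    ace_c_ref_umol_per_L: 1.30
    v_liver_L: 1.35
  Najib:
    n_individuals: 24
    dose_mg: 20
    fasted: true
    body_weight_kg: 73.38
    vmax_liv_umol_per_min_L: 146.50
    renal_clearance_ena_L_per_min_kg: 4.61e-03
    renal_clearance_enaat_L_per_min_kg: 6.37e-04
    ace_c_ref_umol_per_L: 2.14
    v_liver_L: 1.49
  Noormohamed:
    n_individuals: 12
    dose_mg: 20
    fasted: true
    body_weight_kg: 70
    vmax_liv_umol_per_min_L: 194.36
    renal_clearance_ena_L_per_min_kg: 5.50e-03
    renal_clearance_enaat_L_per_min_kg: 6.21e-04
    ace_c_ref_umol_per_L: 4.15
    v_liver_L: 1.42
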