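# Packaged lisinopril configuration: literature physicochemistry plus the
# reference protocols.  Calibrated parameters (clearance, permeability,
# partition scalar, food-effect slope, deep exchange) carry placeholder
# defaults here and are overwritten by the calibration workflow.
drug:
  log_p: -1.22
  pka: 2.5
  mw_g_mol: 405.48
  solubility_mg_l: 97000
  fu_plasma: 1.0            # does not bind plasma proteins
  peff_cm_h: 0.06
  cl_renal_adult_l_h: 2.82  # printed literature value; replaced by calibration
  kp_scalar: 1.0
  deep_kin_per_h: 0.0
  deep_kout_per_h: 1.0
  fed_alpha: 5.0
  regional_perm_weights:
    duodenum: 0.2
    jejunum: 0.6
    ileum: 1.0
    colon: 0.1

formulation:
  release_model: first_order
  t80_min: 30.0             # compendial 80 % release time

physiology:
  n: 18                     # oral reference study population
  prop_female: 0.0
  age_min_years: 21.0
  age_max_years: 37.0
  height_sd_fraction: 0.10
  seed: 0

regimen:
  route: oral
  dose_mg: 20.0
  n_doses: 1
  tau_h: 24.0
  fed: false
  meal_kcal: 524.0

calibration:
  observations_csv: null    # null -> packaged reference set
  passes: 8                 # maximum outer passes; stops earlier on parameter convergence
  vss_target_l_per_kg: 0.89
  multiple_dose_fed: false  # prandial state of the 10-day protocol (assumed)

dosefind:
  n_per_group: 100
  seed: 0
  groups: [neonates_to_infants, infants_to_toddler, preschool, school, adolescent]
  window:
    cmax_range: [38.0, 124.0]
    tmax_range: [5.1, 7.3]
    auc_range: [611.0, 1851.0]

output:
  directory: pedpk_output
  grid_h: 0.05
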