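# Shipped defaults. The geometry calibration constants (basal_radius_mm,
# w1_gain) and the activation calibration (v_threshold, hh_drive_gain) are
# frozen outputs of scripts/calibrate.py; everything else is a design default.
geometry:
  basal_radius_mm: 3.419280
  radial_decay: 0.12
  pitch_mm_per_turn: 1.0
  turns: 2.75
  w1_gain: 0.043554
  w2_gain: 0.08
  w3_gain: 0.15
  duct_offset_base_mm: 0.6
  duct_offset_apex_mm: 0.2
  n_bundles: 334
  total_fibers: 30000
  greenwood_A: 165.4
  greenwood_a: 2.1
  greenwood_k: 0.88
  max_abs_weight: 3.0
implant:
  n_contacts: 12
  active_range_mm: 23.1
  tip_mm: 1.0
field_model:
  distance_floor_mm: 0.1
activation:
  backend: threshold
  v_threshold: 1.041342
  pulse_phase_us: 100.0
  pulse_amplitude_ua: 350.0
  hh_drive_gain: 225.679765
  hh_dt_us: 1.0
  hh_window_ms: 1.0
  hh_spike_mv: 40.0
  hh_temperature_c: 37.0
scoring:
  band_halfwidth_mm: 1.5
  band_edge_weight: 0.1
  out_of_band_penalty: 0.25
fitting:
  grid_min_ua: 10.0
  grid_max_ua: 1000.0
  grid_step_ua: 10.0
  refine_ua: 1.0
  cross_turn_lambda: 0.5
uq:
  insertion_mean_mm: 27.0
  insertion_sd_population_mm: 1.0
  insertion_sd_patient_mm: 0.5
  resistivity_mean_ohm_m: 65.0
  resistivity_sd_group_ohm_m: 4.5
  resistivity_sd_full_ohm_m: 21.6
  weight_truncation_sd: 3.0
  mc_default_n: 250
  pcm_default_order: 2
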