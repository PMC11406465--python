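# Demonstration run: a small cohort with a planted protective insight effect
# (OR 0.29 on the high-insight indicator) and a planted negative
# fatigue-by-insight interaction on a 16x16x8 synthetic skeleton.
seed: 20240911
cohort:
  n_subjects: 36
  beta_intercept: 0.8
  beta_insight_high: -1.2379769525652723   # log(0.29)
  p_high_insight: 0.5
effect_field:
  grid_shape: [16, 16, 8]
  skeleton_fraction: 0.15
  gamma_fatigue: 0.04
  gamma_insight: 0.0
  gamma_interaction: -0.12
  noise_sd: 0.05
  smoothing_fwhm_vox: 2.0
  modalities: [FA]
analysis:
  fatigue_cutoff: median
  alpha_screen: 0.25
voxelwise:
  n_perm: 200
  behavioural_variable: htt_insight_r
  tail: two
  alpha: 0.05
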