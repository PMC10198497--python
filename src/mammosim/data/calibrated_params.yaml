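effects:
  alcohol_on_growth: false
  beta_alcohol: 0.0015
  bmi_per5_growth: 1.2278812270298407
  brca_mult: 1.5698772825167246
  brca_seed_class: 1
  brca_seed_volume: 0.0001
  brca_variant: faster_accumulation
  grams_per_drink: 14.0
  m_ht: 1.079699874012784
  m_oc: 1.0747769875490905
  prs_scale: 0.09467905549577796
  sigma_smoke: 1.0213869043464532
rates:
  baseline_volume: 1.0
  bf_loss_factor: 5.08944262604528
  g0: 0.08
  g_malignant: 1.2
  growth_rate_attenuation: 1.0
  lambda0: 0.045
  late_loss_factor: 3.0
  late_loss_onset_age: 74
  loss_fraction:
  - 1.0
  - 0.87
  - 0.74
  - 0.61
  - 0.48
  - 0.25
  quantum: 0.0001
  tau: 0.004601706651268577
  tau_final: 0.3
  theta_clinical: 1.0
  theta_screen: 0.25
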