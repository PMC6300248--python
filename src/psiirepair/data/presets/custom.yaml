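# Template for user-defined presets: all kinetic and turnover rates are zero,
# protein contents are given explicitly (they cannot be derived from zero rates).
# Override any field through make_preset("custom", **overrides).
name: custom
strain_id: custom
growth_light: 30.0
kinetics:
  k_pi: 0.0
  k_rec: 0.0
  k_psii: 0.0
  k_psba: 0.0
removal_rates:
  psba: 0.0
  psbd: 0.0
synthesis_rates:
  psba: 0.0
  psbd: 0.0
psba_psbd_ratio: 2.0
ftsh_hexamer_per_psba: 0.10
contents:             # fmol ug protein-1, explicit because rates are zero
  psba0: 100.0
  psbd0: 50.0
  ftsh_monomer0: 60.0
  psii_active0: 50.0
fluorescence:
  f0_base: 0.24
  fm_base: 0.60
  sigma_psii: 0.08
  connectivity_p: 0.30
qp:
  growth: 0.80
  treatment: 0.50
o2_per_psii:
  pre: 2.0
  post: 2.0
growth_curve:
  lag_d: 2.0
  rate_per_d: 0.30
  capacity_au: 0.50
  baseline_au: 0.05
transcript_pools: null
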