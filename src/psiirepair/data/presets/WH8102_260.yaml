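# Synechococcus sp. WH 8102 grown at 260 umol photons m-2 s-1.
name: WH8102_260
strain_id: WH8102
growth_light: 260.0
kinetics:
  k_pi: 7.8e-5
  k_rec: 7.1e-4
  k_psii: 3.7e-5
  k_psba: 1.6e-4
removal_rates:
  psba: 5.0e-3
  psbd: 3.0e-3
synthesis_rates:
  psba: 3.8e-3
  psbd: 2.6e-3
psba_psbd_ratio: 2.3
ftsh_hexamer_per_psba: 0.273
fluorescence:
  f0_base: 0.24
  fm_base: 0.60
  sigma_psii: 0.08
  connectivity_p: 0.30
qp:
  growth: 0.70
  treatment: 0.65
o2_per_psii:
  pre: 2.5
  post: 2.5
growth_curve:
  lag_d: 2.0
  rate_per_d: 0.25
  capacity_au: 0.50
  baseline_au: 0.05
transcript_pools: null
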