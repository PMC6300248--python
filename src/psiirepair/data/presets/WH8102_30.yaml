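# Synechococcus sp. WH 8102 grown at 30 umol photons m-2 s-1.
name: WH8102_30
strain_id: WH8102
growth_light: 30.0
kinetics:
  k_pi: 2.1e-4
  k_rec: 8.9e-4
  k_psii: 2.6e-4
  k_psba: 1.2e-4
removal_rates:
  psba: 6.8e-3
  psbd: 1.2e-3
synthesis_rates:
  psba: 2.4e-3
  psbd: 4.9e-4
psba_psbd_ratio: 3.2
ftsh_hexamer_per_psba: 0.095
fluorescence:
  f0_base: 0.24
  fm_base: 0.60
  sigma_psii: 0.08
  connectivity_p: 0.30
qp:
  growth: 0.80
  treatment: 0.60
o2_per_psii:
  pre: 1.5
  post: 2.0
growth_curve:
  lag_d: 2.0
  rate_per_d: 0.25
  capacity_au: 0.50
  baseline_au: 0.05
transcript_pools: null   # no qRT-PCR-grade RNA could be isolated for this strain
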