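# Prochlorococcus marinus MED 4 grown at 260 umol photons m-2 s-1.
name: MED4_260
strain_id: MED4
growth_light: 260.0
kinetics:
  k_pi: 1.2e-4
  k_rec: 1.1e-3
  k_psii: 1.9e-4
  k_psba: 1.7e-4
removal_rates:
  psba: 1.7e-2
  psbd: 1.1e-2
synthesis_rates:
  psba: 1.3e-2
  psbd: 6.2e-3
psba_psbd_ratio: 1.1
ftsh_hexamer_per_psba: 0.293
fluorescence:
  f0_base: 0.24
  fm_base: 0.60
  sigma_psii: 0.08
  connectivity_p: 0.30
qp:
  growth: 0.70
  treatment: 0.60
o2_per_psii:
  pre: 2.5
  post: 2.5
growth_curve:
  lag_d: 2.0
  rate_per_d: 0.30
  capacity_au: 0.50
  baseline_au: 0.05
transcript_pools: null
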