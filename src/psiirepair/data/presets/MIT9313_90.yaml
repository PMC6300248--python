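# Prochlorococcus marinus MIT 9313 grown at 90 umol photons m-2 s-1.
name: MIT9313_90
strain_id: MIT9313
growth_light: 90.0
kinetics:
  k_pi: 2.2e-4
  k_rec: 2.7e-4
  k_psii: 1.9e-4
  k_psba: 7.2e-5
removal_rates:
  psba: 3.4e-3
  psbd: 3.6e-3
synthesis_rates:
  psba: 3.2e-3
  psbd: 1.9e-3
psba_psbd_ratio: 1.9
ftsh_hexamer_per_psba: 0.092
fluorescence:
  f0_base: 0.24
  fm_base: 0.60
  sigma_psii: 0.08
  connectivity_p: 0.30
qp:
  growth: 0.80
  treatment: 0.30
o2_per_psii:          # grown at the higher light: no post-shift increase
  pre: 2.0
  post: 2.0
growth_curve:
  lag_d: 2.0
  rate_per_d: 0.35
  capacity_au: 0.50
  baseline_au: 0.05
transcript_pools: null   # qPCR was performed on 30-umol-grown cultures only
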