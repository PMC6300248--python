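# Prochlorococcus marinus MED 4 grown at 30 umol photons m-2 s-1.
name: MED4_30
strain_id: MED4
growth_light: 30.0
kinetics:
  k_pi: 1.7e-4
  k_rec: 2.3e-4
  k_psii: 2.2e-4
  k_psba: 1.5e-4
removal_rates:
  psba: 1.8e-2
  psbd: 9.2e-3
synthesis_rates:
  psba: 2.8e-3
  psbd: 9.5e-3
psba_psbd_ratio: 2.0
ftsh_hexamer_per_psba: 0.097
fluorescence:
  f0_base: 0.24
  fm_base: 0.60
  sigma_psii: 0.08
  connectivity_p: 0.30
qp:
  growth: 0.85
  treatment: 0.35
o2_per_psii:
  pre: 1.5
  post: 2.2
growth_curve:
  lag_d: 2.0
  rate_per_d: 0.30
  capacity_au: 0.50
  baseline_au: 0.05
transcript_pools:     # GL pool small and balanced across FtsH 1-3;
  gl: {FtsH1: 1.0e-4, FtsH2: 0.9e-4, FtsH3: 1.1e-4, FtsH4: 0.2e-4}
  # HL total = 8 x GL total, dominated by FtsH 1 and 2
  hl: {FtsH1: 1.15e-3, FtsH2: 1.05e-3, FtsH3: 3.0e-4, FtsH4: 6.0e-5}
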