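# Prochlorococcus marinus MIT 9313 grown at 30 umol photons m-2 s-1.
# Kinetic constants and protein turnover rates are the published group means for
# this strain x growth-light combination; fluorescence, qp, oxygen-per-PSII,
# growth-curve and transcript-pool entries are calibration constants chosen to
# reproduce the published derived quantities (see docs/methods.md).
name: MIT9313_30
strain_id: MIT9313
growth_light: 30.0
kinetics:
  k_pi: 1.6e-4        # s-1, photoinactivation (fluorescence)
  k_rec: -3.6e-5      # s-1, repair; negative = no measurable repair
  k_psii: 3.0e-4      # s-1, loss of active PSII (oxygen flash yield)
  k_psba: -2.0e-4     # s-1, PsbA removal; negative = net accumulation under lincomycin
removal_rates:        # fmol ug protein-1 s-1
  psba: -1.7e-2
  psbd: -1.0e-2
synthesis_rates:      # fmol ug protein-1 s-1
  psba: -1.8e-2
  psbd: -1.9e-2
psba_psbd_ratio: 2.1
ftsh_hexamer_per_psba: 0.030
fluorescence:
  f0_base: 0.24
  fm_base: 0.60
  sigma_psii: 0.08    # per unit flashlet photon dose
  connectivity_p: 0.30
qp:
  growth: 0.85
  treatment: 0.25
o2_per_psii:          # O2 PSII-1 s-1; post/pre = 2 reproduces the doubling at high light
  pre: 1.0
  post: 2.0
growth_curve:
  lag_d: 2.0
  rate_per_d: 0.40
  capacity_au: 0.50
  baseline_au: 0.05
transcript_pools:     # relative abundance, 1/E^Cq units; GL pool large, FtsH 3 dominated
  gl: {FtsH1: 2.0e-4, FtsH2: 3.0e-4, FtsH3: 2.5e-3, FtsH4: 2.0e-4}
  hl: {FtsH1: 1.8e-4, FtsH2: 2.7e-4, FtsH3: 2.25e-3, FtsH4: 1.8e-4}
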