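# psiirepair

Kinetics of Photosystem II (PSII) photoinactivation and repair in marine
picocyanobacteria — *Prochlorococcus marinus* MIT 9313 and MED 4 and
*Synechococcus* sp. WH 8102 — as a tested, reusable analysis pipeline with a
matched synthetic-experiment generator.

## The scientific problem

Light both drives photosynthesis and damages it: photons photoinactivate
PSII centres, and cells counter this with a repair cycle in which the FtsH
protease removes the damaged PsbA (D1) core protein and newly synthesised
protein is inserted.  Strains adapted to different light niches differ
sharply in repair capacity.  Quantifying that difference takes several
assays measured on the same cultures:

* **Fluorescence kinetics.** Fast repetition rate (FRR) chlorophyll
  fluorescence inductions (40 flashlets of 1.2 µs separated by 2.0 µs dark,
  a 128 µs train) yield F₀′, F_M′, the effective absorption cross-section
  σ_PSII, and re-opening lifetimes τ₁, τ₂.  F_V′/F_M′ = (F_M′ − F₀′)/F_M′
  serves as a proxy for the active-PSII pool.  During a standard light
  treatment (ten 330-s periods: dark, 30, then 8 × 260 µmol photons
  m⁻² s⁻¹ — 2640 s of treatment light), F_V′/F_M′ is tracked in paired
  cuvettes with and without lincomycin, a ribosome inhibitor that blocks
  repair.  The +lincomycin decay follows

      A(t) = A₀ · exp(−k_PI · t),

  giving the photoinactivation constant k_PI (s⁻¹); the −lincomycin series
  is then fit with k_PI frozen using the two-state damage/repair closed form

      A(t) = A₀ · (k_REC + k_PI · e^{−(k_PI + k_REC) t}) / (k_PI + k_REC),

  giving the repair constant k_REC (s⁻¹).
* **Quantitative immunoblots.** PsbA, PsbD and FtsH band signals calibrated
  against fmol standards (7–250 fmol) give contents in fmol per µg total
  protein; from T0 and post-treatment ±lincomycin samples come the removal
  constant k_PsbA = (ln c_T0 − ln c_T,linco)/T, removal rate k·c_T0, and
  synthesis rate (c_T,−linco − c_T,+linco)/T.  FtsH hexamers (monomer/6) per
  PsbA tell how many PSII one protease complex must serve.
* **Oxygen.** The O₂ evolved per saturating single-turnover flash, times 4,
  gives the active-PSII concentration; steady-state optode slopes give O₂
  evolved per PSII per second.
* **Growth.** Daily absorbance peaks fit with the Zwietering modified
  Gompertz model (lag, rate, capacity).
* **Transcripts.** qPCR C_q values for the four *ftsH* isoforms convert to
  relative abundances 1/E^Cq and per-condition pool compositions.

Because no raw data accompany the study, the package ships strain ×
growth-light **presets** carrying the published rate constants,
turnover rates and stoichiometry ratios, and a **generator** that
forward-simulates every assay from them — so the full pipeline is testable
end-to-end and parameter recovery can be verified exactly.

## Worked example

```python
from psiirepair import make_preset, NoiseModel, generate_dataset, pair_and_fit
from psiirepair.proteins import calibrate_blots, protein_rates, protein_rates_summary

preset = make_preset("MED4_260")          # MED 4 grown at 260 umol photons m-2 s-1
dataset = generate_dataset(preset, NoiseModel(seed=1), n=5)

kin = pair_and_fit(dataset.decay)         # k_PI then k_REC per replicate
print(kin.summary.round(6).to_string(index=False))

rates = protein_rates(calibrate_blots(dataset.blots))
summary = protein_rates_summary(rates)
cols = ["target", "removal_rate_mean", "removal_rate_sem",
        "synthesis_rate_mean", "synthesis_rate_sem", "n"]
print(summary[cols].round(4).to_string(index=False))
```

prints

```
strain_id  growth_light  k_pi_mean  k_pi_sem  k_rec_mean  k_rec_sem  n
     MED4         260.0   0.000119  0.000002    0.001005   0.000063  5
target  removal_rate_mean  removal_rate_sem  synthesis_rate_mean  synthesis_rate_sem  n
  PsbA             0.0186            0.0051               0.0141              0.0046  5
  PsbD             0.0137            0.0070               0.0082              0.0043  5
```

The recovered k_PI ≈ 1.2 × 10⁻⁴ s⁻¹ and k_REC ≈ 1.0–1.1 × 10⁻³ s⁻¹ match
the preset's generating constants for this high-light strain; the PsbA
removal rate (≈ 1.9 × 10⁻² fmol µg⁻¹ s⁻¹ here, truth 1.7 × 10⁻²) scatters
between replicates exactly as widely as the SEM columns indicate — the
generator's between-replicate variability is calibrated to the SEM scale of
the published group tables, so single five-replicate group means are noisy
by design.  With `NoiseModel.zero()` every estimator returns the preset
truth to better than 10⁻⁶ relative.

A command-line interface covers the same ground:

```bash
psiirepair simulate --preset MED4_260 --n 5 --seed 1 --outdir out/sim
psiirepair validate --input-dir out/sim/MED4_260
psiirepair run-all --preset MED4_260 --preset MIT9313_30 --n 5 --seed 1 --outdir out/run
```

`run-all` writes long-format CSV summaries: the four-constant kinetics
table (k_PI, k_REC, k_PSII, k_PsbA ± SEM), protein turnover rates,
stoichiometry (PsbA:PsbD, FtsH hexamer:PsbA), qp at growth versus treatment
light, growth fits, transcript pools and fold induction, plus rejects
tables (unpaired series, QC-flagged extracts, RT⁻ failures) and a
provenance record.

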