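# Methods

## The two-state damage/repair model

The active-PSII pool A(t) (tracked through F_V′/F_M′) exchanges with an
inactivated pool of fixed total A₀:

    dA/dt = −k_PI·A + k_REC·(A₀ − A).

The closed form used everywhere is

    A(t) = A₀ (k_REC + k_PI e^{−(k_PI+k_REC)t}) / (k_PI + k_REC),

the unique solution with A(0) = A₀; it reduces *identically* (special-cased
in code) to A₀e^{−k_PI t} when k_REC = 0, and plateaus at
A₀·k_REC/(k_PI+k_REC).  `predict_active` is verified against numerical
integration of the ODE to 10⁻⁸ over the full 2640-s protocol window for
every preset.

Model assumptions: first-order kinetics in both directions; the repaired
pool returns to the same photoinactivatable pool (fixed total A₀);
photoinactivation proceeds identically with and without lincomycin, which
is what lets the +lincomycin fit's k_PI be frozen in the paired −lincomycin
fit.  A₀ defaults to the measured t0 value of the series (F_V′/F_M′ is a
proxy, not an absolute concentration); `co_fit_a0=True` estimates it
jointly instead.  Negative estimates of any rate constant are reported with
a flag and never truncated — net accumulation under lincomycin is a real,
published phenomenon for low-light MIT 9313.

## FRR induction and relaxation

A single-turnover flashlet train (40 × 1.2 µs flashlets, 2.0 µs dark gaps,
128 µs total) is far shorter than the re-opening lifetimes, so no Q_A
re-oxidation occurs within the train.  With per-flashlet excitation
probability 1 − e^{−σ·dose}, the closed fraction before flashlet k is
C_k = 1 − e^{−kσ·dose} and the yield follows the Joliot connectivity model
F_k = F₀ + (F_M−F₀)·C_k(1−p)/(1−C_k p).  σ_PSII is reported in reciprocal
flashlet-dose units unless the protocol supplies an absolute dose.
Connectivity p is a free parameter by default (`fix_connectivity` pins
it).  Relaxation is biexponential toward F₀ with τ₁ ≤ τ₂ enforced by
sorting; single-exponential data collapse one amplitude and raise a
`reduced_model_preferred` flag.  Fits are unweighted nonlinear least
squares (scipy `least_squares`, tolerances 10⁻¹⁵) initialised from the
first yield (F₀), the maximum yield (F_M) and a log-slope heuristic for σ;
noiseless simulate-then-refit recovers parameters to 10⁻⁶ relative.

qp = (F_M′−F′)/(F_M′−F₀′) is clamped to [0, 1] with a flag rather than
rejected, so noisy replicates survive the pipeline; the quantum yield
(F_M′−F₀′)/F_M′ returns negative values with a warning when F₀′ > F_M′.

## Blot calibration and turnover rates

Calibration is strictly per blot and per target (ECL detection does not
transfer across membranes): an OLS line of band signal on fmol standard
load, with an intercept because membranes carry background.  Standards must
number ≥ 3 and span an order of magnitude within the 7–250 fmol design;
quantitation beyond 1.5× the calibrated range is flagged but returned.
Turnover quantities are the log-difference removal constant
(ln c_T0 − ln c_T,linco)/T, removal rate k·c_T0, synthesis rate
(c_T,−linco − c_T,+linco)/T and accumulation rate (c_final − c_initial)/T,
all sign-preserving.  The PSII-per-hexamer count rounds 1/(hexamer:PsbA)
half away from zero, which reproduces the published 0.030→33, 0.092→11,
0.097→10, 0.293→3 and 0.15→7 conversions.  A QC rule flags extracts whose
flash-yield active-PSII content exceeds the PsbA copy number (boundary
inclusive, factor configurable): one PsbA per active centre is a physical
ceiling, and such extracts indicate failed protein determinations.

## Oxygen metrics

One saturating flash advances each active centre's S-state cycle once and
four advances evolve one O₂, so [PSII] = 4 × (O₂ per flash), with no
miss/double-hit correction (a hook exists for one).  Conversion to fmol per
µg protein uses the extract geometry (mL culture pelleted, µL extract, µg
protein µL⁻¹) with the 10⁹ fmol/µmol factor pinned by a unit test.
Steady-state slopes default to Theil–Sen (optode drift spikes), OLS by
option; evolution is positive, consumption negative.  O₂ per PSII is
evaluated at the treatment start (acclimation segment over the
pre-treatment pool) and end (last treatment segment over the remaining
−lincomycin pool measured by the post flash yield).

## Growth

Zwietering modified Gompertz, y = baseline + K·exp(−exp(µe/K·(lag−t)+1)),
with a baseline term because absorbance proxies have nonzero blanks.  Raw
absorbance is fit (log is not taken).  A series without an increasing trend
is flagged `no_growth` rather than raising.  Time-shift equivariance (lag
moves, rate and capacity do not) is a tested property.

## Transcripts

Relative abundance is 1/E^Cq with per-isoform efficiency E ∈ (1, 2],
default 2.0 (no efficiencies were published; a dilution-series value can be
supplied per record).  Technical triplicates are averaged in Cq space after
dropping replicates > 0.5 cycles from the triplicate median; biological
replicates are then averaged in abundance space ("mean of means").  The
RT⁻ screen passes a record when the RT⁻ Cq trails RT⁺ by ≥ 5 cycles
(≥ 32-fold separation at E = 2) or is undetected; failing records are
excluded from pools, missing partners retained with a warning flag.  Pools
are raw 1/E^Cq compositions — no reference-gene normalisation.

## Presets and the synthetic generator

Each strain × growth-light preset stores the published group means: k_PI,
k_REC, k_PSII, k_PsbA; PsbA/PsbD removal and synthesis rates; the
PsbA:PsbD and FtsH hexamer:PsbA ratios.  Initial contents are derived so
that every stored number is self-consistent: psbA₀ = removal/k_PsbA,
psbD₀ = psbA₀/(PsbA:PsbD), k_PsbD = removal_PsbD/psbD₀, FtsH monomer =
6 × ratio × psbA₀.  The published tables are group means of per-replicate
ratios, so they cannot all be satisfied by a single parameter vector; where
they conflict (the low-light MIT 9313 no-lincomycin accumulation figure
versus that strain's removal/synthesis entries) the preset follows the rate
tables and the accumulation value comes out near 4 × 10⁻³ rather than the
separately printed 9.6 × 10⁻³ fmol µg⁻¹ s⁻¹.  Fluorescence baselines
(F₀ = 0.24, F_M = 0.60, so F_V′/F_M′ = 0.6), σ_PSII = 0.08 dose⁻¹,
connectivity 0.3, qp levels, O₂-per-PSII values (with post/pre = 2 for
low-light MIT 9313, reproducing its doubling under high light), growth
parameters and per-isoform transcript abundances (MED 4: 8-fold high-light
pool induction dominated by isoforms 1–2; MIT 9313: larger, FtsH 3-dominated
pool that does not increase) are calibration constants chosen to reproduce
published derived quantities; they are not ground truth and are stored in
the per-preset YAML files.  `psii_active0` is set to psbD₀ — active centres
bounded by the scarcer core subunit, always ≤ psbA₀.

Noise structure: additive Gaussian on fluorescence yields (sd 0.005,
calibrated so the implied per-replicate k_REC scatter matches the published
k_REC SEMs); mean-one multiplicative lognormal on band signals (cv 0.08,
typical densitometry) plus a mean-one lognormal *biological* factor (cv
0.60) shared by all contents of a replicate — the published rate SEMs imply
per-replicate coefficients of variation of 0.5–1.8, far beyond densitometry
error, so a replicate-level component is required to land group SEMs on the
published scale; Gaussian Cq noise (0.15 cycles technical, 0.30 per
biological replicate); additive optode noise (10⁻⁴ µmol mL⁻¹) and lognormal
flash-yield noise (cv 0.05).  Within-blot versus between-blot variance
components were not published; a single `blot_cv` plus the biological factor
is the deliberate simplification.  Each assay consumes an independent child
stream of the seed; identical seed + preset gives bit-identical CSVs.

The decay series carries nine strictly increasing treatment-clock times
(0, 330, …, 2640 s): the protocol's two pre-treatment periods (dark and
30 µmol) both map to t = 0 on the treatment-light clock, and one t = 0 row
is kept so times remain strictly increasing.

What the generator does *not* emulate: instrument voltages and gain,
optode temperature drift, blot image artefacts, biological covariance
between assays (the replicate factor is per-assay), day-to-day culture
history, and any deviation of the real decay kinetics from the two-state
model.  Passing recovery tests therefore demonstrate correctness of the
estimators under the stated models and noise — not robustness to model
misspecification in real data.

## Estimator bias and the Monte-Carlo tests

Linear-in-parameters or log-linear estimators (k_PI from a well-identified
exponential, blot removal/synthesis rates under mean-one noise) are
unbiased: 100-seed × 5-replicate recovery means sit within 2 Monte-Carlo
SEs of truth, and that is the tolerance their tests use.  Nonlinear,
weakly-identified estimators carry an O(σ²) Jensen bias: the one-parameter
k_REC fit (plateau barely expressed within 2640 s for fast-repair strains)
runs ≈ +3 % at paper-scale noise, the Gompertz rate ≈ +1.6 % at 5 % noise,
σ_PSII < 2 % at 1 % noise.  Their recovery tests therefore bound the mean
by max(2 MC SE, a small relative bound: 5 % of max(|k_REC|, k_PI), 3 % of
the growth rate, 2 % of σ) — asserting small bias and consistency rather
than exact unbiasedness, which these estimators do not possess.  Recovery
tests that sweep all six presets reuse the same per-seed noise stream
across presets (common random numbers), which makes the per-preset
deviations comparable.

## Numerical choices

scipy `least_squares` with xtol = ftol = gtol = 10⁻¹⁵ throughout;
Levenberg–Marquardt where unbounded, trust-region-reflective where bounds
apply (k_REC ∈ [−10, 10] s⁻¹ with saturation flagged above 1 s⁻¹;
amplitudes ≥ 0; p ∈ [0, 0.999]).  Standard errors come from the Jacobian at
the solution (pseudo-inverse, residual-variance scaled).  Flat inputs are
handled before optimisation: flat decay → k = 0 with `no_decay`; flat
induction → unconverged with σ = 0; flat growth → unconverged `no_growth`.
Ratio denominators of zero yield explicit `None` markers, not NaN
propagation.  Group SEMs use ddof = 1 over biological replicates and are
NaN for n = 1.

## Known limitations

* The two-state model has no second photoinactivation phase and no
  UV-wavelength resolution; multi-phase decays will bias k_PI.
* k_REC for fast-repair strains is weakly identified by design (plateau
  within the 2640-s window); its estimator bias and variance are documented
  above rather than engineered away.
* Flash-yield quantitation assumes no misses or double hits.
* The per-target standard-curve schema assumes each antibody was calibrated
  against a standard of its own target.
* Efficiencies default to perfect doubling; real primer pairs run below 2
  and shift absolute (not relative) pool sizes.
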