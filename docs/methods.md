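# Methods

This note records the models, parameter choices and known limitations of
`mcmrs`, in the spirit of a package methods appendix: what is simulated,
how each estimator works, which defaults were genuinely open choices, and
what the passing tests do and do not establish about real data.

## Signal model and conventions

All signals are complex FIDs of `n_points` samples at dwell time
`1/spectral_width`.  A resonance at chemical shift δ contributes
`exp(2πi f t)` with `f = (water_ppm − δ)·f0`, where `f0` is the
spectrometer frequency in MHz and water is the ppm reference at 4.68 ppm.
Lineshapes are Voigt: the time-domain product of a Lorentzian decay
`exp(−π L t)` and a Gaussian envelope `exp(−(π G t)²/(4 ln 2))`, with L
and G the FWHM in Hz.  The FFT is orthonormal, so white-noise standard
deviations coincide in both domains and Parseval holds exactly — this is
what lets a frequency-domain noise estimate calibrate CRLBs computed on
time-domain-derived models.

The spectrometer frequency defaults to 123.25 MHz (3 T).  Spectral width
(4000 Hz) and FID length (2048 complex points) are configurable defaults
of this package, not claims about any particular scanner protocol.

## What the generator emulates

`synthgen` produces, per subject: `n_runs × n_shots_per_run` single shots
(brain 2×128 at TR 2500/TE 35 ms, cord 2×256 at TR 2000/TE 41 ms) and an
8-echo unsuppressed water series (first echo at the sequence TE, then
50…1000 ms, TR 6000 ms).  Each shot contains

- a water line whose TE=0 amplitude is `2·(f_GM·0.78 + f_WM·0.65 +
  f_CSF·0.97)·55500` in concentration-scaled units (factor 2 = protons per
  water molecule), T1-saturated at the shot TR and T2-decayed at the shot
  TE.  In the cord, CSF nulling by the water-selective inversion is
  modelled simply as `f_CSF = 0`; no inversion-recovery dynamics.
- the 18 basis metabolites at their ground-truth concentrations, each
  attenuated by `(1−exp(−TR/T1))·exp(−TE/(1.5·T2))` using the shipped
  relaxation table, plus a macromolecular background of broad (45 Hz
  Lorentz) components at standard MM positions, both sign-alternating
  with the cycling state (ideal inversion);
- zero-order phase, frequency offset, linear or random-walk drift per
  shot, and additive complex white noise (`noise_sd` per component per
  point);
- motion corruption on a designated shot subset: a multiplicative
  amplitude factor U(0.4, 0.8), a frequency jump of U(8, 25) Hz with
  random sign, and U(5, 15) Hz extra Lorentz broadening.

Randomness is split from one master seed with `numpy` `SeedSequence`
spawning (one stream per shot, per subject), so any subset is
reproducible in isolation.

The basis is parametric: per-metabolite lists of line positions and
proton-weighted intensities from standard chemical-shift compilations,
stored in `mcmrs/data/metabolite_basis.json` (versioned).  This is
deliberate: parametric multiplets are sufficient to exercise fitting,
CRLB and quantification machinery at desk scale.  They are *not*
density-matrix simulations, so J-evolution, strong coupling and
TE-dependent multiplet phases of real spectra are absent.

The default two-group study (`study_design`) sets group mean
concentrations so that tCr, tNAA/tCr, tCho/tCr and mI/tCr match the
published group summary statistics of a spinal-cord-injury cohort (brain:
HC 18 / SCI 15, tCr 7.74/7.88 mM, tNAA/tCr 1.94/1.77; cord: HC 19 /
SCI 15, tCr 4.02/4.75 mM, tNAA/tCr 2.48/1.81), with between-subject SDs
mapped from the printed ratio SDs assuming independent numerator and
denominator variation, and per-group corrupt-shot fractions set to the
reported shot-exclusion rates (17.6/21.5% brain, 10.8/8.0% cord).  The
default per-shot noise (`noise_sd = 25` against a parenchymal water
amplitude of ≈7.8·10⁴) yields averaged metabolite spectra with NAA SNR
well above the SNR ≥ 15 regime the validation experiments assume.

## Preprocessing choices

- **Water shot fit**: a single Lorentzian line fitted to the first 256
  FID samples (water dominates there by ~2–3 orders of magnitude).
  Uncertainties are Gauss–Newton: `cov = σ̂²(JᵀJ)⁻¹`.  Non-convergence
  flags the fit with infinite uncertainties instead of raising.
- **MoCom**: the uncertainty rule is a strict `> 5%` ("exceeds"), so a
  shot at exactly 5.0% is kept.  The outlier statistic is the robust
  z-score `|x − median| / (1.4826·MAD)` per feature (frequency,
  amplitude, linewidth), OR-combined at k = 3; k is configurable.  When
  the MAD is zero, any deviation from the median is treated as infinite.
- **Corrections**: frequency/phase corrections are estimated per shot but
  applied as the pair mean — drift is slow on the pair timescale, and an
  identical correction within a cycling pair is what preserves exact
  water cancellation in the difference.  Eddy-current correction is
  Klose-style subtraction of the time-dependent water phase, estimated
  from the *pair sum* (where metabolites cancel), low-pass filtered
  (±30 Hz), smoothed over ~3 ms and tapered where the water magnitude
  approaches the in-band noise floor so late-FID phase noise is not
  imprinted on the metabolites.  Orphaned shots whose cycling partner was
  rejected are dropped (logged), not re-paired across neighbours.
- **HSVD**: poles from the shift-invariance of the signal subspace of a
  Hankel matrix of the first ≤1024 samples (truncated Lanczos SVD, model
  order 16 default); singular directions below 10⁻⁸ of the largest are
  discarded (a rank guard — otherwise junk poles carry large cancelling
  amplitudes on nearly noiseless data); growing poles are clipped to
  |z| = 1 before extrapolating over the full FID.  Only components with
  frequencies inside 4.68 ± 0.4 ppm are subtracted.  If nothing lands in
  the band the input spectrum is returned unchanged, bit for bit.

Whether to frequency-correct before or after pairing was an open choice;
corrections here are estimated per shot *before* pairing (and averaged
per pair, above).

## LCM fitting and CRLBs

The fit is variable projection: four nonlinear parameters (shared Gauss
width, shared extra Lorentz width, global shift, zero-order phase) are
optimised by trust-region least squares on the real+imaginary parts of
the windowed spectrum (0.5–4.2 ppm default), and at each step the
amplitudes (19 metabolite columns + 1 MMBG scale) are solved exactly by
NNLS.  Starting values are fixed (3 Hz Gauss, 0.5 Hz Lorentz, zero
shift/phase), making fits deterministic.  Lorentz widths are shared by
default (a per-metabolite option was considered out of scope).  No soft
constraint couples Cr/PCr or GPC/PCho; their collinearity at 3 T is
handled by reporting the sums tNAA = NAA+NAAG, tCr = Cr+PCr,
tCho = GPC+PCho, whose joint error bounds come from the parameter
covariance.

The MMBG model is a comb of Voigt lines every 5 Hz across the fit window
(14 Hz Lorentz width; 7.8 Hz Gauss in brain, 0.7 Hz in cord).  Its
amplitude profile is estimated once by a joint metabolite+comb NNLS fit
to the healthy-control cohort average (≥ 2 spectra required) and then
frozen; subject fits see a single free MMBG scale.

CRLBs: `F = JᵀJ/σ²` with J the stacked real/imaginary Jacobian over
amplitudes, MMBG scale and the four nonlinear parameters, and σ the noise
SD estimated from the detrended real part of the 10.5–12 ppm region.
Bounds are `sqrt(diag(F⁻¹))`; a singular information matrix falls back to
a pseudo-inverse with infinite bounds on null directions.  The
Monte-Carlo calibration experiment places the ground truth strictly
inside the parameter space — estimators pinned at the `≥ 0` bounds
(e.g. zero extra Lorentz width) scatter less than the unconstrained
bound, which is a property of constrained estimation, not an error in
the bound.

## Quantification

Absolute concentrations follow the standard internal-water-reference
equation (README) with the semi-LASER T2 stretch factor 1.5 applied both
in simulation and correction, the tissue-water factor
`f_GM·0.78 + f_WM·0.65` over the CSF-free voxel fractions, and
[H2O] = 55 500 mM (pure-water molarity; configurable).  `S_M` is the
fitted amplitude of the proton-weighted basis; `S_H2O` is the fitted
parenchymal TE=0 amplitude divided by 2 (water protons).  Metabolite
T1/T2 values are a shipped literature-style table — configuration, not
measurement.  Water-series echo times are always read from the series
header (the first echo differs between regions).

Ratios to tCr are formed from relaxation-corrected amplitudes (each
amplitude divided by its own `(1−exp(−TR/T1))·exp(−TE/(1.5·T2))`), so
they estimate concentration ratios; without this, metabolite-specific T2
differences would bias e.g. mI/tCr by ~10% at brain TE.  The reported
tCr error budget combines the joint Cr+PCr CRLB (through the calibration
factor) with the water-reference amplitude SE in quadrature.

The two-compartment water fit uses magnitudes (phase handling of the
echo series is not modelled), bounds all parameters positive, and
relabels compartments if the optimiser converges with T2 order inverted.

## QC gating and statistics

Cutoffs are `multiplier × pooled cohort median` of the absolute (mM)
CRLB per metabolite, computed in a single pass over all subjects of both
groups before any exclusion (per-group or iterative re-medianing were
plausible alternatives; pooled single-pass is the simplest deterministic
reading).  "More than half" is strict: a subject failing exactly half of
the analysed metabolites (default set: NAA, NAAG, Cr, PCr, GPC, PCho,
mI) is kept.  Whole spectra are excluded, never individual metabolites.

Group tests are Welch's t (Satterthwaite df) via `scipy.stats`; the
default is two-sided, with a `directional` mode that runs each contrast
one-sided in its hypothesised direction (tNAA and tCho decrease, mI
increase, areas decrease) and labels the report accordingly.  No
multiplicity correction is applied by default; Benjamini–Hochberg is
available as an option.  Percent differences are reported rounded to one
decimal, means/SDs to two, matching the convention of the cohort tables
the package reproduces.

## Validation experiment sizes

The acceptance script and acceptance tests run: a 50+50-subject brain
study (full pipeline per subject, ~2 s each), 500 noise replicates for
the CRLB calibration (bounds computed on 25 of them), 5000 Welch null
replicates, 100 water-decay replicates, and single-fixture MoCom (26
corrupt shots of 256) and HSVD experiments.  These sizes give standard
errors comfortably below the decision thresholds while keeping a full
run in the minutes range on one CPU.

## Known limitations

- No J-evolution, strong coupling, or TE-dependent multiplet structure;
  basis and data share the same parametric lineshapes, so LCM model
  error on real spectra (basis mismatch, baseline, lipids) is not
  represented — recovery results here bound only the noise- and
  artifact-driven part of the error.
- First-order phase, B0-map distortions, respiratory/cardiac waveforms
  and k-space effects are not simulated.
- Imperfect metabolite-cycling inversion is off by default (ideal sign
  alternation), so cycling-related subtraction artifacts are absent.
- Tissue fractions are inputs; no segmentation is performed.
- The water echo series is simulated with full T1 recovery at TR 6 s
  (the ~0.4% residual saturation of real water is ignored).
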