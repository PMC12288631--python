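# mcmrs — metabolite-cycled ¹H-MRS quantification

`mcmrs` is a tested, end-to-end pipeline for quantifying single-voxel
proton MR spectroscopy data acquired with **metabolite cycling** (a
non-water-suppressed scheme in which the metabolite spectral region is
inverted on alternating shots, so water and metabolite spectra come from
sums and differences of shot pairs).  It targets the kind of study that
compares brain and spinal-cord metabolite levels between a patient group
and healthy controls — e.g. neurodegeneration across the motor system
after spinal cord injury — where the deliverables are metabolite ratios
(tNAA/tCr, tCho/tCr, mI/tCr), absolute tCr in mM, spectral quality
gating, and Welch group statistics.

Because raw clinical data of such studies are rarely deposited, the
package ships a first-class synthetic-data generator that emulates the
acquisition (3 T semi-LASER, per-shot complex FIDs with cycling, drift,
motion-corrupted shots and noise, plus an 8-echo unsuppressed water
series), so every stage of the pipeline is testable against known ground
truth.

## The processing model

For each subject the chain is:

1. **Per-shot water fitting** — each single shot is dominated by water; a
   Voigt/Lorentz line fit yields amplitude *A*, frequency *f*, phase *φ*
   and linewidth *λ* with relative uncertainties from the Gauss–Newton
   covariance.
2. **Motion compensation (MoCom)** — a shot is excluded if the relative
   uncertainty of *A* or *λ* exceeds 5%, or if *f*, *A* or *λ* is a
   median/MAD outlier (|z| > k, default k = 3) within the shot cohort.
3. **Correction & cycling combination** — kept shots are frequency- and
   zero-order-phase-corrected (per cycling pair), eddy-current corrected
   by subtracting the time-dependent water phase, then pair differences
   (metabolite) and sums (water) are averaged over both runs.
4. **HSVD residual-water removal** — the FID is modelled as damped
   complex exponentials via a truncated (Lanczos) SVD of its Hankel
   matrix; only components inside the water band (4.68 ± 0.4 ppm) are
   subtracted.
5. **Linear-combination model (LCM) fit** — non-negative amplitudes of a
   19-component basis (18 metabolites + macromolecular background) under
   a shared Gauss linewidth, Lorentz width, global shift and phase.  The
   MMBG is a comb of equally spaced Voigt lines (5 Hz spacing, 14 Hz
   Lorentz; 7.8 Hz Gauss in brain, 0.7 Hz in cord) whose profile is
   estimated once from the healthy-control cohort average.  CRLBs come
   from the Fisher information `F = JᵀJ/σ²` at the solution.
6. **Water referencing** — the unsuppressed echo series is fitted with a
   two-compartment decay
   `S(TE) = S_par·exp(−TE/T2_par) + S_CSF·exp(−TE/T2_CSF)`, and
   amplitudes convert to millimolar via

   ```
   M = S_M/S_H2O · 1/(1−exp(−TR/T1)) · 1/exp(−TE/(1.5·T2))
         · (f_GM·d_GM + f_WM·d_WM) · [H2O]_molar
   ```

   with d_GM = 0.78, d_WM = 0.65 and [H2O] = 55.5 M.
7. **Quality gating** — whole spectra are excluded when more than half of
   the analysed metabolites have absolute (mM) CRLBs above
   1.5× (brain) / 2.0× (cord) their cohort median, or when the common
   Gauss linewidth exceeds 7.5 Hz (brain) / 10 Hz (cord).
8. **Cohort statistics** — Welch's unequal-variance t-tests, percent
   differences `100·(m_SCI − m_HC)/m_HC`, and Pearson/Spearman
   correlations against clinical covariates.

## Worked example

Simulate two healthy-control brain subjects at the design concentrations
(tCr = 7.74 mM, tNAA/tCr = 1.94), estimate the MMBG from their average,
and quantify the first subject:

```python
from mcmrs.basis import load_default_basis
from mcmrs.synthgen import study_design, simulate_cohort
from mcmrs.preproc import preprocess
from mcmrs.lcmfit import cohort_average, estimate_mmbg
from mcmrs.pipeline import process_subject

basis = load_default_basis()
design = study_design("brain", n_hc=2, n_sci=0, noise_sd=10.0,
                      corrupt=False, between_subject_variation=False)
records = simulate_cohort(design, seed=42, basis=basis)
specs = [preprocess(r.transients)[0] for r in records]
mmbg = estimate_mmbg(cohort_average(specs), basis, "brain")
res = process_subject(records[0], basis, mmbg, f_GM=0.38, f_WM=0.62)
print(f"tNAA/tCr = {res.ratios.at['tNAA', 'ratio_to_tcr']:.3f}")
print(f"tCr      = {res.tcr_mM:.2f} mM  (+/- {res.tcr_joint_sd_mM:.2f})")
```

prints

```
tNAA/tCr = 1.930
tCr      = 7.97 mM  (+/- 0.19)
```

i.e. the design ratio 1.94 is recovered to 0.5% and the design tCr
7.74 mM within its 2σ error budget (the fit CRLB combined with the
water-reference uncertainty).  A full two-group study — simulation,
preprocessing, fitting, quantification, QC and statistics — is one call,
`mcmrs.pipeline.run_study(design, seed)`, or from the shell:

```bash
mcmrs run-all --region brain --seed 1 --out results/
```

## Layout

- `mcmrs.synthgen` — ground-truth data model and simulators
- `mcmrs.preproc` — shot fitting, MoCom, combination, HSVD
- `mcmrs.lcmfit` — basis handling, MMBG estimation, LCM fit, CRLBs
- `mcmrs.waterquant` — two-compartment water fit and absolute quantification
- `mcmrs.qc` — cohort-level spectral quality gating
- `mcmrs.cohortstats` — Welch tests, percent differences, correlations
- `mcmrs.pipeline` / `mcmrs.cli` — orchestration and the `mcmrs` command
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
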