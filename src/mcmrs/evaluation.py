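"""Self-validation metrics: the quantitative checks the package stands on.

Each function runs one well-defined experiment through the public pipeline
and returns summary numbers: end-to-end parameter recovery on a simulated
two-group study, CRLB calibration against Monte-Carlo scatter, motion
(MoCom) rejection operating characteristics, HSVD water-suppression
performance, Welch type-I error calibration, and two-compartment water-fit
recovery.  The acceptance script and the acceptance tests both call these,
so the reported numbers are always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np

from mcmrs.basis import load_default_basis, voigt_envelope
from mcmrs.config import brain_config
from mcmrs.lcmfit import fit_lcm
from mcmrs.pipeline import run_study
from mcmrs.preproc import fit_water_shot, reject_shots, remove_residual_water
from mcmrs.spectrum import fid_to_spectrum
from mcmrs.synthgen import GroundTruth, WaterEchoSeries, simulate_subject, study_design
from mcmrs.waterquant import fit_water_decay


def recovery_study(seed: int, n_per_group: int = 50, region: str = "brain") -> dict:
    """End-to-end recovery on a simulated two-group study.

    Returns the mean relative bias of the recovered tNAA/tCr ratio against
    each subject's ground truth, the fraction of subjects whose absolute
    tCr falls within twice its joint (Cr+PCr) error bound, and the group
    percent difference of the recovered ratios.
    """
    design = study_design(region, n_hc=n_per_group, n_sci=n_per_group)
    study = run_study(design, seed, keep_records=True)
    rel_err, covered = [], []
    for res, rec in zip(study.results, study.records):
        tr = rec.truth.concentrations
        truth_ratio = (tr["NAA"] + tr["NAAG"]) / (tr["Cr"] + tr["PCr"])
        est_ratio = res.ratios.at["tNAA", "ratio_to_tcr"]
        rel_err.append(est_ratio / truth_ratio - 1.0)
        truth_tcr = tr["Cr"] + tr["PCr"]
        covered.append(abs(res.tcr_mM - truth_tcr) <= 2.0 * res.tcr_joint_sd_mM)
    out = {
        "n_subjects": 2 * n_per_group,
        "tnaa_tcr_bias_pct": 100.0 * float(np.mean(rel_err)),
        "tcr_within_joint_uncertainty_pct": 100.0 * float(np.mean(covered)),
    }
    if study.report is not None:
        row = study.report[study.report["measure"] == "tNAA/tCr"]
        if not row.empty:
            out["simulated_tnaa_tcr_delta_pct"] = float(row["delta_pct"].iloc[0])
    return out


def crlb_calibration(seed: int, n_rep: int = 500, noise_sd: float = 0.01) -> dict:
    """CRLB of an isolated line vs the Monte-Carlo SD over noise replicates."""
    acq = brain_config()
    basis = load_default_basis(acq.TE)
    # truth strictly inside the parameter space
    fid0 = basis.metabolite_fid("Gly", acq, gauss_lw=3.0, extra_lorentz_lw=1.5,
                                shift_hz=1.0) * np.exp(1j * np.radians(5.0))
    ss = np.random.SeedSequence(seed)
    amps, crlbs = [], []
    for i, child in enumerate(ss.spawn(n_rep)):
        rng = np.random.default_rng(child)
        noise = noise_sd * (rng.standard_normal(acq.n_points)
                            + 1j * rng.standard_normal(acq.n_points))
        spec = fid_to_spectrum(fid0 + noise, acq)
        r = fit_lcm(spec, basis, mmbg=None, names=("Gly",), window=(3.0, 4.0),
                    compute_bounds=(i < 25))
        amps.append(r.amplitudes["Gly"])
        if i < 25:
            crlbs.append(r.crlb["Gly"])
    mc_sd = float(np.std(amps, ddof=1))
    return {
        "n_replicates": n_rep,
        "mc_sd": mc_sd,
        "crlb": float(np.mean(crlbs)),
        "crlb_over_mc_sd": float(np.mean(crlbs)) / mc_sd,
    }


def mocom_operating_point(seed: int, n_corrupt: int = 26) -> dict:
    """Sensitivity / false-exclusion of MoCom with injected corrupt shots."""
    acq = brain_config()
    basis = load_default_basis(acq.TE)
    rng = np.random.default_rng(seed)
    corrupt = frozenset(rng.choice(acq.n_shots_total, n_corrupt, replace=False).tolist())
    truth = GroundTruth(
        concentrations={n: m.default_conc_mm for n, m in basis.metabolites.items()},
        noise_sd=25.0,
        corrupt_shot_indices=corrupt,
    )
    ts, _ = simulate_subject(truth, acq, int(rng.integers(2**31)), basis)
    fits = [fit_water_shot(t, acq) for t in ts]
    kept, excluded, _ = reject_shots(fits)
    excluded_set = set(excluded)
    tp = len(excluded_set & corrupt)
    fp = len(excluded_set - corrupt)
    return {
        "n_shots": acq.n_shots_total,
        "n_corrupt": n_corrupt,
        "exclusion_fraction_pct": 100.0 * len(excluded) / acq.n_shots_total,
        "sensitivity_pct": 100.0 * tp / n_corrupt,
        "false_exclusion_pct": 100.0 * fp / (acq.n_shots_total - n_corrupt),
    }


def hsvd_performance() -> dict:
    """Suppression of a dominant water line; NAA fidelity outside the band."""
    acq = brain_config()
    t = acq.time_axis()
    naa = np.exp(2j * np.pi * acq.ppm_to_hz(2.01) * t) * voigt_envelope(t, 3.0, 2.0)
    water = 50.0 * np.exp(2j * np.pi * acq.ppm_to_hz(4.68) * t) * voigt_envelope(t, 6.0, 2.0)
    spec = fid_to_spectrum(naa + water, acq)
    truth = fid_to_spectrum(naa, acq)
    out = remove_residual_water(spec)
    before = np.max(np.abs(spec.band(4.28, 5.08)))
    after = np.max(np.abs(out.band(4.28, 5.08)))
    naa_after = np.sum(np.abs(out.band(1.8, 2.2)))
    naa_truth = np.sum(np.abs(truth.band(1.8, 2.2)))
    return {
        "water_ratio": 50.0,
        "residual_water_pct": 100.0 * after / before,
        "naa_perturbation_pct": 100.0 * abs(naa_after - naa_truth) / naa_truth,
    }


def welch_type1(seed: int, n_rep: int = 5000, n: int = 15, alpha: float = 0.05) -> dict:
    """Empirical two-sided type-I error of the Welch test under the null."""
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_rep, n))
    b = rng.standard_normal((n_rep, n))
    p = sps.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    return {"n_replicates": n_rep, "type1_error_rate": float(np.mean(p < alpha))}


def water_fit_recovery(seed: int, n_rep: int = 100) -> dict:
    """Median relative errors of the two-compartment fit at 1% noise."""
    tes = np.array([41.0, 50.0, 75.0, 100.0, 140.0, 200.0, 400.0, 1000.0])
    truth = dict(S_par=0.8, S_CSF=0.2, T2_par=70.0, T2_CSF=500.0)
    ss = np.random.SeedSequence(seed)
    errs = {k: [] for k in truth}
    for child in ss.spawn(n_rep):
        rng = np.random.default_rng(child)
        amps = truth["S_par"] * np.exp(-tes / truth["T2_par"]) + truth["S_CSF"] * np.exp(
            -tes / truth["T2_CSF"]
        )
        amps = amps * (1.0 + 0.01 * rng.standard_normal(tes.size))
        fit = fit_water_decay(WaterEchoSeries(tes, np.abs(amps), 6000.0))
        est = dict(S_par=fit.S_parenchyma, S_CSF=fit.S_CSF,
                   T2_par=fit.T2_parenchyma, T2_CSF=fit.T2_CSF)
        for k in truth:
            errs[k].append(abs(est[k] - truth[k]) / truth[k])
    return {
        "n_replicates": n_rep,
        **{f"{k.lower()}_median_err_pct": 100.0 * float(np.median(v)) for k, v in errs.items()},
        "max_median_err_pct": 100.0 * float(max(np.median(v) for v in errs.values())),
    }
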