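"""LCM fitting: recovery, MMBG estimation, CRLB scaling and calibration."""

import numpy as np
import pytest

from mcmrs.basis import voigt_envelope
from mcmrs.config import brain_config
from mcmrs.lcmfit import (
    MMBG_GAUSS_LW,
    MMBGModel,
    cohort_average,
    compute_crlb,
    estimate_mmbg,
    fit_lcm,
)
from mcmrs.spectrum import Spectrum, fid_to_spectrum


def synth_spectrum(acq, basis, conc, gauss_lw=3.0, noise_sd=0.0, seed=0,
                   mmbg_fid=None, shift_hz=0.0, phase_deg=0.0, extra_lorentz=0.0):
    fid = np.zeros(acq.n_points, dtype=complex)
    for name, c in conc.items():
        fid += c * basis.metabolite_fid(name, acq, gauss_lw, extra_lorentz, shift_hz)
    if mmbg_fid is not None:
        fid = fid + mmbg_fid
    fid = fid * np.exp(1j * np.radians(phase_deg))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fid = fid + noise_sd * (rng.standard_normal(acq.n_points) + 1j * rng.standard_normal(acq.n_points))
    return fid_to_spectrum(fid, acq)


class TestFitLCM:
    def test_pure_naa_exact_recovery(self, brain_acq, basis):
        spec = synth_spectrum(brain_acq, basis, {"NAA": 1.0}, gauss_lw=3.0)
        res = fit_lcm(spec, basis, mmbg=None, start={"gauss_lw": 2.5})
        assert res.converged
        assert res.amplitudes["NAA"] == pytest.approx(1.0, abs=1e-6)
        for name, amp in res.amplitudes.items():
            if name != "NAA":
                assert amp < 1e-6

    def test_ratio_recovery_within_crlb_band(self, brain_acq, basis):
        """NAA:Cr:PCr = 1.5:0.5:0.5 at moderate SNR: ratio within 3 joint-CRLBs."""
        conc = {"NAA": 1.5, "Cr": 0.5, "PCr": 0.5}
        spec = synth_spectrum(brain_acq, basis, conc, noise_sd=0.004, seed=3)
        res = fit_lcm(spec, basis, mmbg=None, names=("NAA", "Cr", "PCr"))
        ratio = res.amplitudes["NAA"] / (res.amplitudes["Cr"] + res.amplitudes["PCr"])
        # delta-method SD of the ratio from the fitted covariance
        num, den = res.amplitudes["NAA"], res.amplitudes["Cr"] + res.amplitudes["PCr"]
        i_n = res.param_names.index("NAA")
        i_c = [res.param_names.index(x) for x in ("Cr", "PCr")]
        cov = res.covariance
        var_n = cov[i_n, i_n]
        var_d = sum(cov[a, b] for a in i_c for b in i_c)
        cov_nd = sum(cov[i_n, a] for a in i_c)
        sd_ratio = abs(ratio) * np.sqrt(
            var_n / num**2 + var_d / den**2 - 2 * cov_nd / (num * den)
        )
        assert ratio == pytest.approx(1.5, abs=3 * sd_ratio)

    def test_scale_equivariance(self, brain_acq, basis):
        """c x spectrum -> c x amplitudes and CRLBs; ratios unchanged."""
        conc = {"NAA": 1.2, "Cr": 0.6, "PCr": 0.4}
        spec = synth_spectrum(brain_acq, basis, conc, noise_sd=0.005, seed=1)
        c = 7.5
        scaled = Spectrum(c * spec.data, spec.ppm, spec.acq)
        r1 = fit_lcm(spec, basis, mmbg=None, names=tuple(conc))
        r2 = fit_lcm(scaled, basis, mmbg=None, names=tuple(conc))
        for n in conc:
            assert r2.amplitudes[n] == pytest.approx(c * r1.amplitudes[n], rel=1e-3)
            assert r2.crlb[n] == pytest.approx(c * r1.crlb[n], rel=0.02)
        assert r2.ratio_to_tcr("NAA") == pytest.approx(r1.ratio_to_tcr("NAA"), rel=1e-3)

    def test_glu_gln_amplitudes_anticorrelated(self, brain_acq, basis):
        """Strong spectral overlap makes replicate Glu/Gln estimates anticorrelated."""
        conc = {"Glu": 1.0, "Gln": 0.4, "Cr": 0.8}
        glu, gln = [], []
        for i in range(30):
            spec = synth_spectrum(brain_acq, basis, conc, noise_sd=0.01, seed=100 + i)
            r = fit_lcm(spec, basis, mmbg=None, names=("Glu", "Gln", "Cr"),
                        compute_bounds=False)
            glu.append(r.amplitudes["Glu"])
            gln.append(r.amplitudes["Gln"])
        assert np.corrcoef(glu, gln)[0, 1] < 0

    def test_residual_rms_matches_noise_estimate(self, brain_acq, basis):
        conc = {"NAA": 1.2, "Cr": 1.0}
        spec = synth_spectrum(brain_acq, basis, conc, noise_sd=0.01, seed=9)
        res = fit_lcm(spec, basis, mmbg=None, names=tuple(conc))
        rms = float(np.sqrt(np.mean(res.residual**2)))
        assert rms == pytest.approx(res.noise_sd, rel=0.15)


class TestCRLB:
    def test_crlb_linear_in_noise_sd(self, brain_acq, basis):
        """Doubling the noise SD exactly doubles every amplitude CRLB."""
        conc = {"NAA": 1.0, "Cr": 0.8}
        rng = np.random.default_rng(2)
        noise = rng.standard_normal(brain_acq.n_points) + 1j * rng.standard_normal(brain_acq.n_points)
        base = synth_spectrum(brain_acq, basis, conc)
        crlbs = {}
        for k in (1.0, 2.0):
            spec = Spectrum(base.data + k * 0.01 * fid_to_spectrum(noise, brain_acq).data,
                            base.ppm, base.acq)
            r = fit_lcm(spec, basis, mmbg=None, names=tuple(conc))
            crlbs[k] = (r.crlb["NAA"], r.noise_sd)
        assert crlbs[2.0][1] == pytest.approx(2 * crlbs[1.0][1], rel=0.02)
        assert crlbs[2.0][0] == pytest.approx(2 * crlbs[1.0][0], rel=0.05)

    def test_crlb_matches_monte_carlo_sd(self, brain_acq, basis):
        """Isolated line: CRLB within 20% of the Monte-Carlo amplitude SD."""
        conc = {"Gly": 1.0}  # single line at 3.55 ppm
        amps, crlbs = [], []
        for i in range(500):
            # truth strictly inside the parameter space (all four nonlinear
            # parameters interior) so the unconstrained bound applies
            spec = synth_spectrum(brain_acq, basis, conc, noise_sd=0.01, seed=2000 + i,
                                  extra_lorentz=1.5, shift_hz=1.0, phase_deg=5.0)
            r = fit_lcm(spec, basis, mmbg=None, names=("Gly",), window=(3.0, 4.0),
                        compute_bounds=(i < 25))
            amps.append(r.amplitudes["Gly"])
            if i < 25:
                crlbs.append(r.crlb["Gly"])
        mc_sd = np.std(amps, ddof=1)
        assert np.mean(crlbs) == pytest.approx(mc_sd, rel=0.20)

    def test_crlb_scales_with_averaging(self, brain_acq, basis):
        """Doubling averaged shots (noise / sqrt 2) shrinks CRLB by sqrt 2."""
        conc = {"NAA": 1.0}
        out = {}
        for label, sd in (("N", 0.01), ("2N", 0.01 / np.sqrt(2))):
            spec = synth_spectrum(brain_acq, basis, conc, noise_sd=sd, seed=5)
            r = fit_lcm(spec, basis, mmbg=None, names=("NAA",))
            out[label] = r.crlb["NAA"]
        assert out["N"] / out["2N"] == pytest.approx(np.sqrt(2), rel=0.10)


class TestMMBG:
    def _broad_hump(self, acq, scale=0.5):
        t = acq.time_axis()
        fid = np.zeros(acq.n_points, dtype=complex)
        for ppm, w in ((0.9, 4.0), (1.4, 3.0), (2.1, 3.5), (3.0, 2.0)):
            fid += w * np.exp(2j * np.pi * acq.ppm_to_hz(ppm) * t)
        return scale * fid * voigt_envelope(t, 50.0, 0.0)

    def test_requires_cohort_of_two(self, brain_acq, basis):
        spec = synth_spectrum(brain_acq, basis, {"NAA": 1.0})
        with pytest.raises(ValueError, match="2 control spectra"):
            estimate_mmbg(spec, basis, "brain")

    def test_absent_background_yields_negligible_lines(self, brain_acq, basis):
        conc = {"NAA": 1.0, "Cr": 0.8, "mI": 0.6}
        specs = [synth_spectrum(brain_acq, basis, conc, noise_sd=0.002, seed=s)
                 for s in (1, 2, 3)]
        mm = estimate_mmbg(cohort_average(specs), basis, "brain")
        total = mm.fid(brain_acq)
        assert np.abs(total[0]) < 20 * 0.002 * np.sqrt(brain_acq.n_points)

    def test_hump_absorbed_without_biasing_naa(self, brain_acq, basis):
        """Injected broad hump captured >= 80%; NAA amplitude bias <= 5%."""
        conc = {"NAA": 1.0, "Cr": 0.8}
        hump = self._broad_hump(brain_acq)
        specs = [synth_spectrum(brain_acq, basis, conc, noise_sd=0.002, seed=s,
                                mmbg_fid=hump) for s in (4, 5)]
        mm = estimate_mmbg(cohort_average(specs), basis, "brain")
        subject = synth_spectrum(brain_acq, basis, conc, noise_sd=0.002, seed=9,
                                 mmbg_fid=hump)
        res = fit_lcm(subject, basis, mm, names=tuple(conc))
        assert res.amplitudes["NAA"] == pytest.approx(1.0, rel=0.05)
        # captured hump energy in the fit window
        hump_spec = fid_to_spectrum(hump, brain_acq)
        model_spec = fid_to_spectrum(res.mmbg_scale * mm.fid(brain_acq), brain_acq)
        mask = hump_spec.band_mask(0.5, 4.2)
        captured = 1 - (
            np.sum(np.abs(hump_spec.data[mask] - model_spec.data[mask]))
            / np.sum(np.abs(hump_spec.data[mask]))
        )
        assert captured >= 0.80

    def test_region_specific_gauss_widths(self, brain_acq, basis):
        """Brain 7.8 Hz vs cord 0.7 Hz Gauss widths propagate into the model."""
        conc = {"NAA": 1.0, "Cr": 0.8}
        specs = [synth_spectrum(brain_acq, basis, conc, noise_sd=0.002, seed=s)
                 for s in (1, 2)]
        avg = cohort_average(specs)
        assert estimate_mmbg(avg, basis, "brain").gauss_lw == MMBG_GAUSS_LW["brain"] == 7.8
        assert estimate_mmbg(avg, basis, "cord").gauss_lw == MMBG_GAUSS_LW["cord"] == 0.7
        assert MMBGModel.empty(brain_acq, "cord").gauss_lw == 0.7
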