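"""Shot fitting, MoCom rejection, correction/combination and HSVD removal."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcmrs.basis import voigt_envelope
from mcmrs.config import brain_config
from mcmrs.preproc import (
    AllShotsRejectedError,
    RejectionPolicy,
    WaterShotFit,
    correct_and_combine,
    fit_water_shot,
    reject_shots,
    remove_residual_water,
)
from mcmrs.spectrum import fid_to_spectrum, spectrum_to_fid
from mcmrs.synthgen import DriftModel, GroundTruth, Transient, TransientSet, simulate_subject

from conftest import make_truth


def lorentzian_shot(acq, amp=1000.0, freq=5.0, phase=0.3, lw=6.0, noise_sd=0.0, seed=0):
    t = acq.time_axis()
    s = amp * np.exp(1j * (2 * np.pi * freq * t + phase)) * np.exp(-np.pi * lw * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        s = s + noise_sd * (rng.standard_normal(t.size) + 1j * rng.standard_normal(t.size))
    return Transient(s, +1, 0, 0)


class TestWaterShotFit:
    def test_noiseless_recovery(self, brain_acq):
        fit = fit_water_shot(lorentzian_shot(brain_acq), brain_acq)
        assert fit.frequency == pytest.approx(5.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(1000.0, rel=1e-6)
        assert fit.linewidth == pytest.approx(6.0, rel=1e-6)
        assert fit.zero_order_phase == pytest.approx(math.degrees(0.3), rel=1e-5)
        assert fit.amplitude_rel_uncertainty < 1e-8

    def test_uncertainty_scales_with_noise(self, brain_acq):
        """Halving SNR doubles the amplitude relative uncertainty (±15%)."""
        med = {}
        for sd in (5.0, 10.0):
            uncs = [
                fit_water_shot(
                    lorentzian_shot(brain_acq, noise_sd=sd, seed=i), brain_acq
                ).amplitude_rel_uncertainty
                for i in range(60)
            ]
            med[sd] = np.median(uncs)
        assert med[10.0] / med[5.0] == pytest.approx(2.0, rel=0.15)


def make_fit(i, freq=0.0, amp=1000.0, lw=6.0, amp_unc=0.001, lw_unc=0.001):
    return WaterShotFit(
        amplitude=amp,
        amplitude_rel_uncertainty=amp_unc,
        frequency=freq,
        frequency_uncertainty=0.01,
        zero_order_phase=0.0,
        linewidth=lw,
        linewidth_rel_uncertainty=lw_unc,
        shot_index=i,
    )


class TestRejectShots:
    def test_identical_fits_no_exclusions(self):
        fits = [make_fit(i) for i in range(16)]
        kept, excluded, _ = reject_shots(fits)
        assert excluded == [] and len(kept) == 16

    def test_frequency_jump_detected_by_mad_rule(self):
        """One +20 Hz shot among clean ones, vs a brute-force MAD oracle."""
        rng = np.random.default_rng(4)
        freqs = rng.normal(0.0, 0.2, 128)
        freqs[37] += 20.0
        fits = [make_fit(i, freq=f) for i, f in enumerate(freqs)]
        kept, excluded, reasons = reject_shots(fits)
        # oracle: explicit median/MAD computation
        med = np.median(freqs)
        mad = np.median(np.abs(freqs - med))
        oracle = [i for i in range(128) if abs(freqs[i] - med) / (1.4826 * mad) > 3.0]
        assert excluded == oracle
        assert 37 in excluded and "frequency_outlier" in reasons[37]

    def test_uncertainty_rule_strict_inequality(self):
        """6% uncertainty excluded; exactly 5.0% kept (strict 'exceeds')."""
        fits = [make_fit(i) for i in range(10)]
        fits.append(make_fit(10, lw_unc=0.06))
        fits.append(make_fit(11, lw_unc=0.05))
        kept, excluded, reasons = reject_shots(fits)
        assert 10 in excluded and reasons[10] == ["linewidth_uncertainty"]
        assert 11 in kept

    def test_all_rejected_raises_with_dominant_reason(self):
        fits = [make_fit(i, amp_unc=0.5) for i in range(6)]
        with pytest.raises(AllShotsRejectedError, match="amplitude_uncertainty"):
            reject_shots(fits)

    @given(st.integers(0, 2**31 - 1), st.floats(1.0, 4.0), st.floats(0.1, 2.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_rejection_monotone_in_threshold(self, seed, k_hi, dk):
        """Lowering the MAD threshold never shrinks the excluded set."""
        rng = np.random.default_rng(seed)
        fits = [
            make_fit(i, freq=rng.normal(0, 1), amp=1000 + rng.normal(0, 50),
                     lw=6 + abs(rng.normal(0, 1)))
            for i in range(24)
        ]
        try:
            _, excl_hi, _ = reject_shots(fits, RejectionPolicy(mad_k=k_hi))
            _, excl_lo, _ = reject_shots(fits, RejectionPolicy(mad_k=k_hi - dk))
        except AllShotsRejectedError:
            return
        assert set(excl_hi) <= set(excl_lo)


class TestCorrectAndCombine:
    def test_noiseless_pair_cancels_water_exactly(self, brain_acq, basis):
        """Difference of a clean cycling pair carries no water signal."""
        # pure-water shots isolate the cancellation itself; metabolite
        # Lorentzian tails would otherwise contribute real signal in-band
        conc = {n: 0.0 for n in basis.names}
        truth = GroundTruth(concentrations=conc, mmbg_scale=0.0)
        ts, _ = simulate_subject(truth, brain_acq, 0, basis)
        fits = [fit_water_shot(t, brain_acq) for t in ts.transients[:2]]
        metab, water = correct_and_combine(
            TransientSet(ts.transients[:2], brain_acq), fits, [0, 1]
        )
        water_peak = np.max(np.abs(water.band(4.58, 4.78)))
        assert np.max(np.abs(metab.band(4.28, 5.08))) < 1e-9 * water_peak

    def test_drift_correction_narrows_water_line(self, brain_acq, default_conc, basis):
        truth = make_truth(default_conc, drift=DriftModel("linear", freq_per_shot=0.1))
        ts, _ = simulate_subject(truth, brain_acq, 4, basis)
        fits = [fit_water_shot(t, brain_acq) for t in ts]
        kept, _, _ = reject_shots(fits)
        _, w_corr = correct_and_combine(ts, fits, kept)
        _, w_raw = correct_and_combine(ts, fits, kept, correct=False)
        lw = {}
        for tag, spec in (("corr", w_corr), ("raw", w_raw)):
            lw[tag] = fit_water_shot(
                Transient(spectrum_to_fid(spec), +1, 0, 0), brain_acq
            ).linewidth
        assert lw["corr"] < lw["raw"]

    def test_average_noise_scales_inverse_sqrt_n(self, brain_acq, default_conc, basis):
        truth = make_truth(default_conc, noise_sd=25.0)
        ts, _ = simulate_subject(truth, brain_acq, 6, basis)
        fits = [fit_water_shot(t, brain_acq) for t in ts]
        all_idx = [f.shot_index for f in fits]
        m_full, _ = correct_and_combine(ts, fits, all_idx)
        m_half, _ = correct_and_combine(ts, fits, all_idx[: len(all_idx) // 2])
        ratio = m_half.noise_sd() / m_full.noise_sd()
        assert ratio == pytest.approx(np.sqrt(2.0), rel=0.10)

    def test_shot_order_invariance(self, noisy_subject, noisy_subject_fits, brain_acq):
        _, transients, _ = noisy_subject
        fits, kept, _, _ = noisy_subject_fits
        m1, w1 = correct_and_combine(transients, fits, kept)
        perm = np.random.default_rng(0).permutation(len(transients))
        shuffled = TransientSet([transients[int(i)] for i in perm], brain_acq)
        m2, w2 = correct_and_combine(shuffled, list(np.array(fits, dtype=object)[perm]), kept)
        assert np.allclose(m1.data, m2.data, atol=1e-12)
        assert np.allclose(w1.data, w2.data, atol=1e-12)

    def test_orphan_shots_dropped(self, brain_acq, default_conc, basis):
        truth = make_truth(default_conc)
        ts, _ = simulate_subject(truth, brain_acq, 0, basis)
        fits = [fit_water_shot(t, brain_acq) for t in ts]
        kept = [f.shot_index for f in fits]
        kept.remove(1)  # break the first pair
        metab, _ = correct_and_combine(ts, fits, kept)
        assert metab.provenance["n_orphans_dropped"] == 1
        assert metab.provenance["n_pairs"] == brain_acq.n_shots_total // 2 - 1


class TestResidualWaterRemoval:
    def _spectrum_with_water(self, acq, water_amp=50.0, naa_amp=1.0):
        t = acq.time_axis()
        fid = naa_amp * np.exp(2j * np.pi * acq.ppm_to_hz(2.01) * t) * voigt_envelope(t, 3.0, 2.0)
        fid = fid + water_amp * np.exp(2j * np.pi * acq.ppm_to_hz(4.68) * t) * voigt_envelope(
            t, 6.0, 2.0
        )
        return fid_to_spectrum(fid, acq)

    def test_no_component_in_band_returns_input(self, brain_acq):
        spec = self._spectrum_with_water(brain_acq, water_amp=0.0)
        out = remove_residual_water(spec)
        assert np.array_equal(out.data, spec.data)

    def test_dominant_water_suppressed(self, brain_acq):
        """50x water suppressed to < 1% of its injected amplitude."""
        spec = self._spectrum_with_water(brain_acq, water_amp=50.0)
        before = np.max(np.abs(spec.band(4.28, 5.08)))
        out = remove_residual_water(spec)
        after = np.max(np.abs(out.band(4.28, 5.08)))
        assert after < 0.01 * before

    def test_naa_preserved_outside_band(self, brain_acq):
        """NAA integral after removal matches the water-free truth < 0.5%."""
        spec = self._spectrum_with_water(brain_acq, water_amp=50.0)
        truth = self._spectrum_with_water(brain_acq, water_amp=0.0)
        out = remove_residual_water(spec)
        naa_after = np.sum(np.abs(out.band(1.8, 2.2)))
        naa_truth = np.sum(np.abs(truth.band(1.8, 2.2)))
        assert abs(naa_after - naa_truth) / naa_truth < 0.005

    def test_excessive_model_order_reduced(self, brain_acq):
        spec = self._spectrum_with_water(brain_acq)
        out = remove_residual_water(spec, model_order=10_000, n_hsvd_points=64)
        assert out.data.shape == spec.data.shape
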