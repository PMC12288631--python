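"""From raw shot sets to one artifact-free averaged spectrum.

Processing chain for metabolite-cycled single shots:

1. :func:`fit_water_shot` — nonlinear least-squares fit of the dominant
   water line in each shot (amplitude, frequency, phase, Lorentz width)
   with relative uncertainties from the local curvature of the objective.
2. :func:`reject_shots` — motion-compensation (MoCom) outlier rejection:
   a shot is excluded if a fit uncertainty exceeds 5% or if its water
   frequency/amplitude/linewidth is a robust (median/MAD) outlier.
3. :func:`correct_and_combine` — per-shot phase/frequency correction,
   Klose-style eddy-current correction from the water phase, then cycling
   combination (pair difference -> metabolite, pair sum -> water) and
   averaging over pairs and runs.
4. :func:`remove_residual_water` — HSVD: model the time-domain signal as
   damped complex exponentials via a truncated (Lanczos) SVD of its Hankel
   matrix and subtract only the components inside the water band.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import hankel, lstsq
from scipy.optimize import least_squares
from scipy.sparse.linalg import svds

from mcmrs.config import AcquisitionConfig
from mcmrs.spectrum import Spectrum, fid_to_spectrum, spectrum_to_fid
from mcmrs.synthgen import Transient, TransientSet

logger = logging.getLogger(__name__)


@dataclass
class WaterShotFit:
    """Single-shot water-line fit and its relative uncertainties."""

    amplitude: float
    amplitude_rel_uncertainty: float
    frequency: float  # Hz offset from carrier
    frequency_uncertainty: float  # Hz
    zero_order_phase: float  # degrees
    linewidth: float  # Lorentz FWHM, Hz
    linewidth_rel_uncertainty: float
    shot_index: int
    converged: bool = True

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.linewidth <= 0:
            raise ValueError("amplitude must be >= 0 and linewidth > 0")
        for u in (
            self.amplitude_rel_uncertainty,
            self.frequency_uncertainty,
            self.linewidth_rel_uncertainty,
        ):
            if u < 0:
                raise ValueError("uncertainties must be non-negative")


def _water_model(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    amp, freq, phase, lw = theta
    return amp * np.exp(1j * (2 * np.pi * freq * t + phase)) * np.exp(-np.pi * lw * t)


def fit_water_shot(
    transient: Transient,
    acq: AcquisitionConfig,
    n_fit_points: int = 256,
) -> WaterShotFit:
    """Fit a single water line to the (water-dominated) start of one FID.

    The water signal dwarfs the metabolites in a non-water-suppressed shot,
    so a single Lorentzian line fitted to the first ``n_fit_points``
    samples characterises the shot's amplitude, frequency, phase and
    linewidth.  Relative uncertainties come from the Gauss-Newton
    covariance (J^T J)^-1 scaled by the residual variance; a fit that fails
    to converge is returned flagged with infinite uncertainties rather than
    raising.
    """
    n = min(n_fit_points, acq.n_points)
    s = transient.samples[:n]
    t = acq.time_axis()[:n]

    a0 = float(np.abs(s[0]))
    if a0 == 0.0:
        a0 = float(np.max(np.abs(s))) or 1.0
    ph0 = float(np.angle(s[0]))
    # frequency from the median phase increment over the early FID
    dphi = np.angle(s[1:32] * np.conj(s[:31]))
    f0 = float(np.median(dphi)) / (2 * np.pi * acq.dwell_time)
    mag = np.abs(s)
    good = mag > 1e-12 * a0
    lw0 = 5.0
    if np.count_nonzero(good) > 8:
        slope = np.polyfit(t[good], np.log(mag[good] + 1e-300), 1)[0]
        lw0 = max(0.5, -slope / np.pi)

    def resid(theta: np.ndarray) -> np.ndarray:
        d = _water_model(theta, t) - s
        return np.concatenate([d.real, d.imag])

    x0 = np.array([a0, f0, ph0, lw0])
    try:
        sol = least_squares(
            resid,
            x0,
            bounds=([0.0, -acq.spectral_width / 2, -2 * np.pi, 0.01], [np.inf, acq.spectral_width / 2, 2 * np.pi, np.inf]),
            xtol=1e-12,
            ftol=1e-12,
            max_nfev=200,
        )
        ok = sol.success and np.isfinite(sol.cost)
    except Exception:  # pragma: no cover - defensive
        sol, ok = None, False

    if not ok:
        return WaterShotFit(
            amplitude=a0,
            amplitude_rel_uncertainty=np.inf,
            frequency=f0,
            frequency_uncertainty=np.inf,
            zero_order_phase=math.degrees(ph0),
            linewidth=max(lw0, 0.01),
            linewidth_rel_uncertainty=np.inf,
            shot_index=transient.shot_index,
            converged=False,
        )

    amp, freq, phase, lw = sol.x
    dof = max(2 * n - 4, 1)
    sigma2 = 2 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = sigma2 * np.linalg.inv(jtj)
        sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        sd = np.full(4, np.inf)
    rel = lambda v, s_: (s_ / abs(v)) if abs(v) > 0 else np.inf

    return WaterShotFit(
        amplitude=float(max(amp, 0.0)),
        amplitude_rel_uncertainty=float(rel(amp, sd[0])),
        frequency=float(freq),
        frequency_uncertainty=float(sd[1]),
        zero_order_phase=float(math.degrees(((phase + np.pi) % (2 * np.pi)) - np.pi)),
        linewidth=float(max(lw, 1e-3)),
        linewidth_rel_uncertainty=float(rel(lw, sd[3])),
        shot_index=transient.shot_index,
        converged=True,
    )


@dataclass(frozen=True)
class RejectionPolicy:
    """Thresholds for MoCom shot rejection.

    ``rel_uncertainty_max`` is the quality rule: shots whose amplitude or
    linewidth relative fit uncertainty strictly exceeds it are dropped.
    ``mad_k`` is the outlier rule: robust z-scores (median/MAD) of
    frequency, amplitude and linewidth beyond ``mad_k`` flag motion.
    """

    rel_uncertainty_max: float = 0.05
    mad_k: float = 3.0
    features: tuple[str, ...] = ("frequency", "amplitude", "linewidth")


class AllShotsRejectedError(RuntimeError):
    pass


def _robust_z(values: np.ndarray) -> np.ndarray:
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0.0:
        z = np.zeros_like(values)
        z[values != med] = np.inf
        return z
    return np.abs(values - med) / (1.4826 * mad)


def reject_shots(
    fits: list[WaterShotFit],
    policy: RejectionPolicy | None = None,
) -> tuple[list[int], list[int], dict[int, list[str]]]:
    """MoCom rejection: uncertainty rule OR robust-outlier rule.

    Returns (kept shot indices, excluded shot indices, reasons per excluded
    shot).  Thresholding of the uncertainty rule is strict ("exceeds 5%"),
    so a shot at exactly the threshold is kept.
    """
    policy = policy or RejectionPolicy()
    if len(fits) < 4:
        raise ValueError("need at least 4 shot fits for outlier statistics")

    feats = {
        "frequency": np.array([f.frequency for f in fits]),
        "amplitude": np.array([f.amplitude for f in fits]),
        "linewidth": np.array([f.linewidth for f in fits]),
    }
    z = {name: _robust_z(feats[name]) for name in policy.features}

    kept, excluded, reasons = [], [], {}
    for i, f in enumerate(fits):
        why = []
        if not f.converged:
            why.append("fit_not_converged")
        if f.amplitude_rel_uncertainty > policy.rel_uncertainty_max:
            why.append("amplitude_uncertainty")
        if f.linewidth_rel_uncertainty > policy.rel_uncertainty_max:
            why.append("linewidth_uncertainty")
        for name in policy.features:
            if z[name][i] > policy.mad_k:
                why.append(f"{name}_outlier")
        if why:
            excluded.append(f.shot_index)
            reasons[f.shot_index] = why
        else:
            kept.append(f.shot_index)

    if not kept:
        counts: dict[str, int] = {}
        for why in reasons.values():
            for w in why:
                counts[w] = counts.get(w, 0) + 1
        dominant = max(counts, key=counts.get)
        raise AllShotsRejectedError(f"all shots excluded (dominant reason: {dominant})")
    return kept, excluded, reasons


def _eddy_phase(fid: np.ndarray, acq: AcquisitionConfig, band_hz: float = 30.0) -> np.ndarray:
    """Time-dependent phase of the water component of a corrected FID.

    The water line sits at the carrier after frequency correction, so a
    band-limited filter around 0 Hz isolates it; its instantaneous phase is
    the eddy-current phase error.  The phase is smoothed over a few ms and
    tapered where the filtered water magnitude approaches the in-band noise
    floor, so late-FID phase noise is not imprinted on the metabolites.
    """
    spec = np.fft.fft(fid)
    freqs = np.fft.fftfreq(acq.n_points, d=acq.dwell_time)
    in_band = np.abs(freqs) <= band_hz
    water = np.fft.ifft(np.where(in_band, spec, 0.0))
    phase = np.unwrap(np.angle(water))
    # ~3 ms moving-average smoothing
    width = max(3, int(round(0.003 * acq.spectral_width)) | 1)
    kernel = np.ones(width) / width
    phase = np.convolve(phase, kernel, mode="same")
    # noise floor of the band-limited water signal, from a signal-free band
    far = np.abs(freqs) > 0.35 * acq.spectral_width
    sigma = (
        np.sqrt(np.mean(np.abs(spec[far]) ** 2) * np.mean(in_band) / acq.n_points)
        if np.any(far)
        else 0.0
    )
    mag = np.abs(water)
    weight = mag**2 / (mag**2 + (5.0 * sigma) ** 2 + 1e-300)
    return phase * weight


def correct_and_combine(
    transients: TransientSet,
    fits: list[WaterShotFit],
    kept: list[int],
    eddy_correction: bool = True,
    correct: bool = True,
) -> tuple[Spectrum, Spectrum]:
    """Correct kept shots, pair them by cycling state, average both runs.

    Each kept shot is frequency-shifted and zero-order-phased according to
    its water fit and (optionally) eddy-current corrected by subtracting
    the time-dependent phase of its water signal.  Consecutive cycling
    pairs are combined as difference (metabolite) and sum (water); orphaned
    shots whose partner was rejected are dropped with a warning.  Returns
    the (metabolite, water) average spectra with shot-count provenance.
    ``correct=False`` skips the per-shot corrections (diagnostic use).
    """
    if not kept:
        raise ValueError("kept shot list is empty")
    acq = transients.acq
    fit_by_idx = {f.shot_index: f for f in fits}
    kept_set = set(kept)
    t = acq.time_axis()

    # frequency/phase are estimated per shot but applied per cycling pair
    # (mean of the pair): drift is slow on the shot-pair timescale, and an
    # identical correction within a pair preserves exact water cancellation
    pair_of = {}
    for tr in transients:
        if tr.shot_index in kept_set:
            base = tr.shot_index - (0 if tr.cycling_state == +1 else 1)
            pair_of[tr.shot_index] = base
    corrected: dict[int, np.ndarray] = {}
    for tr in transients:
        if tr.shot_index not in kept_set:
            continue
        s = tr.samples
        if correct:
            base = pair_of[tr.shot_index]
            members = [i for i in (base, base + 1) if i in kept_set and pair_of.get(i) == base]
            freq = float(np.mean([fit_by_idx[i].frequency for i in members]))
            # circular mean avoids wrap-around at +-180 deg
            phase = float(
                np.angle(
                    np.mean(
                        [np.exp(1j * math.radians(fit_by_idx[i].zero_order_phase)) for i in members]
                    )
                )
            )
            s = s * np.exp(-1j * (2 * np.pi * freq * t + phase))
        corrected[tr.shot_index] = s

    by_pos = {tr.shot_index: tr for tr in transients}
    metab_acc = np.zeros(acq.n_points, dtype=complex)
    water_acc = np.zeros(acq.n_points, dtype=complex)
    n_pairs = 0
    n_orphans = 0
    runs_seen = set()
    for idx in sorted(corrected):
        tr = by_pos[idx]
        if tr.cycling_state != +1:
            continue
        partner = idx + 1
        if partner not in corrected or by_pos[partner].run_index != tr.run_index:
            n_orphans += 1
            continue
        plus, minus = corrected[idx], corrected[partner]
        diff = (plus - minus) / 2.0
        wsum = (plus + minus) / 2.0
        if correct and eddy_correction:
            # eddy phase from the pair's water sum (metabolites cancel
            # there), applied identically to both combinations
            ecc = np.exp(-1j * _eddy_phase(wsum, acq))
            diff = diff * ecc
            wsum = wsum * ecc
        metab_acc += diff
        water_acc += wsum
        n_pairs += 1
        runs_seen.add(tr.run_index)
    # odd shots whose even partner is missing are also orphans
    n_orphans += sum(
        1
        for idx in corrected
        if by_pos[idx].cycling_state == -1 and (idx - 1) not in corrected
    )
    if n_pairs == 0:
        raise ValueError("no complete cycling pairs remain after rejection")
    if n_orphans:
        level = logging.WARNING if n_orphans > n_pairs else logging.INFO
        logger.log(level, "dropped %d orphaned cycling shots", n_orphans)

    prov = {
        "n_shots_kept": 2 * n_pairs,
        "n_shots_excluded": len(transients) - 2 * n_pairs,
        "n_pairs": n_pairs,
        "n_orphans_dropped": n_orphans,
        "runs_averaged": sorted(runs_seen),
    }
    metab = fid_to_spectrum(metab_acc / n_pairs, acq, dict(prov))
    water = fid_to_spectrum(water_acc / n_pairs, acq, dict(prov))
    return metab, water


def remove_residual_water(
    spectrum: Spectrum,
    water_band: tuple[float, float] = (4.28, 5.08),
    model_order: int = 16,
    n_hsvd_points: int = 1024,
) -> Spectrum:
    """HSVD residual-water removal.

    The time-domain signal is modelled as a sum of ``model_order`` damped
    complex exponentials estimated from the truncated SVD (Lanczos) of its
    Hankel matrix; only components whose frequency falls inside
    ``water_band`` (ppm) are subtracted, leaving the rest of the spectrum
    untouched.  If no component lands in the band the input is returned
    unchanged.
    """
    acq = spectrum.acq
    fid = spectrum_to_fid(spectrum)
    k = min(n_hsvd_points, fid.size)
    sig = fid[:k]
    rows = k // 2
    h = hankel(sig[:rows], sig[rows - 1 : k])

    max_order = min(h.shape) - 2
    if model_order > max_order:
        logger.warning("model_order %d reduced to feasible %d", model_order, max_order)
        model_order = max_order

    u, sv, _ = svds(h, k=model_order)
    # keep only the numerically significant part of the signal subspace;
    # spurious directions otherwise yield junk poles with large
    # mutually-cancelling amplitudes
    order = np.argsort(sv)[::-1]
    u, sv = u[:, order], sv[order]
    keep = sv >= 1e-8 * sv[0]
    u = u[:, keep]
    # shift-invariance of the signal subspace gives the pole matrix
    z_mat = lstsq(u[:-1, :], u[1:, :], lapack_driver="gelsd")[0]
    poles = np.linalg.eigvals(z_mat)
    # clip growing exponentials so extrapolation over the full FID is stable
    mags = np.minimum(np.abs(poles), 1.0)
    poles = mags * np.exp(1j * np.angle(poles))

    freqs = np.angle(poles) / (2 * np.pi * acq.dwell_time)
    band_lo = acq.ppm_to_hz(max(water_band))
    band_hi = acq.ppm_to_hz(min(water_band))
    in_band = (freqs >= band_lo) & (freqs <= band_hi)
    if not np.any(in_band):
        return spectrum

    # complex amplitudes by linear least squares on the modelled segment
    basis = poles[None, :] ** np.arange(k)[:, None]
    amps = lstsq(basis, sig, lapack_driver="gelsd")[0]

    n = fid.size
    water_fid = (poles[in_band][None, :] ** np.arange(n)[:, None]) @ amps[in_band]
    cleaned = fid - water_fid
    prov = dict(spectrum.provenance)
    prov["hsvd"] = {
        "model_order": int(model_order),
        "n_components_removed": int(np.count_nonzero(in_band)),
        "water_band_ppm": [float(min(water_band)), float(max(water_band))],
    }
    return fid_to_spectrum(cleaned, acq, prov)


def preprocess(
    transients: TransientSet,
    policy: RejectionPolicy | None = None,
    water_band: tuple[float, float] = (4.28, 5.08),
    model_order: int = 16,
) -> tuple[Spectrum, Spectrum, list[WaterShotFit], dict]:
    """Full shot-to-spectrum chain; returns (metabolite, water, fits, qc).

    Convenience wrapper running water fitting, rejection, correction,
    combination and residual-water removal with default settings.
    """
    fits = [fit_water_shot(tr, transients.acq) for tr in transients]
    kept, excluded, reasons = reject_shots(fits, policy)
    metab, water = correct_and_combine(transients, fits, kept)
    metab = remove_residual_water(metab, water_band, model_order)
    qc = {
        "kept": kept,
        "excluded": excluded,
        "reasons": reasons,
        "exclusion_fraction": len(excluded) / len(fits),
    }
    return metab, water, fits, qc
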