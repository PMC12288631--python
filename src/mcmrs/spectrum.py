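"""Frequency-domain spectrum container and FFT conventions.

The package-wide convention: a time-domain component
``exp(2i*pi*f*t)`` with ``f = (water_ppm - delta) * f0_MHz`` appears at
chemical shift ``delta``.  Spectra are stored on a strictly increasing ppm
axis (water to the right of NAA on this axis; plotting in the conventional
reversed direction is a display choice).  The FFT is orthonormal
(``norm="ortho"``), so time- and frequency-domain energies and white-noise
standard deviations coincide (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mcmrs.config import AcquisitionConfig


@dataclass
class Spectrum:
    """A complex frequency-domain spectrum with its ppm axis.

    ``provenance`` records how the spectrum was built (shots kept/excluded,
    runs averaged, number of subjects in a cohort average, ...).
    """

    data: np.ndarray
    ppm: np.ndarray
    acq: AcquisitionConfig
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.data.shape != self.ppm.shape:
            raise ValueError("data and ppm axis must have the same length")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")

    def band_mask(self, ppm_lo: float, ppm_hi: float) -> np.ndarray:
        lo, hi = min(ppm_lo, ppm_hi), max(ppm_lo, ppm_hi)
        return (self.ppm >= lo) & (self.ppm <= hi)

    def band(self, ppm_lo: float, ppm_hi: float) -> np.ndarray:
        return self.data[self.band_mask(ppm_lo, ppm_hi)]

    def noise_sd(self, band: tuple[float, float] = (10.5, 12.0)) -> float:
        """Per-point noise SD from the real part of a signal-free region.

        A first-order detrend guards against baseline tails leaking into
        the band.
        """
        vals = np.real(self.band(*band))
        if vals.size < 8:
            raise ValueError("noise band contains too few points")
        x = np.arange(vals.size, dtype=float)
        coef = np.polynomial.polynomial.polyfit(x, vals, 1)
        resid = vals - np.polynomial.polynomial.polyval(x, coef)
        return float(np.std(resid, ddof=2))

    def copy(self) -> "Spectrum":
        return Spectrum(self.data.copy(), self.ppm.copy(), self.acq, dict(self.provenance))


def ppm_axis(acq: AcquisitionConfig) -> np.ndarray:
    """Strictly increasing ppm axis matching :func:`fid_to_spectrum`."""
    freqs = np.fft.fftshift(np.fft.fftfreq(acq.n_points, d=acq.dwell_time))
    return (acq.water_ppm - freqs / acq.spectrometer_frequency)[::-1]


def fid_to_spectrum(fid: np.ndarray, acq: AcquisitionConfig, provenance: dict | None = None) -> Spectrum:
    """Orthonormal FFT of a complex FID onto the increasing-ppm axis."""
    fid = np.asarray(fid, dtype=complex)
    if fid.shape[-1] != acq.n_points:
        raise ValueError(f"FID length {fid.shape[-1]} != n_points {acq.n_points}")
    spec = np.fft.fftshift(np.fft.fft(fid, norm="ortho"))[::-1]
    return Spectrum(spec, ppm_axis(acq), acq, provenance or {})


def spectrum_to_fid(spectrum: Spectrum) -> np.ndarray:
    """Inverse of :func:`fid_to_spectrum`."""
    return np.fft.ifft(np.fft.ifftshift(spectrum.data[::-1]), norm="ortho")


def fid_matrix_to_spectra(fids: np.ndarray) -> np.ndarray:
    """FFT each row of a (k, n_points) FID matrix; rows align with the ppm axis."""
    return np.fft.fftshift(np.fft.fft(fids, axis=-1, norm="ortho"), axes=-1)[..., ::-1]
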