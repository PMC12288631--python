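"""Two-compartment water referencing and absolute quantification.

The unsuppressed water echo series decays biexponentially with TE,

    S(TE) = S_par * exp(-TE/T2_par) + S_CSF * exp(-TE/T2_CSF),

separating parenchymal from CSF water.  The parenchymal TE=0 amplitude is
the internal concentration reference: a metabolite amplitude S_M converts
to millimolar as

    M = S_M/S_H2O * 1/(1 - exp(-TR/T1))
              * 1/exp(-TE/(1.5 * T2))
              * (f_GM * d_GM + f_WM * d_WM) * [H2O]_molar

with metabolite relaxation times T1/T2, GM/WM voxel volume fractions
(CSF excluded, f_GM + f_WM = 1), literature water contents d_GM = 0.78 and
d_WM = 0.65, and [H2O]_molar = 55.5 M.  T2 is stretched by 1.5 because
transverse decay under the semi-LASER echo train is slower than a
conventional spin echo.  S_M and S_H2O are per-proton-normalised signal
amplitudes; the proton-weighted basis handles the metabolite side, and the
factor 2 for water is applied when building the reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from mcmrs.basis import SUMS, BasisSet
from mcmrs.config import AcquisitionConfig
from mcmrs.lcmfit import LCMResult
from mcmrs.synthgen import D_GM, D_WM, H2O_MOLAR, WaterEchoSeries

logger = logging.getLogger(__name__)


@dataclass
class TwoCompartmentResult:
    """Biexponential water-decay fit: TE=0 amplitudes and T2s."""

    S_parenchyma: float
    S_CSF: float
    T2_parenchyma: float  # ms
    T2_CSF: float  # ms
    residual_rms: float = 0.0
    s_par_rel_uncertainty: float = 0.0  # SE of S_parenchyma / S_parenchyma

    def __post_init__(self) -> None:
        if self.S_parenchyma < 0 or self.S_CSF < 0:
            raise ValueError("compartment amplitudes must be non-negative")
        if not (0 < self.T2_parenchyma < self.T2_CSF):
            raise ValueError("require 0 < T2_parenchyma < T2_CSF")

    @property
    def S_total(self) -> float:
        """Extrapolated S(0): the sum of both compartments."""
        return self.S_parenchyma + self.S_CSF

    def model(self, te: np.ndarray) -> np.ndarray:
        te = np.asarray(te, dtype=float)
        return self.S_parenchyma * np.exp(-te / self.T2_parenchyma) + self.S_CSF * np.exp(
            -te / self.T2_CSF
        )


def fit_water_decay(
    series: WaterEchoSeries, start: dict | None = None
) -> TwoCompartmentResult:
    """Fit the two-compartment TE decay to eddy-corrected water magnitudes.

    Magnitude amplitudes are used.  If the optimiser converges with the
    compartments in the wrong T2 order they are relabelled.  Requires at
    least 5 distinct echo times spanning short and long TEs.
    """
    te = series.te_list
    y = series.magnitudes.astype(float)
    if np.unique(te).size < 5:
        raise ValueError("need >= 5 distinct echo times for a two-compartment fit")

    s0 = float(np.max(y))
    guesses = {"S_par": 0.8 * s0, "S_CSF": 0.2 * s0, "T2_par": 80.0, "T2_CSF": 500.0}
    if start:
        guesses.update(start)

    def resid(x):
        s_par, s_csf, t2_par, t2_csf = x
        return s_par * np.exp(-te / t2_par) + s_csf * np.exp(-te / t2_csf) - y

    x0 = np.array([guesses["S_par"], guesses["S_CSF"], guesses["T2_par"], guesses["T2_CSF"]])
    sol = least_squares(
        resid,
        x0,
        bounds=([0.0, 0.0, 1.0, 1.0], [np.inf, np.inf, 3000.0, 5000.0]),
        xtol=1e-14,
        ftol=1e-14,
        max_nfev=2000,
    )
    s_par, s_csf, t2_par, t2_csf = sol.x
    swapped = t2_par > t2_csf
    if swapped:
        logger.info("compartments relabelled: T2 order violated at optimum")
        s_par, s_csf = s_csf, s_par
        t2_par, t2_csf = t2_csf, t2_par
    if math.isclose(t2_par, t2_csf, rel_tol=1e-9):
        t2_csf = t2_par * (1 + 1e-9)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    # standard error of S_par from the Gauss-Newton covariance
    dof = max(te.size - 4, 1)
    sigma2 = float(np.sum(sol.fun**2)) / dof
    rel_unc = 0.0
    try:
        cov = sigma2 * np.linalg.inv(sol.jac.T @ sol.jac)
        idx = 1 if swapped else 0
        var = cov[idx, idx]
        if var > 0 and s_par > 0:
            rel_unc = float(np.sqrt(var) / s_par)
    except np.linalg.LinAlgError:
        rel_unc = float("inf")
    return TwoCompartmentResult(
        float(s_par), float(s_csf), float(t2_par), float(t2_csf), rms, rel_unc
    )


@dataclass
class QuantParams:
    """Every symbol of the absolute-quantification equation."""

    S_M: float  # metabolite signal amplitude (per-proton-normalised)
    S_H2O: float  # parenchymal water amplitude at TE=0 (per-proton-normalised)
    TR: float  # ms
    TE: float  # ms
    T1: float  # metabolite T1, ms
    T2: float  # metabolite T2, ms
    f_GM: float
    f_WM: float
    t2_stretch: float = 1.5
    d_GM: float = D_GM
    d_WM: float = D_WM
    H2O_molar: float = H2O_MOLAR  # mM

    def __post_init__(self) -> None:
        if abs(self.f_GM + self.f_WM - 1.0) > 1e-9:
            raise ValueError("f_GM + f_WM must sum to 1 (CSF excluded)")
        if self.T1 <= 0 or self.T2 <= 0 or self.TR <= 0 or self.TE < 0:
            raise ValueError("relaxation times and TR must be positive, TE non-negative")
        if self.S_H2O <= 0:
            raise ValueError("water reference amplitude must be positive")

    @property
    def tissue_water_factor(self) -> float:
        """f_GM*d_GM + f_WM*d_WM — the voxel's relative water content."""
        return self.f_GM * self.d_GM + self.f_WM * self.d_WM


def absolute_concentration(p: QuantParams) -> float:
    """Millimolar concentration from the water-referenced signal ratio.

    Applies, in order: the signal ratio, the T1-saturation correction, the
    (stretched) T2-loss correction, the tissue-water factor and the molar
    water concentration.
    """
    t1_corr = 1.0 / (1.0 - math.exp(-p.TR / p.T1))
    t2_corr = 1.0 / math.exp(-p.TE / (p.t2_stretch * p.T2))
    return (p.S_M / p.S_H2O) * t1_corr * t2_corr * p.tissue_water_factor * p.H2O_molar


def quantify_tcr(
    lcm: LCMResult,
    water: TwoCompartmentResult,
    acq: AcquisitionConfig,
    basis: BasisSet,
    f_GM: float,
    f_WM: float,
    t2_stretch: float = 1.5,
) -> float:
    """Absolute tCr (mM) = mM(Cr) + mM(PCr), water-referenced per component.

    The water echo series measures both protons of each water molecule, so
    the per-proton water reference is S_parenchyma / 2.
    """
    s_h2o = water.S_parenchyma / basis.water_protons
    total = 0.0
    for name in SUMS["tCr"]:
        m = basis.metabolites[name]
        p = QuantParams(
            S_M=lcm.amplitudes[name],
            S_H2O=s_h2o,
            TR=acq.TR,
            TE=acq.TE,
            T1=m.t1_ms,
            T2=m.t2_ms,
            f_GM=f_GM,
            f_WM=f_WM,
            t2_stretch=t2_stretch,
        )
        total += absolute_concentration(p)
    return total


def amplitude_to_mm_factor(
    lcm: LCMResult,
    water: TwoCompartmentResult,
    acq: AcquisitionConfig,
    basis: BasisSet,
    f_GM: float,
    f_WM: float,
    name: str,
    t2_stretch: float = 1.5,
) -> float:
    """Multiplicative calibration from institutional amplitude to mM."""
    m = basis.metabolites[name]
    p = QuantParams(
        S_M=1.0,
        S_H2O=water.S_parenchyma / basis.water_protons,
        TR=acq.TR,
        TE=acq.TE,
        T1=m.t1_ms,
        T2=m.t2_ms,
        f_GM=f_GM,
        f_WM=f_WM,
        t2_stretch=t2_stretch,
    )
    return absolute_concentration(p)


def calibrate_ratios(
    lcm: LCMResult,
    tcr_mM: float,
    relax_correction: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-metabolite table of ratios to tCr and tCr-anchored mM values.

    mM(metabolite) = (ratio to tCr) x absolute tCr concentration; the
    ratios themselves carry the primary analysis.  ``relax_correction``
    maps metabolite names to 1/attenuation factors (inverse of the T1/T2
    signal loss); when given, amplitudes are corrected before ratios are
    formed so that ratios estimate concentration ratios rather than raw
    signal ratios.
    """

    def corrected(name: str) -> float:
        amp = lcm.amplitudes[name]
        if relax_correction:
            amp *= relax_correction.get(name, 1.0)
        return amp

    tcr_amp = sum(corrected(c) for c in SUMS["tCr"])
    if tcr_amp <= 0:
        raise ValueError("tCr amplitude must be positive for calibration")
    rows = []
    entries = {n: corrected(n) for n in lcm.amplitudes}
    entries.update(
        {
            s: sum(corrected(c) for c in comps)
            for s, comps in SUMS.items()
            if all(c in lcm.amplitudes for c in comps)
        }
    )
    for name, amp in entries.items():
        ratio = amp / tcr_amp
        rows.append(
            {
                "metabolite": name,
                "amplitude": amp,
                "ratio_to_tcr": ratio,
                "mM": ratio * tcr_mM,
                "crlb": lcm.crlb.get(name, np.nan),
                "crlb_mm": lcm.crlb_mm.get(name, np.nan),
            }
        )
    return pd.DataFrame(rows).set_index("metabolite")
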