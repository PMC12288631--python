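"""Synthetic metabolite-cycled acquisitions with known ground truth.

The simulator produces what the scanner would hand to the processing chain:
per-shot complex FIDs of a non-water-suppressed, metabolite-cycled
semi-LASER acquisition (water plus 18 metabolites plus a macromolecular
background, Voigt lineshapes, phase/frequency drift, motion-corrupted
shots, additive complex white noise) and an 8-echo unsuppressed water
series whose TE-decay follows a two-compartment (parenchyma/CSF) model.

Metabolite cycling is modelled as an ideal sign alternation of the
metabolite (and macromolecular) signal between consecutive shots while the
water signal is unaffected, so that shot-pair differences yield the
metabolite spectrum and sums the water spectrum.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from mcmrs.basis import BasisSet, load_default_basis, voigt_envelope
from mcmrs.config import AcquisitionConfig, ConfigurationError, brain_config, cord_config

# GM/WM/CSF water contents (fraction of pure water) used throughout.
D_GM = 0.78
D_WM = 0.65
D_CSF = 0.97
H2O_MOLAR = 55500.0  # mM, pure-water molarity


@dataclass(frozen=True)
class DriftModel:
    """Shot-to-shot frequency/phase drift.

    ``kind="linear"``: offset grows by ``freq_per_shot`` Hz (resp.
    ``phase_per_shot`` degrees) per shot.  ``kind="random_walk"``: the
    per-shot increments are N(0, rate) draws accumulated over shots.
    """

    kind: str = "linear"
    freq_per_shot: float = 0.0
    phase_per_shot: float = 0.0

    def realise(self, n_shots: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        if self.kind == "linear":
            s = np.arange(n_shots)
            return self.freq_per_shot * s, self.phase_per_shot * s
        if self.kind == "random_walk":
            df = rng.normal(0.0, abs(self.freq_per_shot), n_shots)
            dp = rng.normal(0.0, abs(self.phase_per_shot), n_shots)
            return np.cumsum(df), np.cumsum(dp)
        raise ConfigurationError(f"unknown drift kind {self.kind!r}")


@dataclass(frozen=True)
class CorruptionModel:
    """Motion-like corruption of individual shots.

    Each corrupted shot receives a multiplicative amplitude factor, an
    additive frequency jump (random sign) and extra Lorentzian broadening,
    drawn uniformly from the configured ranges.
    """

    amplitude_range: tuple[float, float] = (0.4, 0.8)
    freq_jump_range_hz: tuple[float, float] = (8.0, 25.0)
    broadening_range_hz: tuple[float, float] = (5.0, 15.0)

    def draw(self, rng: np.random.Generator) -> tuple[float, float, float]:
        amp = rng.uniform(*self.amplitude_range)
        jump = rng.uniform(*self.freq_jump_range_hz) * rng.choice([-1.0, 1.0])
        broad = rng.uniform(*self.broadening_range_hz)
        return amp, jump, broad


@dataclass
class GroundTruth:
    """Everything the simulator knows and the pipeline tries to recover."""

    concentrations: dict[str, float]
    mmbg_scale: float = 1.0
    gauss_lw: float = 3.4
    lorentz_lw: float = 0.0  # extra Lorentz broadening on top of basis widths
    zero_order_phase: float = 0.0  # degrees
    frequency_offset: float = 0.0  # Hz
    noise_sd: float = 0.0  # per-point complex noise SD (each component)
    drift: DriftModel = field(default_factory=DriftModel)
    corruption: CorruptionModel = field(default_factory=CorruptionModel)
    corrupt_shot_indices: frozenset[int] = frozenset()
    f_GM: float = 0.38
    f_WM: float = 0.62
    f_CSF: float = 0.0
    water_T2_parenchyma: float = 80.0  # ms
    water_T2_CSF: float = 600.0  # ms
    water_echo_noise_frac: float = 0.0  # additive noise SD as fraction of S(0)
    t2_stretch: float = 1.5

    def validate(self, acq: AcquisitionConfig) -> None:
        if any(c < 0 for c in self.concentrations.values()):
            raise ConfigurationError("concentrations must be non-negative")
        if abs(self.f_GM + self.f_WM + self.f_CSF - 1.0) > 1e-9:
            raise ConfigurationError("f_GM + f_WM + f_CSF must sum to 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.corrupt_shot_indices and (
            min(self.corrupt_shot_indices) < 0
            or max(self.corrupt_shot_indices) >= acq.n_shots_total
        ):
            raise ConfigurationError("corrupt_shot_indices outside valid shot range")
        if not (0 < self.water_T2_parenchyma < self.water_T2_CSF):
            raise ConfigurationError("require 0 < water_T2_parenchyma < water_T2_CSF")

    @property
    def parenchymal_water_factor(self) -> float:
        """fGM*dGM + fWM*dWM, the CSF-free tissue-water factor."""
        csf_free = self.f_GM + self.f_WM
        if csf_free <= 0:
            return 0.0
        # fractions renormalised to the CSF-free voxel part for the factor
        return (self.f_GM * D_GM + self.f_WM * D_WM) / csf_free

    def digest(self) -> str:
        payload = {
            "concentrations": dict(sorted(self.concentrations.items())),
            "mmbg_scale": self.mmbg_scale,
            "gauss_lw": self.gauss_lw,
            "f": [self.f_GM, self.f_WM, self.f_CSF],
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class Transient:
    """One single-shot FID with its cycling metadata."""

    samples: np.ndarray
    cycling_state: int  # +1 | -1, alternates with shot parity within a run
    run_index: int
    shot_index: int  # global index across runs

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.cycling_state not in (+1, -1):
            raise ValueError("cycling_state must be +1 or -1")


@dataclass
class TransientSet:
    """Ordered collection of shots for one subject/region."""

    transients: list[Transient]
    acq: AcquisitionConfig
    truth_digest: str = ""

    def __len__(self) -> int:
        return len(self.transients)

    def __iter__(self):
        return iter(self.transients)

    def __getitem__(self, i: int) -> Transient:
        return self.transients[i]


@dataclass
class WaterEchoSeries:
    """Unsuppressed water amplitudes over a multi-TE echo train."""

    te_list: np.ndarray  # ms
    amplitudes: np.ndarray  # complex or magnitude, same length
    TR: float  # ms

    def __post_init__(self) -> None:
        self.te_list = np.asarray(self.te_list, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes)
        if self.te_list.ndim != 1 or self.te_list.size != self.amplitudes.size:
            raise ValueError("te_list and amplitudes must be 1-D of equal length")
        if np.any(self.te_list <= 0) or np.unique(self.te_list).size != self.te_list.size:
            raise ValueError("te_list must be strictly positive and unique")

    @property
    def magnitudes(self) -> np.ndarray:
        return np.abs(self.amplitudes)


def _water_compartment_amplitudes(truth: GroundTruth) -> tuple[float, float]:
    """Proton-weighted TE=0 water amplitudes of parenchyma and CSF."""
    protons = 2.0
    s_par = protons * (truth.f_GM * D_GM + truth.f_WM * D_WM) * H2O_MOLAR
    s_csf = protons * truth.f_CSF * D_CSF * H2O_MOLAR
    return s_par, s_csf


def _metabolite_fid(truth: GroundTruth, acq: AcquisitionConfig, basis: BasisSet) -> np.ndarray:
    """Relaxation-attenuated metabolite + MMBG signal at the shot TE/TR."""
    fid = np.zeros(acq.n_points, dtype=complex)
    for name, conc in truth.concentrations.items():
        if conc == 0.0:
            continue
        att = basis.relaxation_attenuation(name, acq, truth.t2_stretch)
        fid += conc * att * basis.metabolite_fid(
            name, acq, gauss_lw=truth.gauss_lw, extra_lorentz_lw=truth.lorentz_lw
        )
    if truth.mmbg_scale != 0.0:
        fid += truth.mmbg_scale * basis.mmbg_truth_fid(acq, gauss_lw=truth.gauss_lw)
    return fid


def _water_fid(truth: GroundTruth, acq: AcquisitionConfig, basis: BasisSet) -> np.ndarray:
    """Water signal at the shot TE, both compartments, T1-saturated."""
    s_par, s_csf = _water_compartment_amplitudes(truth)
    t1_sat = 1.0 - math.exp(-acq.TR / basis.water_t1_ms)
    amp = t1_sat * (
        s_par * math.exp(-acq.TE / truth.water_T2_parenchyma)
        + s_csf * math.exp(-acq.TE / truth.water_T2_CSF)
    )
    t = acq.time_axis()
    return amp * voigt_envelope(t, basis.water_lorentz_lw + truth.lorentz_lw, truth.gauss_lw)


def simulate_subject(
    truth: GroundTruth,
    acq: AcquisitionConfig,
    seed: int,
    basis: BasisSet | None = None,
) -> tuple[TransientSet, WaterEchoSeries]:
    """Simulate one subject's shot set and water echo series.

    Fully reproducible for a given ``seed``: per-shot noise streams are
    spawned from a single :class:`numpy.random.SeedSequence` so any subset
    of shots is reproducible independently of the others.
    """
    basis = basis or load_default_basis(acq.TE)
    truth.validate(acq)

    n_total = acq.n_shots_total
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_total + 2)
    drift_rng = np.random.default_rng(children[-2])
    echo_rng = np.random.default_rng(children[-1])

    metab = _metabolite_fid(truth, acq, basis)
    water = _water_fid(truth, acq, basis)
    t = acq.time_axis()
    drift_f, drift_p = truth.drift.realise(n_total, drift_rng)

    transients: list[Transient] = []
    for s in range(n_total):
        run = s // acq.n_shots_per_run
        within = s % acq.n_shots_per_run
        cyc = +1 if within % 2 == 0 else -1
        rng = np.random.default_rng(children[s])

        amp_fac, jump, broad = 1.0, 0.0, 0.0
        if s in truth.corrupt_shot_indices:
            amp_fac, jump, broad = truth.corruption.draw(rng)

        f_shift = truth.frequency_offset + drift_f[s] + jump
        phase = math.radians(truth.zero_order_phase + drift_p[s])
        sig = amp_fac * (water + cyc * metab)
        if broad > 0:
            sig = sig * np.exp(-np.pi * broad * t)
        sig = sig * np.exp(1j * (2 * np.pi * f_shift * t + phase))
        if truth.noise_sd > 0:
            noise = rng.standard_normal(acq.n_points) + 1j * rng.standard_normal(acq.n_points)
            sig = sig + truth.noise_sd * noise
        transients.append(Transient(sig, cyc, run, s))

    series = _simulate_water_echoes(truth, acq, echo_rng)
    return TransientSet(transients, acq, truth.digest()), series


def _simulate_water_echoes(
    truth: GroundTruth, acq: AcquisitionConfig, rng: np.random.Generator
) -> WaterEchoSeries:
    if not acq.water_echo_tes:
        raise ConfigurationError("acquisition defines no water echo TEs")
    s_par, s_csf = _water_compartment_amplitudes(truth)
    te = np.asarray(acq.water_echo_tes, dtype=float)
    # long-TR series: full T1 recovery assumed
    amps = s_par * np.exp(-te / truth.water_T2_parenchyma) + s_csf * np.exp(
        -te / truth.water_T2_CSF
    )
    amps = amps.astype(complex) * np.exp(1j * math.radians(truth.zero_order_phase))
    if truth.water_echo_noise_frac > 0:
        sd = truth.water_echo_noise_frac * (s_par + s_csf)
        amps = amps + sd * (rng.standard_normal(te.size) + 1j * rng.standard_normal(te.size))
    return WaterEchoSeries(te, amps, acq.water_echo_tr)


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass(frozen=True)
class GroupSpec:
    """One group's design: size, mean concentrations, between-subject SDs."""

    n_subjects: int
    mean_concentrations: dict[str, float]
    between_subject_sd: dict[str, float] = field(default_factory=dict)
    corrupt_fraction: float = 0.1

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ConfigurationError("group size must be non-negative")
        if any(v < 0 for v in self.between_subject_sd.values()):
            raise ConfigurationError("between-subject SDs must be non-negative")
        if not 0 <= self.corrupt_fraction < 1:
            raise ConfigurationError("corrupt_fraction must be in [0, 1)")


@dataclass(frozen=True)
class CohortDesign:
    """A two-group (or multi-group) simulated study design."""

    acq: AcquisitionConfig
    groups: dict[str, GroupSpec]
    truth_template: GroundTruth | None = None
    freq_offset_sd: float = 2.0  # Hz, between subjects
    phase_sd_deg: float = 15.0
    gauss_lw_sd: float = 0.3  # Hz, between subjects

    def validate(self) -> None:
        for g in self.groups.values():
            g.validate()


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    transients: TransientSet
    water_series: WaterEchoSeries
    truth: GroundTruth


def simulate_cohort(
    design: CohortDesign, seed: int, basis: BasisSet | None = None
) -> list[SubjectRecord]:
    """Draw per-subject ground truths from the group distributions and simulate.

    Per-subject seeds are spawned deterministically from the master seed, so
    any subject can be re-simulated in isolation.
    """
    design.validate()
    basis = basis or load_default_basis(design.acq.TE)
    template = design.truth_template or GroundTruth(
        concentrations={n: m.default_conc_mm for n, m in basis.metabolites.items()}
    )
    master = np.random.SeedSequence(seed)
    records: list[SubjectRecord] = []
    sid = 0
    for label, spec in design.groups.items():
        for _ in range(spec.n_subjects):
            draw_ss, sim_ss = master.spawn(2)
            rng = np.random.default_rng(draw_ss)
            conc = {}
            for name, mean in spec.mean_concentrations.items():
                sd = spec.between_subject_sd.get(name, 0.0)
                conc[name] = max(0.0, mean + (rng.normal(0.0, sd) if sd > 0 else 0.0))
            n_total = design.acq.n_shots_total
            n_corrupt = int(round(spec.corrupt_fraction * n_total))
            corrupt = frozenset(
                rng.choice(n_total, size=n_corrupt, replace=False).tolist()
            ) if n_corrupt else frozenset()
            truth = replace(
                template,
                concentrations=conc,
                corrupt_shot_indices=corrupt,
                frequency_offset=template.frequency_offset
                + rng.normal(0.0, design.freq_offset_sd),
                zero_order_phase=template.zero_order_phase
                + rng.normal(0.0, design.phase_sd_deg),
                gauss_lw=max(0.5, template.gauss_lw + rng.normal(0.0, design.gauss_lw_sd)),
            )
            subject_seed = int(sim_ss.generate_state(1)[0] % (2**31))
            transients, series = simulate_subject(truth, design.acq, subject_seed, basis)
            records.append(SubjectRecord(f"S{sid:03d}", label, transients, series, truth))
            sid += 1
    return records


# ---------------------------------------------------------------------------
# Study-condition designs mirroring the cohort summary statistics

# (tCr mean, tCr SD) in mM and ratio (mean, SD) per group, per region.
_GROUP_STATS = {
    "brain": {
        "HC": {"tCr": (7.74, 0.67), "tNAA/tCr": (1.94, 0.21), "tCho/tCr": (0.22, 0.05), "mI/tCr": (0.87, 0.10), "corrupt": 0.176},
        "SCI": {"tCr": (7.88, 0.76), "tNAA/tCr": (1.77, 0.14), "tCho/tCr": (0.23, 0.03), "mI/tCr": (0.86, 0.13), "corrupt": 0.215},
    },
    "cord": {
        "HC": {"tCr": (4.02, 1.33), "tNAA/tCr": (2.48, 0.76), "tCho/tCr": (0.67, 0.43), "mI/tCr": (1.94, 0.61), "corrupt": 0.108},
        "SCI": {"tCr": (4.75, 1.66), "tNAA/tCr": (1.81, 0.80), "tCho/tCr": (0.60, 0.34), "mI/tCr": (2.31, 0.52), "corrupt": 0.080},
    },
}

# fixed splits of the derived sums into their components
_SUM_SPLIT = {"tNAA": ("NAA", "NAAG", 0.90), "tCr": ("Cr", "PCr", 0.58), "tCho": ("GPC", "PCho", 0.65)}


def group_concentrations(region: str, group: str, basis: BasisSet | None = None) -> tuple[dict, dict]:
    """Mean concentrations and between-subject SDs for one study group.

    Sums (tNAA, tCr, tCho) and mI are set so the group means of the ratios
    to tCr match the study's summary table; the remaining basis metabolites
    keep their default concentrations.  Ratio variability is mapped onto the
    numerator metabolites assuming independent numerator/denominator
    variation: cv_num = sqrt(max(cv_ratio^2 - cv_tCr^2, 0.02^2)).
    """
    basis = basis or load_default_basis()
    stats = _GROUP_STATS[region][group]
    tcr_mean, tcr_sd = stats["tCr"]
    cv_tcr = tcr_sd / tcr_mean

    mean = {n: m.default_conc_mm for n, m in basis.metabolites.items()}
    sd = {n: 0.0 for n in mean}

    def set_sum(sum_name: str, total: float, cv: float) -> None:
        a, b, frac = _SUM_SPLIT[sum_name]
        mean[a], mean[b] = frac * total, (1 - frac) * total
        sd[a], sd[b] = cv * mean[a], cv * mean[b]

    set_sum("tCr", tcr_mean, cv_tcr)
    for ratio_name, sum_name in (("tNAA/tCr", "tNAA"), ("tCho/tCr", "tCho")):
        r_mean, r_sd = stats[ratio_name]
        cv_r = r_sd / r_mean
        cv_num = math.sqrt(max(cv_r**2 - cv_tcr**2, 0.02**2))
        set_sum(sum_name, r_mean * tcr_mean, cv_num)
    r_mean, r_sd = stats["mI/tCr"]
    cv_num = math.sqrt(max((r_sd / r_mean) ** 2 - cv_tcr**2, 0.02**2))
    mean["mI"] = r_mean * tcr_mean
    sd["mI"] = cv_num * mean["mI"]
    return mean, sd


def study_design(
    region: str = "brain",
    n_hc: int | None = None,
    n_sci: int | None = None,
    noise_sd: float = 25.0,
    between_subject_variation: bool = True,
    corrupt: bool = True,
    basis: BasisSet | None = None,
    **truth_overrides,
) -> CohortDesign:
    """The default two-group study design for a region.

    Group sizes default to the analysed cohorts (brain 18 HC / 15 SCI,
    cord 19 HC / 15 SCI); concentrations mirror the group summary
    statistics via :func:`group_concentrations`.
    """
    basis = basis or load_default_basis()
    if region == "brain":
        acq = brain_config()
        n_hc = 18 if n_hc is None else n_hc
        n_sci = 15 if n_sci is None else n_sci
        f_gm, f_wm, f_csf = 0.38, 0.62, 0.0
        gauss_lw = 3.4
    elif region == "cord":
        acq = cord_config()
        n_hc = 19 if n_hc is None else n_hc
        n_sci = 15 if n_sci is None else n_sci
        # CSF nulled by water-selective inversion recovery in the cord
        f_gm, f_wm, f_csf = 0.36, 0.64, 0.0
        gauss_lw = 6.4
    else:
        raise ConfigurationError(f"unknown region {region!r}")

    template = GroundTruth(
        concentrations={n: m.default_conc_mm for n, m in basis.metabolites.items()},
        mmbg_scale=1.0,
        gauss_lw=gauss_lw,
        noise_sd=noise_sd,
        drift=DriftModel("linear", freq_per_shot=0.02, phase_per_shot=0.05),
        f_GM=f_gm,
        f_WM=f_wm,
        f_CSF=f_csf,
        water_echo_noise_frac=0.005,
        **truth_overrides,
    )
    groups = {}
    for label, n in (("HC", n_hc), ("SCI", n_sci)):
        mean, sd = group_concentrations(region, label, basis)
        if not between_subject_variation:
            sd = {k: 0.0 for k in sd}
        frac = _GROUP_STATS[region][label]["corrupt"] if corrupt else 0.0
        groups[label] = GroupSpec(n, mean, sd, corrupt_fraction=frac)
    return CohortDesign(acq=acq, groups=groups, truth_template=template)
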