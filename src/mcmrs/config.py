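"""Acquisition configuration for metabolite-cycled single-voxel MRS."""

from __future__ import annotations

from dataclasses import dataclass, field, replace


class ConfigurationError(ValueError):
    """Raised when an acquisition configuration violates its invariants."""


_REGIONS = ("brain", "cord")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Parameters of one metabolite-cycled semi-LASER acquisition.

    Attributes
    ----------
    region:
        ``"brain"`` (motor cortex voxel) or ``"cord"`` (lumbar cord
        enlargement voxel).
    spectrometer_frequency:
        Larmor frequency in MHz (123.25 MHz at 3 T).
    spectral_width:
        Receiver bandwidth in Hz.
    n_points:
        Complex points per FID; power of two, at least 512.
    TR, TE:
        Repetition and echo time of the metabolite acquisition, ms.
    n_shots_per_run:
        Single shots per run; even, because metabolite cycling inverts the
        metabolite region on alternating shots and spectra are built from
        shot pairs.
    n_runs:
        Number of repeated runs that are averaged together.
    water_ppm:
        Chemical shift of water used as the ppm reference (4.68 ppm).
    water_echo_tes:
        Echo times (ms) of the unsuppressed water echo series used for
        two-compartment water referencing.
    water_echo_tr:
        TR (ms) of the water echo series.
    """

    region: str
    TR: float
    TE: float
    n_shots_per_run: int
    n_runs: int = 2
    spectrometer_frequency: float = 123.25
    spectral_width: float = 4000.0
    n_points: int = 2048
    water_ppm: float = 4.68
    water_echo_tes: tuple[float, ...] = ()
    water_echo_tr: float = 6000.0

    def __post_init__(self) -> None:
        if self.region not in _REGIONS:
            raise ConfigurationError(f"region must be one of {_REGIONS}, got {self.region!r}")
        if self.n_points < 512 or (self.n_points & (self.n_points - 1)) != 0:
            raise ConfigurationError("n_points must be a power of two >= 512")
        if self.spectral_width <= 0:
            raise ConfigurationError("spectral_width must be positive")
        if self.n_shots_per_run <= 0 or self.n_shots_per_run % 2 != 0:
            raise ConfigurationError("n_shots_per_run must be positive and even (cycling pairs)")
        if self.n_runs <= 0:
            raise ConfigurationError("n_runs must be positive")
        if self.TR <= 0 or self.TE <= 0:
            raise ConfigurationError("TR and TE must be positive")

    @property
    def dwell_time(self) -> float:
        """Dwell time in seconds."""
        return 1.0 / self.spectral_width

    @property
    def n_shots_total(self) -> int:
        return self.n_shots_per_run * self.n_runs

    def time_axis(self):
        import numpy as np

        return np.arange(self.n_points) * self.dwell_time

    def ppm_to_hz(self, ppm: float) -> float:
        """Offset (Hz) of a resonance at ``ppm`` relative to the water carrier.

        The receiver is centred on water; resonances upfield of water
        (smaller ppm) appear at positive offset with this sign convention.
        """
        return (self.water_ppm - ppm) * self.spectrometer_frequency

    def hz_to_ppm(self, hz: float) -> float:
        return self.water_ppm - hz / self.spectrometer_frequency

    def with_(self, **kwargs) -> "AcquisitionConfig":
        return replace(self, **kwargs)


def brain_config(**overrides) -> AcquisitionConfig:
    """Motor-cortex protocol: TR 2500 ms, TE 35 ms, 2 runs of 128 shots."""
    base = dict(
        region="brain",
        TR=2500.0,
        TE=35.0,
        n_shots_per_run=128,
        n_runs=2,
        water_echo_tes=(35.0, 1000.0, 50.0, 400.0, 200.0, 75.0, 100.0, 140.0),
    )
    base.update(overrides)
    return AcquisitionConfig(**base)


def cord_config(**overrides) -> AcquisitionConfig:
    """Lumbar-cord protocol: TR 2000 ms, TE 41 ms, 2 runs of 256 shots.

    A water-selective inversion nulls CSF in the cord acquisition, so cord
    ground truths normally set f_CSF = 0.
    """
    base = dict(
        region="cord",
        TR=2000.0,
        TE=41.0,
        n_shots_per_run=256,
        n_runs=2,
        water_echo_tes=(41.0, 1000.0, 50.0, 400.0, 200.0, 75.0, 100.0, 140.0),
    )
    base.update(overrides)
    return AcquisitionConfig(**base)
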