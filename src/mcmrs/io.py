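"""Plain-text interchange formats.

A transient set is stored as a JSON header (acquisition configuration,
cycling map, ground-truth digest) next to a CSV body with one row per shot
of interleaved real/imaginary samples at full double precision.  Water
echo series and spectra are JSON/CSV pairs in the same spirit; cohort
manifests and QC reports are ordinary CSV tables.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from mcmrs.config import AcquisitionConfig
from mcmrs.preproc import WaterShotFit
from mcmrs.spectrum import Spectrum
from mcmrs.synthgen import Transient, TransientSet, WaterEchoSeries

_FMT = "%.17g"


def _acq_to_dict(acq: AcquisitionConfig) -> dict:
    d = dataclasses.asdict(acq)
    d["water_echo_tes"] = list(d["water_echo_tes"])
    return d


def _acq_from_dict(d: dict) -> AcquisitionConfig:
    d = dict(d)
    d["water_echo_tes"] = tuple(d["water_echo_tes"])
    return AcquisitionConfig(**d)


def write_transient_set(ts: TransientSet, stem: str | Path) -> tuple[Path, Path]:
    """Write ``<stem>.json`` + ``<stem>.shots.csv``; returns both paths."""
    stem = Path(stem)
    header = {
        "format": "mcmrs-transients/1",
        "acquisition": _acq_to_dict(ts.acq),
        "truth_digest": ts.truth_digest,
        "shots": [
            {"shot_index": t.shot_index, "run_index": t.run_index, "cycling_state": t.cycling_state}
            for t in ts.transients
        ],
    }
    jpath = stem.with_suffix(".json")
    cpath = stem.with_suffix(".shots.csv")
    jpath.write_text(json.dumps(header, indent=1))
    mat = np.empty((len(ts), 2 * ts.acq.n_points))
    for i, t in enumerate(ts.transients):
        mat[i, 0::2] = t.samples.real
        mat[i, 1::2] = t.samples.imag
    np.savetxt(cpath, mat, fmt=_FMT, delimiter=",")
    return jpath, cpath


def read_transient_set(stem: str | Path) -> TransientSet:
    stem = Path(stem)
    header = json.loads(stem.with_suffix(".json").read_text())
    acq = _acq_from_dict(header["acquisition"])
    mat = np.loadtxt(stem.with_suffix(".shots.csv"), delimiter=",", ndmin=2)
    transients = []
    for meta, row in zip(header["shots"], mat):
        samples = row[0::2] + 1j * row[1::2]
        transients.append(
            Transient(samples, meta["cycling_state"], meta["run_index"], meta["shot_index"])
        )
    return TransientSet(transients, acq, header.get("truth_digest", ""))


def write_water_series(series: WaterEchoSeries, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "format": "mcmrs-waterseries/1",
        "TR_ms": series.TR,
        "te_ms": series.te_list.tolist(),
        "amplitudes_real": np.real(series.amplitudes).tolist(),
        "amplitudes_imag": np.imag(series.amplitudes).tolist(),
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_water_series(path: str | Path) -> WaterEchoSeries:
    d = json.loads(Path(path).read_text())
    amps = np.asarray(d["amplitudes_real"]) + 1j * np.asarray(d["amplitudes_imag"])
    return WaterEchoSeries(np.asarray(d["te_ms"]), amps, d["TR_ms"])


def write_spectrum(spectrum: Spectrum, stem: str | Path) -> tuple[Path, Path]:
    stem = Path(stem)
    jpath = stem.with_suffix(".json")
    cpath = stem.with_suffix(".spec.csv")
    jpath.write_text(
        json.dumps(
            {
                "format": "mcmrs-spectrum/1",
                "acquisition": _acq_to_dict(spectrum.acq),
                "provenance": spectrum.provenance,
            },
            indent=1,
            default=str,
        )
    )
    arr = np.column_stack([spectrum.ppm, spectrum.data.real, spectrum.data.imag])
    np.savetxt(cpath, arr, fmt=_FMT, delimiter=",", header="ppm,real,imag", comments="")
    return jpath, cpath


def read_spectrum(stem: str | Path) -> Spectrum:
    stem = Path(stem)
    header = json.loads(stem.with_suffix(".json").read_text())
    arr = np.loadtxt(stem.with_suffix(".spec.csv"), delimiter=",", skiprows=1)
    return Spectrum(
        arr[:, 1] + 1j * arr[:, 2],
        arr[:, 0],
        _acq_from_dict(header["acquisition"]),
        header.get("provenance", {}),
    )


def write_cohort_manifest(records: list, directory: str | Path) -> Path:
    """Write one subject per row: id, group, transient stem, water path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        stem = directory / f"{rec.subject_id}_transients"
        write_transient_set(rec.transients, stem)
        wpath = directory / f"{rec.subject_id}_water.json"
        write_water_series(rec.water_series, wpath)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "transients": stem.name,
                "water_series": wpath.name,
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def write_shot_qc_report(
    fits: list[WaterShotFit], kept: list[int], reasons: dict, path: str | Path
) -> Path:
    kept_set = set(kept)
    rows = [
        {
            "shot_index": f.shot_index,
            "amplitude": f.amplitude,
            "amplitude_rel_uncertainty": f.amplitude_rel_uncertainty,
            "frequency_hz": f.frequency,
            "zero_order_phase_deg": f.zero_order_phase,
            "linewidth_hz": f.linewidth,
            "linewidth_rel_uncertainty": f.linewidth_rel_uncertainty,
            "kept": f.shot_index in kept_set,
            "reason": ";".join(reasons.get(f.shot_index, [])),
        }
        for f in fits
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
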