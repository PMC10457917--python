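"""File formats and canonical fixtures.

All text formats use comma separators, '.' decimals, UTF-8 and LF newlines,
independent of locale:

* recording CSV ``time_s,z_ohm`` with a JSON sidecar carrying ``fs_hz``,
  ``excitation_frequency_hz``, ``seed`` and (for synthetic data) the full
  ground truth;
* spectrum CSV ``freq_hz,mag_ohm,phase_deg,re_ohm,im_ohm``;
* paired-measurements CSV ``id,method_a,method_b``;
* Cole model JSON ``r_e_ohm``, ``r_i_ohm``, ``c_branch_farad``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cole import ColeTissueModel, ImpedanceSpectrum, sweep_spectrum
from .errors import ParseError
from .icg_synth import (
    BioimpedanceRecording,
    IcgGroundTruth,
    SubjectProfile,
    synthesize_recording,
    truth_from_hemodynamics,
)
from .method_compare import PairedMeasurements, simulate_equivalence_study

__all__ = [
    "write_recording",
    "read_recording",
    "write_spectrum",
    "read_spectrum",
    "write_model",
    "read_model",
    "write_pairs",
    "read_pairs",
    "make_fixtures",
]

RECORDING_HEADER = ["time_s", "z_ohm"]
SPECTRUM_HEADER = ["freq_hz", "mag_ohm", "phase_deg", "re_ohm", "im_ohm"]
PAIRS_HEADER = ["id", "method_a", "method_b"]
TIME_UNIFORMITY_PPM = 1.0


def write_recording(rec: BioimpedanceRecording, path_csv, path_json) -> None:
    df = pd.DataFrame({"time_s": rec.t, "z_ohm": rec.z})
    df.to_csv(path_csv, index=False, float_format="%.17g", lineterminator="\n")
    meta = {
        "fs_hz": rec.fs,
        "excitation_frequency_hz": rec.excitation_frequency,
        **rec.metadata,
    }
    Path(path_json).write_text(json.dumps(meta, indent=2) + "\n", encoding="utf-8")


def read_recording(path_csv, path_json) -> BioimpedanceRecording:
    """Load and validate a recording; the time grid must be uniform to 1 ppm."""
    try:
        df = pd.read_csv(path_csv, float_precision="round_trip")
    except Exception as e:  # noqa: BLE001 - surfaced as a parse error
        raise ParseError(f"{path_csv}: {e}") from e
    if list(df.columns) != RECORDING_HEADER:
        raise ParseError(f"{path_csv}: header must be {','.join(RECORDING_HEADER)}, got {','.join(df.columns)}")
    bad = df.index[df.isna().any(axis=1)]
    if len(bad):
        raise ParseError(f"{path_csv}: NaN value at data row {int(bad[0]) + 1}")
    t = df["time_s"].to_numpy(float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 2
        raise ParseError(f"{path_csv}: non-monotone time at data row {row}")
    if (dt.max() - dt.min()) > TIME_UNIFORMITY_PPM * 1e-6 * dt.mean():
        raise ParseError(f"{path_csv}: non-uniform sampling (time-grid jitter above 1 ppm)")
    meta = json.loads(Path(path_json).read_text(encoding="utf-8"))
    fs = float(meta.pop("fs_hz"))
    f_exc = float(meta.pop("excitation_frequency_hz"))
    return BioimpedanceRecording(
        t=t, z=df["z_ohm"].to_numpy(float), fs=fs, excitation_frequency=f_exc, metadata=meta
    )


def write_spectrum(spec: ImpedanceSpectrum, path) -> None:
    z = spec.z
    df = pd.DataFrame(
        {
            "freq_hz": spec.frequencies,
            "mag_ohm": np.abs(z),
            "phase_deg": np.abs(np.angle(z, deg=True)),
            "re_ohm": z.real,
            "im_ohm": z.imag,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def read_spectrum(path) -> ImpedanceSpectrum:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as e:  # noqa: BLE001
        raise ParseError(f"{path}: {e}") from e
    cols = list(df.columns)
    if cols[:3] != SPECTRUM_HEADER[:3]:
        raise ParseError(f"{path}: header must start with {','.join(SPECTRUM_HEADER[:3])}")
    if df.isna().any().any():
        row = int(df.index[df.isna().any(axis=1)][0]) + 1
        raise ParseError(f"{path}: NaN value at data row {row}")
    if {"re_ohm", "im_ohm"}.issubset(cols):
        z = df["re_ohm"].to_numpy(float) + 1j * df["im_ohm"].to_numpy(float)
    else:
        # capacitive convention: reported positive phase means Im <= 0
        z = df["mag_ohm"].to_numpy(float) * np.exp(-1j * np.radians(df["phase_deg"].to_numpy(float)))
    return ImpedanceSpectrum.from_arrays(df["freq_hz"].to_numpy(float), z)


def write_model(model: ColeTissueModel, path) -> None:
    Path(path).write_text(
        json.dumps({"r_e_ohm": model.r_e, "r_i_ohm": model.r_i, "c_branch_farad": model.c}, indent=2)
        + "\n",
        encoding="utf-8",
    )


def read_model(path) -> ColeTissueModel:
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    try:
        return ColeTissueModel(r_e=d["r_e_ohm"], r_i=d["r_i_ohm"], c=d["c_branch_farad"])
    except KeyError as e:
        raise ParseError(f"{path}: missing key {e}") from e


def write_pairs(pairs: PairedMeasurements, path) -> None:
    labels = pairs.labels or [f"S{k + 1:03d}" for k in range(len(pairs))]
    df = pd.DataFrame({"id": labels, "method_a": pairs.method_a, "method_b": pairs.method_b})
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def read_pairs(path) -> PairedMeasurements:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as e:  # noqa: BLE001
        raise ParseError(f"{path}: {e}") from e
    if list(df.columns) != PAIRS_HEADER:
        raise ParseError(f"{path}: header must be {','.join(PAIRS_HEADER)}")
    if df.isna().any().any():
        row = int(df.index[df.isna().any(axis=1)][0]) + 1
        raise ParseError(f"{path}: NaN value at data row {row}")
    return PairedMeasurements.from_arrays(
        df["method_a"].to_numpy(float), df["method_b"].to_numpy(float), labels=df["id"].astype(str)
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Write the canonical test fixtures and a manifest with file hashes.

    Emits: the reference whole-body 2R1C sweep (681/909/3.3 nF over
    4 kHz - 1 MHz), a 60 s synthetic thoracic recording with ground-truth
    sidecar, a 33-pair synthetic equivalence study, and a demodulator
    operating-point table.  Fully seeded; identical inputs give identical
    files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    model = ColeTissueModel(r_e=681.0, r_i=909.0, c=3.3e-9)
    spec = sweep_spectrum(model, 4e3, 1e6, n_points=50, grid="log")
    write_spectrum(spec, out / "cole_sweep.csv")
    write_model(model, out / "cole_model.json")
    files += [out / "cole_sweep.csv", out / "cole_model.json"]

    subject = SubjectProfile(height=171.0)
    truth = truth_from_hemodynamics(subject, z0=30.0, sv_target=52.9, hr=76.5, t_lve=0.3, n_beats=75)
    rec = synthesize_recording(truth, fs=1000.0, respiration=(1.0, 0.25), noise_sd=0.05, seed=seed)
    write_recording(rec, out / "icg_recording.csv", out / "icg_recording.json")
    files += [out / "icg_recording.csv", out / "icg_recording.json"]

    pairs = simulate_equivalence_study(n_subjects=33, seed=seed)
    write_pairs(pairs, out / "sv_pairs.csv")
    files.append(out / "sv_pairs.csv")

    from .demod import DemodulatorConfig, ExcitationConfig, demodulate_behavioral
    from .cole import ImpedanceSample

    cfg = DemodulatorConfig()
    exc = ExcitationConfig(amplitude=120e-6, frequency=100e3)
    rows = []
    for mag in np.geomspace(50.0, 1200.0, 8):
        for ph in (5.0, 20.0, 45.0, 70.0):
            zx = ImpedanceSample.from_complex(exc.frequency, mag * np.exp(-1j * np.radians(ph)))
            r = demodulate_behavioral(zx, exc, cfg, noise_seed=seed)
            rows.append({"true_mag_ohm": mag, "true_phase_deg": ph, **r.to_dict()})
    pd.DataFrame(rows).to_csv(out / "demod_sweep.csv", index=False, float_format="%.17g", lineterminator="\n")
    files.append(out / "demod_sweep.csv")

    manifest = {
        "seed": seed,
        "files": {f.name: _sha256(f) for f in sorted(files)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return manifest
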