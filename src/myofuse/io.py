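"""Readers and writers for the pipeline's on-disk artifacts.

Kinematics, EMG and feature streams travel as CSV with a ``time_s`` column;
ultrasound sequences as 8-bit multi-page TIFF with a JSON sidecar carrying
frame rate and pixel spacing; heel strikes, latent truth and manifests as
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .emg import EMGRecording
from .smg import SMGFeatureStream, UltrasoundSequence

__all__ = [
    "write_trial",
    "read_emg_csv",
    "write_emg_csv",
    "read_kinematics_csv",
    "read_ultrasound",
    "write_ultrasound",
    "read_heel_strikes",
    "write_feature_csv",
    "read_smg_feature_csv",
]


def write_emg_csv(rec: EMGRecording, path) -> None:
    rec.to_frame().to_csv(path, index=False)


def read_emg_csv(path, sample_rate_hz: float = None) -> EMGRecording:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if sample_rate_hz is None:
        sample_rate_hz = 1.0 / float(np.median(np.diff(t)))
    channels = [c for c in df.columns if c != "time_s"]
    return EMGRecording(
        df[channels].to_numpy(), sample_rate_hz, tuple(channels), t0=float(t[0])
    )


def read_kinematics_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ultrasound(seq: UltrasoundSequence, tiff_path, meta_path) -> None:
    """8-bit grayscale multi-page TIFF plus a JSON metadata sidecar."""
    frames = np.clip(np.rint(seq.frames), 0, 255).astype(np.uint8)
    tifffile.imwrite(tiff_path, frames)
    meta = {
        "frame_rate_hz": seq.frame_rate_hz,
        "pixel_spacing_mm": list(seq.pixel_spacing_mm),
        "t0": seq.t0,
        "n_frames": int(seq.n_frames),
    }
    Path(meta_path).write_text(json.dumps(meta, indent=1))


def read_ultrasound(tiff_path, meta_path) -> UltrasoundSequence:
    frames = tifffile.imread(tiff_path)
    meta = json.loads(Path(meta_path).read_text())
    return UltrasoundSequence(
        frames.astype(float),
        meta["frame_rate_hz"],
        tuple(meta["pixel_spacing_mm"]),
        t0=meta.get("t0", 0.0),
    )


def read_heel_strikes(path) -> np.ndarray:
    return np.asarray(json.loads(Path(path).read_text()), dtype=float)


def write_feature_csv(stream, path, sidecar_path=None) -> None:
    """Feature stream to CSV; SMG streams also record grid_shape in JSON."""
    stream.to_frame().to_csv(path, index=False)
    if sidecar_path is not None and isinstance(stream, SMGFeatureStream):
        Path(sidecar_path).write_text(
            json.dumps({"grid_shape": list(stream.grid_shape)})
        )


def read_smg_feature_csv(path, sidecar_path) -> SMGFeatureStream:
    df = pd.read_csv(path)
    grid = tuple(json.loads(Path(sidecar_path).read_text())["grid_shape"])
    cols = [c for c in df.columns if c != "time_s"]
    return SMGFeatureStream(
        df["time_s"].to_numpy(), df[cols].to_numpy(), grid, cols
    )


def write_trial(trial, out_dir) -> dict:
    """Write one synthetic trial's artifact bundle; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trial.kinematics.to_csv(out / "kinematics.csv", index=False)
    write_emg_csv(trial.emg, out / "emg.csv")
    write_ultrasound(trial.ultrasound, out / "ultrasound.tif", out / "ultrasound.json")
    (out / "heel_strikes.json").write_text(
        json.dumps([float(t) for t in trial.heel_strikes])
    )
    trial.latent.to_csv(out / "latent_activations.csv", index=False)
    manifest = {
        "task": trial.task,
        "seed": trial.seed,
        "n_strides": trial.n_strides,
        "files": {
            "kinematics": "kinematics.csv",
            "emg": "emg.csv",
            "ultrasound": "ultrasound.tif",
            "ultrasound_meta": "ultrasound.json",
            "heel_strikes": "heel_strikes.json",
            "latent": "latent_activations.csv",
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
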