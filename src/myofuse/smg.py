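"""Sonomyography (B-mode ultrasound) intensity feature extraction.

A grayscale frame is tiled into non-overlapping 3 x 3 mm blocks anchored at
the superficial-left corner; the per-block mean intensity grid is flattened
row-major (superficial rows first) and complemented by a temporal feature:
the frame-to-frame time derivative of each block mean.  Mean and temporal
halves are concatenated per frame, so a 20 x 13 block grid yields the
520-feature sonomyography vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "UltrasoundSequence",
    "SMGFeatureStream",
    "block_mean_intensity",
    "flatten_blocks",
    "temporal_intensity",
    "extract_smg_features",
]


@dataclass
class UltrasoundSequence:
    """Ordered grayscale frames with physical pixel spacing.

    frames : ndarray, shape (n_frames, n_axial, n_lateral)
        Intensities in [0, 255]; axial rows run superficial to deep.
    frame_rate_hz : float
    pixel_spacing_mm : (axial, lateral) in mm/pixel.
    t0 : float
        Time of the first frame, seconds.
    """

    frames: np.ndarray
    frame_rate_hz: float
    pixel_spacing_mm: tuple
    t0: float = 0.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be 3-D (frame, axial, lateral)")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        ax, lat = self.pixel_spacing_mm
        if ax <= 0 or lat <= 0:
            raise ValueError("pixel spacing must be positive")
        if self.frames.min() < 0 or self.frames.max() > 255:
            raise ValueError("frame intensities must lie in [0, 255]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.frame_rate_hz

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass
class SMGFeatureStream:
    """Per-frame block features: [mean intensities | temporal intensities]."""

    timestamps: np.ndarray
    values: np.ndarray
    grid_shape: tuple
    columns: list

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        n_blocks = self.grid_shape[0] * self.grid_shape[1]
        if self.values.shape[1] != 2 * n_blocks:
            raise ValueError("columns must equal 2 x n_blocks")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")

    @property
    def n_blocks(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        df.insert(0, "time_s", self.timestamps)
        return df


def _block_pixels(pixel_spacing_mm, block_mm: float) -> tuple:
    ax, lat = pixel_spacing_mm
    bpx_ax = int(round(block_mm / ax))
    bpx_lat = int(round(block_mm / lat))
    if bpx_ax < 1 or bpx_lat < 1:
        raise ValueError("block smaller than one pixel")
    return bpx_ax, bpx_lat


def block_mean_intensity(
    frame: np.ndarray, pixel_spacing_mm, block_mm: float = 3.0
) -> np.ndarray:
    """Mean intensity of each non-overlapping block_mm x block_mm block.

    The grid is anchored at the superficial-left corner; trailing partial
    blocks at the deep and right edges are discarded.
    """
    frame = np.asarray(frame, dtype=float)
    bpx_ax, bpx_lat = _block_pixels(pixel_spacing_mm, block_mm)
    n_ax = frame.shape[0] // bpx_ax
    n_lat = frame.shape[1] // bpx_lat
    if n_ax < 1 or n_lat < 1:
        raise ValueError("frame smaller than one block")
    cropped = frame[: n_ax * bpx_ax, : n_lat * bpx_lat]
    return cropped.reshape(n_ax, bpx_ax, n_lat, bpx_lat).mean(axis=(1, 3))


def flatten_blocks(grid: np.ndarray) -> np.ndarray:
    """Row-major flatten, first row = most superficial blocks."""
    grid = np.asarray(grid)
    if grid.size == 0:
        raise ValueError("empty grid")
    return grid.reshape(-1)


def temporal_intensity(
    features_t: np.ndarray, features_prev: np.ndarray, frame_interval_s: float
) -> np.ndarray:
    """Time derivative of a feature vector between consecutive frames."""
    a = np.asarray(features_t, dtype=float)
    b = np.asarray(features_prev, dtype=float)
    if a.shape != b.shape:
        raise ValueError("feature vector length mismatch")
    if frame_interval_s <= 0:
        raise ValueError("frame interval must be positive")
    return (a - b) / frame_interval_s


def extract_smg_features(
    seq: UltrasoundSequence, block_mm: float = 3.0
) -> SMGFeatureStream:
    """Per-frame sonomyography features: block means then their derivatives.

    The first frame has no predecessor; its temporal half is zero so the
    stream stays frame-aligned with the input sequence.
    """
    if seq.n_frames < 2:
        raise ValueError("need at least 2 frames for temporal features")
    means = np.stack(
        [
            flatten_blocks(
                block_mean_intensity(f, seq.pixel_spacing_mm, block_mm)
            )
            for f in seq.frames
        ]
    )
    grid = block_mean_intensity(
        seq.frames[0], seq.pixel_spacing_mm, block_mm
    ).shape
    dt = 1.0 / seq.frame_rate_hz
    temporal = np.zeros_like(means)
    temporal[1:] = (means[1:] - means[:-1]) / dt
    values = np.hstack([means, temporal])
    columns = [f"MI_{k}" for k in range(means.shape[1])] + [
        f"TI_{k}" for k in range(means.shape[1])
    ]
    return SMGFeatureStream(seq.times, values, grid, columns)
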