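"""Stream alignment, stride segmentation, and pooled dataset construction.

The common clock is the 20 Hz EMG feature clock restricted to the temporal
overlap of all three streams: sonomyography features are mapped to each
clock tick by nearest frame time (ties resolved to the earlier frame) and
kinematic targets are linearly interpolated.  Heel-strike events then carve
the aligned rows into strides, the unit of cross-validation, and per-task
datasets are pooled into a single task-invariant table per sensing modality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .emg import EMGFeatureStream
from .smg import SMGFeatureStream

__all__ = [
    "TARGET_NAMES",
    "MODALITIES",
    "AlignmentError",
    "AlignedDataset",
    "Stride",
    "StrideSet",
    "PooledDataset",
    "align_streams",
    "segment_strides",
    "build_pooled",
]

logger = logging.getLogger(__name__)

TARGET_NAMES = (
    "hip_angle",
    "knee_angle",
    "ankle_angle",
    "hip_velocity",
    "knee_velocity",
    "ankle_velocity",
)

MODALITIES = ("emg", "smg", "fusion")


class AlignmentError(ValueError):
    """Streams share no temporal overlap."""


@dataclass
class AlignedDataset:
    """Feature matrices and kinematic targets on the common 20 Hz clock."""

    timestamps: np.ndarray
    X_emg: np.ndarray
    X_smg: np.ndarray
    Y: np.ndarray
    task: str
    emg_columns: list
    smg_columns: list

    def __post_init__(self):
        n = len(self.timestamps)
        for mat in (self.X_emg, self.X_smg, self.Y):
            if mat.shape[0] != n:
                raise ValueError("row counts differ across aligned matrices")
        if not (
            np.all(np.isfinite(self.X_emg))
            and np.all(np.isfinite(self.X_smg))
            and np.all(np.isfinite(self.Y))
        ):
            raise ValueError("non-finite values after alignment")

    @property
    def X_fusion(self) -> np.ndarray:
        """Sensor fusion = SMG features then EMG features, per row."""
        return np.hstack([self.X_smg, self.X_emg])

    def features(self, modality: str) -> np.ndarray:
        if modality == "emg":
            return self.X_emg
        if modality == "smg":
            return self.X_smg
        if modality == "fusion":
            return self.X_fusion
        raise ValueError(f"unknown modality {modality!r}; expected {MODALITIES}")

    @property
    def n_rows(self) -> int:
        return len(self.timestamps)


@dataclass(frozen=True)
class Stride:
    """One stride: a contiguous row range [start, stop) on a common clock."""

    task: str
    index: int
    start: int
    stop: int

    @property
    def n_rows(self) -> int:
        return self.stop - self.start

    def rows(self) -> np.ndarray:
        return np.arange(self.start, self.stop)


@dataclass
class StrideSet:
    """Ordered, disjoint strides over an aligned dataset."""

    strides: list

    def __post_init__(self):
        prev_stop = None
        for s in self.strides:
            if s.stop <= s.start:
                raise ValueError("empty stride range")
            if prev_stop is not None and s.start < prev_stop:
                raise ValueError("stride ranges overlap or are unordered")
            prev_stop = s.stop

    def __len__(self) -> int:
        return len(self.strides)

    def __iter__(self):
        return iter(self.strides)


def _nearest_frame_indices(clock: np.ndarray, frame_times: np.ndarray):
    """Nearest frame per clock tick; ties go to the earlier frame."""
    pos = np.searchsorted(frame_times, clock)
    pos = np.clip(pos, 1, len(frame_times) - 1)
    left, right = frame_times[pos - 1], frame_times[pos]
    # strictly closer right wins; equality keeps the earlier (left) frame
    take_right = (right - clock) < (clock - left)
    return np.where(take_right, pos, pos - 1)


def align_streams(
    emg_feats: EMGFeatureStream,
    smg_feats: SMGFeatureStream,
    kinematics,
    task: str = "",
) -> AlignedDataset:
    """Align the three streams on the EMG feature clock.

    ``kinematics`` is a DataFrame with a ``time_s`` column and the six
    target columns; it is linearly interpolated to each clock tick.
    """
    t_kin = np.asarray(kinematics["time_s"], dtype=float)
    start = max(emg_feats.timestamps[0], smg_feats.timestamps[0], t_kin[0])
    stop = min(emg_feats.timestamps[-1], smg_feats.timestamps[-1], t_kin[-1])
    mask = (emg_feats.timestamps >= start - 1e-12) & (
        emg_feats.timestamps <= stop + 1e-12
    )
    if not np.any(mask):
        raise AlignmentError("streams share no temporal overlap")
    clock = emg_feats.timestamps[mask]

    idx = _nearest_frame_indices(clock, smg_feats.timestamps)
    X_smg = smg_feats.values[idx]

    Y = np.column_stack(
        [
            np.interp(clock, t_kin, np.asarray(kinematics[c], dtype=float))
            for c in TARGET_NAMES
        ]
    )
    return AlignedDataset(
        timestamps=clock,
        X_emg=emg_feats.values[mask],
        X_smg=X_smg,
        Y=Y,
        task=task,
        emg_columns=list(emg_feats.columns),
        smg_columns=list(smg_feats.columns),
    )


def segment_strides(
    ds: AlignedDataset, heel_strikes, min_rows: int = 4
) -> StrideSet:
    """Carve aligned rows into strides delimited by consecutive heel strikes.

    Stride i covers clock ticks t in [hs_i, hs_{i+1}); intervals yielding
    fewer than ``min_rows`` rows are discarded with a warning.
    """
    hs = np.asarray(heel_strikes, dtype=float)
    if len(hs) < 2:
        raise ValueError("need at least 2 heel strikes to form a stride")
    strides = []
    for i in range(len(hs) - 1):
        start = int(np.searchsorted(ds.timestamps, hs[i], side="left"))
        stop = int(np.searchsorted(ds.timestamps, hs[i + 1], side="left"))
        if stop - start < min_rows:
            logger.warning(
                "discarding stride %d of task %s with %d < %d rows",
                i, ds.task, stop - start, min_rows,
            )
            continue
        strides.append(Stride(ds.task, i, start, stop))
    return StrideSet(strides)


@dataclass
class PooledDataset:
    """Task-invariant pooled feature/target table with stride labels.

    Standardization statistics are *not* computed here: they are a
    fitting-time contract, derived from training-fold rows only inside the
    regression fit.
    """

    X: np.ndarray
    Y: np.ndarray
    strides: list  # Stride objects re-indexed onto pooled rows
    modality: str
    feature_names: list
    target_names: tuple = TARGET_NAMES

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def stride_rows(self, stride_ids) -> np.ndarray:
        """Row indices of the given strides (by position in ``strides``)."""
        return np.concatenate(
            [self.strides[k].rows() for k in stride_ids]
        )

    def tasks(self) -> list:
        seen = []
        for s in self.strides:
            if s.task not in seen:
                seen.append(s.task)
        return seen


def build_pooled(per_task, modality: str) -> PooledDataset:
    """Pool stride rows from all tasks into one table for one modality.

    ``per_task`` maps task -> (AlignedDataset, StrideSet).  Only rows that
    belong to a stride are kept; stride row ranges are re-indexed onto the
    pooled table.
    """
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}; expected {MODALITIES}")
    X_parts, Y_parts, strides = [], [], []
    feature_names = None
    offset = 0
    for task, (ds, stride_set) in per_task.items():
        if len(stride_set) == 0:
            raise ValueError(f"task {task} has no usable strides")
        Xm = ds.features(modality)
        if feature_names is None:
            if modality == "emg":
                feature_names = list(ds.emg_columns)
            elif modality == "smg":
                feature_names = list(ds.smg_columns)
            else:
                feature_names = list(ds.smg_columns) + list(ds.emg_columns)
        for s in stride_set:
            X_parts.append(Xm[s.start : s.stop])
            Y_parts.append(ds.Y[s.start : s.stop])
            strides.append(
                Stride(task, s.index, offset, offset + s.n_rows)
            )
            offset += s.n_rows
    return PooledDataset(
        X=np.vstack(X_parts),
        Y=np.vstack(Y_parts),
        strides=strides,
        modality=modality,
        feature_names=feature_names,
    )
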