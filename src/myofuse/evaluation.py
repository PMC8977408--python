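"""Leave-one-stride-out cross-validation, error metrics and statistics.

Evaluation mirrors a task-invariant protocol: strides from every ambulation
task are pooled; fold i holds out the i-th stride of every task that has at
least i+1 strides, so each stride is the test stride exactly once.  Per-task
root-mean-square error (RMSE), range-normalized RMSE and an adjusted R^2 for
nonlinear regression,

    adj R^2 = 1 - (N - 1) / (N - 1 - p) * (1 - R^2),
    R^2 = 1 - SS_res / SS_tot,

are computed per target and modality (N = training rows, p = number of
feature columns).  Sensing modalities are compared by one-way ANOVA with
Tukey-Kramer pairwise follow-ups on per-replicate overall RMSE values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from . import emg as emg_mod
from . import smg as smg_mod
from .fusion import (
    MODALITIES,
    TARGET_NAMES,
    align_streams,
    build_pooled,
    segment_strides,
)
from .gpr import OptConfig, fit_gpr, predict_mean

__all__ = [
    "Fold",
    "EvalConfig",
    "EvaluationReport",
    "loso_folds",
    "rmse",
    "nrmse",
    "adjusted_r2",
    "compare_modalities",
    "prepare_task",
    "run_experiment",
]


# ---------------------------------------------------------------------------
# folds


@dataclass(frozen=True)
class Fold:
    """Stride indices (positions in the pooled stride list) per fold."""

    index: int
    test_strides: tuple
    train_strides: tuple


def loso_folds(strides) -> list:
    """Leave-one-stride-out folds over a pooled, task-labelled stride list.

    Fold i tests the i-th stride of every task having at least i+1 strides;
    the number of folds is the largest per-task stride count.  Every stride
    is a test stride in exactly one fold.
    """
    strides = list(strides)
    per_task = {}
    for pos, s in enumerate(strides):
        per_task.setdefault(s.task, []).append(pos)
    for task, positions in per_task.items():
        if len(positions) < 2:
            raise ValueError(
                f"task {task} has {len(positions)} stride(s); need >= 2"
            )
    n_folds = max(len(v) for v in per_task.values())
    folds = []
    all_pos = set(range(len(strides)))
    for i in range(n_folds):
        test = tuple(
            positions[i]
            for positions in per_task.values()
            if len(positions) > i
        )
        train = tuple(sorted(all_pos.difference(test)))
        folds.append(Fold(i, test, train))
    return folds


# ---------------------------------------------------------------------------
# metrics


def rmse(y_true, y_pred) -> float:
    """Root-mean-square error."""
    a = np.asarray(y_true, dtype=float)
    b = np.asarray(y_pred, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("series must be non-empty and equal length")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def nrmse(rmse_val: float, y_true) -> float:
    """RMSE as a percentage of the measured signal's range."""
    a = np.asarray(y_true, dtype=float)
    rng = float(a.max() - a.min())
    if rng <= 0:
        raise ValueError("measured series has zero range")
    return 100.0 * rmse_val / rng


def adjusted_r2(y_true, y_pred, N: int, p: int) -> float:
    """Adjusted coefficient of determination for nonlinear regression."""
    if N - 1 - p <= 0:
        raise ValueError(f"N - 1 - p must be positive (N={N}, p={p})")
    a = np.asarray(y_true, dtype=float)
    b = np.asarray(y_pred, dtype=float)
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("y_true is constant")
    r2 = 1.0 - float(np.sum((a - b) ** 2)) / ss_tot
    return 1.0 - (N - 1) / (N - 1 - p) * (1.0 - r2)


# ---------------------------------------------------------------------------
# modality comparison


@dataclass
class ModalityComparison:
    """One-way ANOVA across modality groups with Tukey-Kramer follow-up."""

    F: float
    p: float
    alpha: float
    groups: list
    pairwise: list  # (group_a, group_b, mean_diff, p_adj, significant)

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def compare_modalities(per_group: dict, alpha: float = 0.05) -> ModalityComparison:
    """Compare RMSE observations across sensing modalities.

    ``per_group`` maps modality name -> 1-D array of RMSE observations
    (one per replicate/subject).  Pairwise Tukey-Kramer tests (the
    unequal-n form) run only when the group effect is significant.
    """
    groups = list(per_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 modality groups")
    arrays = [np.asarray(per_group[g], dtype=float) for g in groups]
    for g, a in zip(groups, arrays):
        if a.size < 2:
            raise ValueError(f"group {g} has fewer than 2 observations")
    flat = np.concatenate(arrays)
    if np.ptp(flat) == 0.0:
        return ModalityComparison(0.0, 1.0, alpha, groups, [])
    F, p = stats.f_oneway(*arrays)
    pairwise = []
    if p < alpha:
        labels = np.concatenate(
            [np.repeat(g, a.size) for g, a in zip(groups, arrays)]
        )
        tk = pairwise_tukeyhsd(flat, labels, alpha=alpha)
        summary = tk.summary().data[1:]
        for row in summary:
            pairwise.append(
                (
                    str(row[0]),
                    str(row[1]),
                    float(row[2]),
                    float(row[3]),
                    bool(row[-1]),
                )
            )
    return ModalityComparison(float(F), float(p), alpha, groups, pairwise)


# ---------------------------------------------------------------------------
# experiment orchestration


@dataclass(frozen=True)
class EvalConfig:
    """Experiment settings: modalities, targets and optimizer behaviour."""

    modalities: tuple = ("emg", "smg", "fusion")
    targets: tuple = TARGET_NAMES
    opt: OptConfig = OptConfig()
    seed: int = 0

    def __post_init__(self):
        for m in self.modalities:
            if m not in MODALITIES:
                raise ValueError(f"unknown modality {m!r}")
        for t in self.targets:
            if t not in TARGET_NAMES:
                raise ValueError(f"unknown target {t!r}")


@dataclass
class EvaluationReport:
    """Metrics table plus fold structure and the leakage audit trail."""

    metrics: pd.DataFrame
    folds: dict  # modality -> list[Fold]
    audit: dict
    predictions: dict  # (modality, target) -> per-row predicted values
    y_true: dict  # target -> measured values on pooled rows
    stride_tasks: list

    def cell(self, modality: str, target: str, task: str = "overall"):
        m = self.metrics
        row = m[
            (m.modality == modality) & (m.target == target) & (m.task == task)
        ]
        if row.empty:
            raise KeyError((modality, target, task))
        return row.iloc[0]


def prepare_task(trial, window_s=0.200, step_s=0.050, block_mm=3.0):
    """Trial -> (AlignedDataset, StrideSet): the shared feature front-end."""
    rec = emg_mod.preprocess_emg(trial.emg)
    emg_feats = emg_mod.extract_emg_features(rec, window_s, step_s)
    smg_feats = smg_mod.extract_smg_features(trial.ultrasound, block_mm)
    ds = align_streams(emg_feats, smg_feats, trial.kinematics, task=trial.task)
    stride_set = segment_strides(ds, trial.heel_strikes)
    return ds, stride_set


def _audit_fold(pooled, fold, model, X_train_rows):
    """Leakage checks: disjoint folds and train-only standardization."""
    train_rows = pooled.stride_rows(fold.train_strides)
    test_rows = pooled.stride_rows(fold.test_strides)
    disjoint = len(np.intersect1d(train_rows, test_rows)) == 0
    mu_ok = np.allclose(model.x_mean, X_train_rows.mean(axis=0))
    n_ok = model.n_train_total == len(train_rows)
    return bool(disjoint and mu_ok and n_ok)


def run_experiment(trials: dict, cfg: EvalConfig = EvalConfig()) -> EvaluationReport:
    """Full task-invariant evaluation over one synthetic (or real) dataset.

    For every requested modality and kinematic target, fits one GP per
    leave-one-stride-out fold on the training strides only and predicts the
    held-out strides; accumulates per-task and overall metrics.  The overall
    row of each metric is the unweighted mean of the per-task values.
    """
    per_task = {task: prepare_task(trial) for task, trial in trials.items()}

    records = []
    folds_by_modality = {}
    predictions = {}
    y_true_by_target = {}
    audit = {"folds_checked": 0, "leakage_free": True, "each_stride_tested_once": True}
    stride_tasks = None

    for modality in cfg.modalities:
        pooled = build_pooled(per_task, modality)
        folds = loso_folds(pooled.strides)
        folds_by_modality[modality] = folds
        stride_tasks = [s.task for s in pooled.strides]

        tested = np.zeros(len(pooled.strides), dtype=int)
        for f in folds:
            for s in f.test_strides:
                tested[s] += 1
        if not np.all(tested == 1):
            audit["each_stride_tested_once"] = False

        p_features = pooled.n_features
        n_train_sizes = []
        for ti, target in enumerate(cfg.targets):
            t_col = TARGET_NAMES.index(target)
            y_all = pooled.Y[:, t_col]
            y_true_by_target[target] = y_all
            pred = np.full(pooled.n_rows, np.nan)
            for f in folds:
                train_rows = pooled.stride_rows(f.train_strides)
                test_rows = pooled.stride_rows(f.test_strides)
                opt = replace(
                    cfg.opt, seed=(cfg.seed * 1009 + f.index * 31 + ti) & 0x7FFFFFFF
                )
                model = fit_gpr(pooled.X[train_rows], y_all[train_rows], opt)
                pred[test_rows] = predict_mean(model, pooled.X[test_rows])
                if not _audit_fold(pooled, f, model, pooled.X[train_rows]):
                    audit["leakage_free"] = False
                audit["folds_checked"] += 1
                n_train_sizes.append(len(train_rows))
            if np.any(np.isnan(pred)):
                raise RuntimeError("some pooled rows were never predicted")
            predictions[(modality, target)] = pred

            N_eq = int(round(float(np.mean(n_train_sizes))))
            task_vals = {"rmse": [], "nrmse": [], "adj_r2": []}
            for task in pooled.tasks():
                rows = np.concatenate(
                    [s.rows() for s in pooled.strides if s.task == task]
                )
                r = rmse(y_all[rows], pred[rows])
                nr = nrmse(r, y_all[rows])
                try:
                    ar2 = adjusted_r2(y_all[rows], pred[rows], N_eq, p_features)
                except ValueError:
                    ar2 = np.nan
                task_vals["rmse"].append(r)
                task_vals["nrmse"].append(nr)
                task_vals["adj_r2"].append(ar2)
                records.append(
                    dict(
                        modality=modality,
                        target=target,
                        task=task,
                        rmse=r,
                        nrmse=nr,
                        adj_r2=ar2,
                        n_train=N_eq,
                        p=p_features,
                        n_test_strides=sum(
                            1 for s in pooled.strides if s.task == task
                        ),
                    )
                )
            records.append(
                dict(
                    modality=modality,
                    target=target,
                    task="overall",
                    rmse=float(np.mean(task_vals["rmse"])),
                    nrmse=float(np.mean(task_vals["nrmse"])),
                    adj_r2=float(np.mean(task_vals["adj_r2"])),
                    n_train=N_eq,
                    p=p_features,
                    n_test_strides=len(pooled.strides),
                )
            )

    return EvaluationReport(
        metrics=pd.DataFrame.from_records(records),
        folds=folds_by_modality,
        audit=audit,
        predictions=predictions,
        y_true=y_true_by_target,
        stride_tasks=stride_tasks,
    )
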