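"""Align EMG features, sonomyography features and kinematics; segment strides.

All streams are mapped onto the 20 Hz EMG feature clock (nearest ultrasound
frame, linearly interpolated kinematics), split into strides at heel
strikes, and pooled across tasks into task-invariant feature/target tables
for each sensing modality.
"""

import myofuse as mf
from myofuse.evaluation import prepare_task
from myofuse.fusion import build_pooled

trials = mf.generate_dataset(mf.DatasetConfig().scaled(3, 2), rng_seed=4)
per_task = {task: prepare_task(trial) for task, trial in trials.items()}

for modality in ("emg", "smg", "fusion"):
    pooled = build_pooled(per_task, modality)
    print(
        f"{modality:7s} rows={pooled.n_rows:4d}  features={pooled.n_features:4d}  "
        f"strides={len(pooled.strides)}"
    )

# Fusion concatenates the 520 sonomyography columns with the 48 EMG columns
# (568 total). Row counts match across modalities because the same aligned
# clock and stride segmentation underlie all three tables.
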