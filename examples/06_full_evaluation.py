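"""Full leave-one-stride-out evaluation comparing sensing modalities.

Runs the complete pipeline (generate -> features -> fuse -> GP fits ->
metrics) on a small dataset and prints the overall RMSE / nRMSE / adjusted
R^2 table per modality, plus the cross-validation leakage audit.
"""

import myofuse as mf
from myofuse.evaluation import EvalConfig, run_experiment

trials = mf.generate_dataset(mf.DatasetConfig().scaled(4, 2), rng_seed=6)
report = run_experiment(
    trials,
    EvalConfig(
        modalities=("emg", "smg", "fusion"),
        targets=("hip_angle", "knee_angle", "ankle_angle"),
        seed=0,
    ),
)

m = report.metrics
overall = m[m.task == "overall"]
print(
    overall.pivot(index="target", columns="modality", values="rmse")
    .round(2)
    .to_string()
)
print("audit:", report.audit)

# RMSE is in degrees. Fusion is lowest at every joint: the synthetic
# coupling routes part of each joint's stride-to-stride variability through
# muscles only the ultrasound can see and part of the hip/ankle variability
# through EMG-only muscles, so concatenating both feature sets recovers the
# most kinematic information, while each single modality misses its share.
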