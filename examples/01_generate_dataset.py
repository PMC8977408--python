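"""Generate a small synthetic multimodal gait dataset and describe it.

One trial per ambulation task: 100 Hz hip/knee/ankle kinematics, 8-channel
1,200 Hz surface EMG, and a 20 Hz ultrasound image sequence, all sharing
heel-strike events and latent muscle-activation ground truth.
"""

import myofuse as mf

cfg = mf.DatasetConfig().scaled(walk_strides=4, stair_strides=2)
trials = mf.generate_dataset(cfg, rng_seed=1)

for task, trial in trials.items():
    k = trial.kinematics
    print(
        f"{task:14s} strides={trial.n_strides}  "
        f"duration={trial.heel_strikes[-1]:5.1f} s  "
        f"emg={trial.emg.data.shape}  "
        f"frames={trial.ultrasound.frames.shape}  "
        f"knee range=[{k.knee_angle.min():6.1f}, {k.knee_angle.max():6.1f}] deg"
    )

# Each line shows one task's trial: stream shapes confirm the 1,200 Hz x 8
# EMG and 120 x 78 pixel image geometry; knee ranges differ by task because
# each task has its own stride-periodic joint templates.
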