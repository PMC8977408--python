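"""Extract sonomyography features from an ultrasound image sequence.

Each frame is tiled into 3 x 3 mm blocks (20 axial x 13 lateral under the
default 60 x 39 mm field of view at 0.5 mm/pixel); per-block mean intensity
plus its frame-to-frame time derivative give 520 features per frame.
"""

import myofuse as mf
from myofuse.smg import extract_smg_features

trial = mf.generate_trial(mf.make_template("stair_ascent", 1), n_strides=3, rng_seed=3)
feats = extract_smg_features(trial.ultrasound)

print(f"frames={feats.values.shape[0]}  features/frame={feats.values.shape[1]}")
print(f"block grid={feats.grid_shape} (axial x lateral)")
mean_half = feats.values[:, : feats.n_blocks]
print(f"mean-intensity range: [{mean_half.min():.1f}, {mean_half.max():.1f}]")

# 520 = 2 x 260 blocks. Mean intensities stay within the 8-bit range; the
# temporal half is zero on the first frame and tracks how fast regional
# brightness (muscle state) changes between consecutive frames.
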