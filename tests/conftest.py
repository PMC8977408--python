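import numpy as np
import pytest

import myofuse as mf


@pytest.fixture(scope="session")
def level_template():
    return mf.make_template("level_walk", rng_seed=1)


@pytest.fixture(scope="session")
def small_trial():
    """Default-noise trial, 5 strides of level walking."""
    tpl = mf.make_template("level_walk", rng_seed=1)
    return mf.generate_trial(tpl, n_strides=5, rng_seed=11)


@pytest.fixture(scope="session")
def zero_noise_trial():
    tpl = mf.make_template("level_walk", rng_seed=1)
    return mf.generate_trial(
        tpl, n_strides=4, noise_cfg=mf.NoiseConfig.zero(), rng_seed=11
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small default-noise dataset: 3 walk / 2 stair strides per task."""
    cfg = mf.DatasetConfig().scaled(3, 2)
    return mf.generate_dataset(cfg, rng_seed=42)


@pytest.fixture(scope="session")
def tiny_pertask(tiny_dataset):
    from myofuse.evaluation import prepare_task

    return {task: prepare_task(trial) for task, trial in tiny_dataset.items()}
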