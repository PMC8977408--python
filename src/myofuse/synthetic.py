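"""Synthetic multimodal gait trials with known latent ground truth.

Each ambulation task has a stride-periodic template: smooth hip/knee/ankle
angle profiles (low-order Fourier series over gait phase, affinely mapped to
physiologic ranges) and non-negative periodic activation profiles for ten
latent muscles - the eight recorded by surface EMG plus two (VM, VI) visible
only to the ultrasound transducer.  A trial realizes the template on a
jittered stride clock:

* kinematics (100 Hz): template angle + a stride-to-stride coupling term +
  Gaussian noise; angular velocity by numerical differentiation of the
  noisy angle;
* EMG (1,200 Hz): 20-450 Hz band-limited unit-variance carrier noise,
  amplitude-modulated by the latent activation, plus a small measurement
  noise floor;
* ultrasound (20 Hz): a static speckle-like texture plus a per-muscle band
  whose brightness follows the mapped latent activation, clipped to [0,255].

The coupling term is the designed reason sensor fusion helps: per-stride
activation gains perturb the joint angles through a joint-by-muscle matrix
whose default routes every joint partly through an imaging-only latent
(VM or VI) and the hip and ankle also through EMG-only muscles, so neither
modality alone observes all kinematic variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .emg import EMG_CHANNELS, EMGRecording
from .smg import UltrasoundSequence

__all__ = [
    "TASKS",
    "JOINTS",
    "LATENT_MUSCLES",
    "IMAGING_MUSCLES",
    "UnknownTaskError",
    "NoiseConfig",
    "CouplingConfig",
    "GaitTemplate",
    "SyntheticTrial",
    "DatasetConfig",
    "make_template",
    "generate_trial",
    "generate_dataset",
]

TASKS = (
    "level_walk",
    "incline_walk",
    "decline_walk",
    "stair_ascent",
    "stair_descent",
)
JOINTS = ("hip", "knee", "ankle")

#: Latent muscle states: the eight EMG channels plus vastus medialis and
#: vastus intermedius, which the anterior transducer images but EMG does not.
LATENT_MUSCLES = EMG_CHANNELS + ("VM", "VI")

#: Muscles mapped to ultrasound image bands (anterior thigh placement:
#: rectus femoris superficial, vastus medialis, vastus intermedius deep).
IMAGING_MUSCLES = ("RF", "VM", "VI")


class UnknownTaskError(ValueError):
    """Task label outside the five ambulation tasks."""


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class NoiseConfig:
    """Noise and variability levels for trial synthesis.

    kinematic_noise_sd_deg : additive Gaussian noise on sampled joint angles.
    stride_jitter_frac : SD of stride-duration multiplier (1 + jitter).
    activation_gain_sd : SD of per-stride, per-muscle latent gain about 1.
    emg_noise_frac : EMG measurement-noise SD as a fraction of channel gain.
    us_texture_sd : SD of the static per-pixel background texture.
    us_noise_sd : SD of per-frame per-pixel additive intensity noise.
    """

    kinematic_noise_sd_deg: float = 0.5
    stride_jitter_frac: float = 0.05
    activation_gain_sd: float = 0.2
    emg_noise_frac: float = 0.002
    us_texture_sd: float = 8.0
    us_noise_sd: float = 4.0

    def __post_init__(self):
        if self.kinematic_noise_sd_deg < 0:
            raise ValueError("kinematic noise SD must be >= 0")
        if self.stride_jitter_frac < 0 or self.stride_jitter_frac > 0.3:
            raise ValueError("stride jitter fraction out of range")

    @classmethod
    def zero(cls) -> "NoiseConfig":
        """All stochastic terms off: strides repeat the template exactly."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def _default_coupling() -> dict:
    # degrees of angle deviation per unit (gain - 1) x activation
    return {
        "hip": {"TFL": 6.0, "VI": 6.0},
        "knee": {"VM": 8.0, "VI": 6.0},
        "ankle": {"SOL": 5.0, "VM": 4.0},
    }


@dataclass(frozen=True)
class CouplingConfig:
    """Joint-by-muscle weights routing latent gain variability into angles.

    ``weights[joint][muscle]`` is in degrees per unit gain deviation.  The
    default gives every joint a component carried by an imaging-only latent
    (VM/VI) and gives the hip and ankle components carried by EMG-only
    muscles (TFL, SOL), so fused features dominate either modality alone.
    """

    weights: dict = field(default_factory=_default_coupling)

    def matrix(self) -> np.ndarray:
        """Dense (n_joints x n_latents) weight matrix in template order."""
        out = np.zeros((len(JOINTS), len(LATENT_MUSCLES)))
        for i, j in enumerate(JOINTS):
            for m, w in self.weights.get(j, {}).items():
                out[i, LATENT_MUSCLES.index(m)] = w
        return out


# ---------------------------------------------------------------------------
# templates

# Target (min, max) joint angles in degrees per task, motivated by typical
# lower-limb kinematics during level/ramp/stair ambulation.
_JOINT_RANGES = {
    "level_walk": {"hip": (-10, 30), "knee": (3, 63), "ankle": (-15, 12)},
    "incline_walk": {"hip": (-5, 40), "knee": (5, 70), "ankle": (-8, 18)},
    "decline_walk": {"hip": (-12, 25), "knee": (4, 74), "ankle": (-20, 14)},
    "stair_ascent": {"hip": (-4, 56), "knee": (8, 88), "ankle": (-22, 16)},
    "stair_descent": {"hip": (-8, 34), "knee": (6, 84), "ankle": (-30, 20)},
}

# Base Fourier coefficients (cos_k, sin_k for k = 1..3) giving each joint a
# task-specific periodic shape before affine range mapping.
_JOINT_SHAPES = {
    "level_walk": {
        "hip": ((1.0, 0.15, 0.05), (0.35, 0.10, 0.0)),
        "knee": ((0.25, -0.55, 0.10), (-0.65, -0.30, 0.05)),
        "ankle": ((0.45, 0.35, -0.10), (-0.50, 0.25, 0.05)),
    },
    "incline_walk": {
        "hip": ((1.0, 0.25, 0.05), (0.25, 0.12, 0.02)),
        "knee": ((0.15, -0.60, 0.12), (-0.70, -0.22, 0.04)),
        "ankle": ((0.55, 0.30, -0.08), (-0.40, 0.30, 0.02)),
    },
    "decline_walk": {
        "hip": ((0.95, 0.10, 0.08), (0.40, 0.05, -0.02)),
        "knee": ((0.35, -0.50, 0.15), (-0.55, -0.35, 0.08)),
        "ankle": ((0.35, 0.40, -0.12), (-0.55, 0.20, 0.08)),
    },
    "stair_ascent": {
        "hip": ((0.90, 0.35, 0.02), (0.45, -0.10, 0.05)),
        "knee": ((0.60, -0.35, 0.05), (-0.75, -0.15, 0.10)),
        "ankle": ((0.30, 0.45, -0.05), (-0.35, 0.35, 0.10)),
    },
    "stair_descent": {
        "hip": ((0.85, 0.20, 0.10), (0.30, 0.15, -0.05)),
        "knee": ((-0.20, -0.55, 0.08), (-0.60, -0.40, 0.12)),
        "ankle": ((0.25, 0.50, -0.15), (-0.30, 0.40, -0.05)),
    },
}

_STRIDE_PERIODS = {
    "level_walk": 1.20,
    "incline_walk": 1.30,
    "decline_walk": 1.30,
    "stair_ascent": 1.50,
    "stair_descent": 1.40,
}

# Activation bumps per muscle: (centre phase, concentration, amplitude).
# Centres follow the broad timing of lower-limb muscle activity over a
# stride (stance extensors early, tibialis anterior around swing, etc.).
_ACTIVATION_BUMPS = {
    "AM": ((0.05, 12.0, 0.8), (0.55, 10.0, 0.4)),
    "BF": ((0.90, 10.0, 0.9), (0.15, 14.0, 0.3)),
    "RF": ((0.10, 12.0, 0.8), (0.62, 16.0, 0.5)),
    "VL": ((0.08, 10.0, 0.9),),
    "TFL": ((0.20, 8.0, 0.7), (0.70, 12.0, 0.3)),
    "MG": ((0.38, 14.0, 0.9),),
    "TA": ((0.02, 16.0, 0.7), (0.65, 8.0, 0.6)),
    "SOL": ((0.35, 12.0, 0.9),),
    "VM": ((0.12, 10.0, 0.85), (0.55, 14.0, 0.3)),
    "VI": ((0.16, 9.0, 0.8), (0.75, 12.0, 0.35)),
}

_TASK_INDEX = {t: k for k, t in enumerate(TASKS)}


def _fourier(phi: np.ndarray, cos_c, sin_c) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    out = np.zeros_like(phi)
    for k, (a, b) in enumerate(zip(cos_c, sin_c), start=1):
        out += a * np.cos(2 * np.pi * k * phi) + b * np.sin(2 * np.pi * k * phi)
    return out


def _vonmises_bump(phi: np.ndarray, centre: float, kappa: float) -> np.ndarray:
    return np.exp(kappa * (np.cos(2 * np.pi * (phi - centre)) - 1.0))


@dataclass
class GaitTemplate:
    """Stride-periodic kinematic and activation profiles for one task."""

    task: str
    stride_period_s: float
    joint_coeffs: dict  # joint -> (cos tuple, sin tuple)
    joint_affine: dict  # joint -> (scale, offset) mapping Fourier -> degrees
    activation_bumps: dict  # muscle -> tuple of (centre, kappa, amplitude)

    def joint_angle(self, joint: str, phi) -> np.ndarray:
        """Template angle (degrees) at gait phase phi in [0, 1)."""
        cos_c, sin_c = self.joint_coeffs[joint]
        scale, offset = self.joint_affine[joint]
        return scale * _fourier(np.asarray(phi, dtype=float), cos_c, sin_c) + offset

    def activation(self, muscle: str, phi) -> np.ndarray:
        """Non-negative activation profile in [0, ~1] at phase phi."""
        phi = np.asarray(phi, dtype=float)
        out = np.zeros_like(phi)
        for centre, kappa, amp in self.activation_bumps[muscle]:
            out += amp * _vonmises_bump(phi, centre, kappa)
        return out

    def joint_range(self, joint: str, n_grid: int = 2048) -> float:
        phi = np.linspace(0.0, 1.0, n_grid, endpoint=False)
        ang = self.joint_angle(joint, phi)
        return float(ang.max() - ang.min())


def make_template(task: str, rng_seed: int) -> GaitTemplate:
    """Build the stride template for one ambulation task.

    A fixed per-task shape table is perturbed by a small seeded jitter
    (+-8% on Fourier coefficients, small shifts of activation bump centres),
    then each joint profile is affinely mapped onto its physiologic target
    range, so ranges are exact regardless of the jitter draw.
    """
    if task not in TASKS:
        raise UnknownTaskError(f"unknown task {task!r}; expected one of {TASKS}")
    rng = np.random.default_rng([int(rng_seed) & 0x7FFFFFFF, _TASK_INDEX[task]])

    joint_coeffs = {}
    joint_affine = {}
    phi = np.linspace(0.0, 1.0, 2048, endpoint=False)
    for joint in JOINTS:
        cos_c, sin_c = _JOINT_SHAPES[task][joint]
        jit = lambda c: tuple(v * (1.0 + rng.uniform(-0.08, 0.08)) for v in c)
        cos_j, sin_j = jit(cos_c), jit(sin_c)
        base = _fourier(phi, cos_j, sin_j)
        lo, hi = _JOINT_RANGES[task][joint]
        span = base.max() - base.min()
        scale = (hi - lo) / span
        offset = lo - scale * base.min()
        joint_coeffs[joint] = (cos_j, sin_j)
        joint_affine[joint] = (scale, offset)

    activation_bumps = {}
    for muscle in LATENT_MUSCLES:
        bumps = []
        for centre, kappa, amp in _ACTIVATION_BUMPS[muscle]:
            bumps.append(
                (
                    (centre + rng.uniform(-0.03, 0.03)) % 1.0,
                    kappa * (1.0 + rng.uniform(-0.1, 0.1)),
                    amp * (1.0 + rng.uniform(-0.1, 0.1)),
                )
            )
        activation_bumps[muscle] = tuple(bumps)

    return GaitTemplate(
        task=task,
        stride_period_s=_STRIDE_PERIODS[task],
        joint_coeffs=joint_coeffs,
        joint_affine=joint_affine,
        activation_bumps=activation_bumps,
    )


# ---------------------------------------------------------------------------
# trials


@dataclass
class SyntheticTrial:
    """One simulated ambulation trial with latent ground truth.

    kinematics : DataFrame at 100 Hz with time_s, {joint}_angle (deg) and
        {joint}_velocity (deg/s) columns.
    emg : EMGRecording at 1,200 Hz.
    ultrasound : UltrasoundSequence.
    heel_strikes : stride boundaries, seconds (n_strides + 1 entries).
    latent : DataFrame at 100 Hz with per-muscle activation ground truth.
    stride_gains : (n_strides x n_latents) per-stride activation gains.
    """

    task: str
    kinematics: pd.DataFrame
    emg: EMGRecording
    ultrasound: UltrasoundSequence
    heel_strikes: np.ndarray
    latent: pd.DataFrame
    stride_gains: np.ndarray
    coupling: CouplingConfig
    seed: int

    @property
    def n_strides(self) -> int:
        return len(self.heel_strikes) - 1


def _phase_clock(t: np.ndarray, heel_strikes: np.ndarray):
    """Gait phase and stride index at arbitrary times within the trial."""
    idx = np.clip(
        np.searchsorted(heel_strikes, t, side="right") - 1,
        0,
        len(heel_strikes) - 2,
    )
    t0 = heel_strikes[idx]
    dur = heel_strikes[idx + 1] - heel_strikes[idx]
    phi = np.clip((t - t0) / dur, 0.0, np.nextafter(1.0, 0.0))
    return phi, idx


def _bandlimited_carrier(n: int, fs: float, rng: np.random.Generator, band):
    """Unit-variance noise band-limited to a sub-band of the EMG band."""
    sos = signal.butter(8, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n + 2000))[2000:]
    return x / x.std()


def _emg_channel(
    env: np.ndarray, fs: float, rng: np.random.Generator, noise_frac: float
):
    """Activation-modulated surface-EMG channel.

    The carrier is a mixture of a low (20-150 Hz) and a high (150-450 Hz)
    band-limited noise whose balance shifts toward the high band as
    activation rises, emulating the spectral compression/recruitment shift
    of real surface EMG; the mixture is renormalized to unit variance so the
    envelope alone sets the amplitude.
    """
    n = len(env)
    c_lo = _bandlimited_carrier(n, fs, rng, (20.0, 150.0))
    c_hi = _bandlimited_carrier(n, fs, rng, (150.0, 450.0))
    w = np.clip(env, 0.0, 1.0)
    mix = (1.0 - w) * c_lo + w * c_hi
    norm = np.sqrt((1.0 - w) ** 2 + w**2)
    meas = noise_frac * rng.standard_normal(n)
    return env * mix / norm + meas


_DEFAULT_IMAGE_SHAPE = (120, 78)  # axial x lateral pixels
_DEFAULT_PIXEL_MM = (0.5, 0.5)
_US_BASELINE = 50.0
_US_GAIN = 80.0  # intensity units per unit activation


def _muscle_bands(n_axial: int, muscles=IMAGING_MUSCLES) -> dict:
    """Horizontal image bands, superficial to deep, one per imaged muscle."""
    edges = np.linspace(0, n_axial, len(muscles) + 1).astype(int)
    return {m: (edges[k], edges[k + 1]) for k, m in enumerate(muscles)}


def generate_trial(
    template: GaitTemplate,
    n_strides: int,
    noise_cfg: NoiseConfig = NoiseConfig(),
    rng_seed: int = 0,
    coupling: CouplingConfig = CouplingConfig(),
    kin_rate_hz: float = 100.0,
    emg_rate_hz: float = 1200.0,
    us_rate_hz: float = 20.0,
    image_shape: tuple = _DEFAULT_IMAGE_SHAPE,
    pixel_spacing_mm: tuple = _DEFAULT_PIXEL_MM,
    emg_gain: float = 1.0,
) -> SyntheticTrial:
    """Realize one trial of ``n_strides`` strides from a template."""
    if n_strides < 1:
        raise ValueError("n_strides must be >= 1")
    rng = np.random.default_rng(int(rng_seed) & 0x7FFFFFFF)

    # stride clock
    jitter = rng.normal(0.0, noise_cfg.stride_jitter_frac, n_strides)
    jitter = np.clip(jitter, -0.25, 0.25)
    durations = template.stride_period_s * (1.0 + jitter)
    heel_strikes = np.concatenate([[0.0], np.cumsum(durations)])
    total = heel_strikes[-1]

    # per-stride latent gains
    gains = 1.0 + rng.normal(
        0.0, noise_cfg.activation_gain_sd, (n_strides, len(LATENT_MUSCLES))
    )
    gains = np.clip(gains, 0.2, 1.8)

    def latent_at(times: np.ndarray) -> np.ndarray:
        phi, s = _phase_clock(times, heel_strikes)
        acts = np.empty((len(times), len(LATENT_MUSCLES)))
        for j, m in enumerate(LATENT_MUSCLES):
            acts[:, j] = gains[s, j] * template.activation(m, phi)
        return acts

    # kinematics at 100 Hz
    t_kin = np.arange(int(np.floor(total * kin_rate_hz))) / kin_rate_hz
    phi_k, s_k = _phase_clock(t_kin, heel_strikes)
    cmat = coupling.matrix()
    act_profiles = np.stack(
        [template.activation(m, phi_k) for m in LATENT_MUSCLES], axis=1
    )
    deviation = ((gains[s_k, :] - 1.0) * act_profiles) @ cmat.T  # (n, 3)
    kin = {"time_s": t_kin}
    for i, joint in enumerate(JOINTS):
        ang = (
            template.joint_angle(joint, phi_k)
            + deviation[:, i]
            + rng.normal(0.0, noise_cfg.kinematic_noise_sd_deg, len(t_kin))
        )
        kin[f"{joint}_angle"] = ang
        kin[f"{joint}_velocity"] = np.gradient(ang, 1.0 / kin_rate_hz)
    kinematics = pd.DataFrame(kin)

    latent_df = pd.DataFrame(latent_at(t_kin), columns=list(LATENT_MUSCLES))
    latent_df.insert(0, "time_s", t_kin)

    # EMG at 1,200 Hz: activation-modulated band-limited carrier
    t_emg = np.arange(int(np.floor(total * emg_rate_hz))) / emg_rate_hz
    env = latent_at(t_emg)[:, : len(EMG_CHANNELS)]
    emg_data = np.empty((len(t_emg), len(EMG_CHANNELS)))
    for j in range(len(EMG_CHANNELS)):
        emg_data[:, j] = emg_gain * _emg_channel(
            env[:, j], emg_rate_hz, rng, noise_cfg.emg_noise_frac
        )
    emg = EMGRecording(emg_data, emg_rate_hz, EMG_CHANNELS, t0=0.0)

    # ultrasound frames
    t_us = np.arange(int(np.floor(total * us_rate_hz))) / us_rate_hz
    acts_us = latent_at(t_us)
    bands = _muscle_bands(image_shape[0])
    texture = rng.normal(0.0, noise_cfg.us_texture_sd, image_shape)
    frames = np.empty((len(t_us),) + tuple(image_shape))
    for k in range(len(t_us)):
        img = _US_BASELINE + texture
        if noise_cfg.us_noise_sd > 0:
            img = img + rng.normal(0.0, noise_cfg.us_noise_sd, image_shape)
        for m, (r0, r1) in bands.items():
            img[r0:r1, :] += _US_GAIN * acts_us[k, LATENT_MUSCLES.index(m)]
        frames[k] = np.clip(img, 0.0, 255.0)
    ultrasound = UltrasoundSequence(
        frames, us_rate_hz, tuple(pixel_spacing_mm), t0=0.0
    )

    return SyntheticTrial(
        task=template.task,
        kinematics=kinematics,
        emg=emg,
        ultrasound=ultrasound,
        heel_strikes=heel_strikes,
        latent=latent_df,
        stride_gains=gains,
        coupling=coupling,
        seed=int(rng_seed),
    )


# ---------------------------------------------------------------------------
# datasets


def _default_strides() -> dict:
    # walking trials contribute more strides than the short stair bouts
    return {
        "level_walk": 15,
        "incline_walk": 15,
        "decline_walk": 15,
        "stair_ascent": 8,
        "stair_descent": 8,
    }


@dataclass(frozen=True)
class DatasetConfig:
    """One trial per ambulation task, with per-task stride counts."""

    tasks: tuple = TASKS
    strides_per_task: dict = field(default_factory=_default_strides)
    noise: NoiseConfig = NoiseConfig()
    coupling: CouplingConfig = CouplingConfig()

    def __post_init__(self):
        if len(self.tasks) == 0:
            raise ValueError("task list must not be empty")
        for t in self.tasks:
            if t not in TASKS:
                raise UnknownTaskError(f"unknown task {t!r}")

    def scaled(self, walk_strides: int, stair_strides: int) -> "DatasetConfig":
        """Same conditions at a different problem size."""
        spt = {
            t: (stair_strides if t.startswith("stair") else walk_strides)
            for t in self.tasks
        }
        return replace(self, strides_per_task=spt)


def generate_dataset(
    cfg: DatasetConfig = DatasetConfig(), rng_seed: int = 0
) -> dict:
    """Generate one SyntheticTrial per task; deterministic in (cfg, seed)."""
    root = np.random.default_rng(int(rng_seed) & 0x7FFFFFFF)
    child_seeds = root.integers(0, 2**31 - 1, size=2 * len(cfg.tasks))
    trials = {}
    for k, task in enumerate(cfg.tasks):
        template = make_template(task, int(child_seeds[2 * k]))
        trials[task] = generate_trial(
            template,
            n_strides=cfg.strides_per_task[task],
            noise_cfg=cfg.noise,
            rng_seed=int(child_seeds[2 * k + 1]),
            coupling=cfg.coupling,
        )
    return trials
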