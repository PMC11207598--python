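"""Simulated 6-DOF physiological head motion.

Each DOF follows an independent noisy sinusoid
``A * sin(2*pi*f*t + phi0) + eps`` with amplitude 1.5 mm / 1.5 deg, a
frequency drawn uniformly from [1.7, 2.3] Hz (slightly above typical head
motion, to widen the pose distribution for training), a random phase
offset, and additive white Gaussian noise.  All six DOF vary simultaneously
at a 30 Hz sample rate for 2000 samples per sinusoid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Pose6DOF
from .pose import PoseTrace

__all__ = ["TrajectoryConfig", "generate_trajectory", "make_pose_pairs"]


@dataclass
class TrajectoryConfig:
    amplitude: tuple = (1.5,) * 6        # mm for x/y/z, deg for pitch/yaw/roll
    freq_range_hz: tuple[float, float] = (1.7, 2.3)
    sample_rate_hz: float = 30.0
    n_samples: int = 2000
    noise_fraction: float = 0.05         # noise sigma as a fraction of amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if np.isscalar(self.amplitude):
            self.amplitude = (float(self.amplitude),) * 6
        if len(self.amplitude) != 6 or any(a < 0 for a in self.amplitude):
            raise ValueError("amplitude must be 6 non-negative values")
        lo, hi = self.freq_range_hz
        if not (0 < lo <= hi):
            raise ValueError("need 0 < f_lo <= f_hi")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample rate must be positive")
        if self.noise_fraction < 0:
            raise ValueError("noise fraction must be >= 0")


def generate_trajectory(config: TrajectoryConfig) -> PoseTrace:
    """Generate the noisy-sinusoid 6-DOF trajectory as a PoseTrace."""
    rng = np.random.default_rng(config.seed)
    t = np.arange(config.n_samples) / config.sample_rate_hz
    dof = np.empty((config.n_samples, 6))
    for j in range(6):
        f = rng.uniform(*config.freq_range_hz)
        phi0 = rng.uniform(0.0, 2.0 * np.pi)
        a = config.amplitude[j]
        noise = rng.normal(0.0, config.noise_fraction * a, config.n_samples)
        dof[:, j] = a * np.sin(2.0 * np.pi * f * t + phi0) + noise
    return PoseTrace.from_arrays(t, dof)


def make_pose_pairs(trace: PoseTrace
                    ) -> list[tuple[Pose6DOF, Pose6DOF, Pose6DOF]]:
    """Consecutive (pose_t, pose_t+1, delta) triples from a trajectory.

    The delta is the componentwise difference (valid in the <= 1.5 deg
    small-angle regime); a cumulative sum of deltas added to the first pose
    reconstructs the trajectory exactly.
    """
    if len(trace) < 2:
        raise ValueError("need at least 2 samples to form pose pairs")
    dof = trace.dof_array
    if np.isnan(dof).any():
        raise ValueError("trace contains invalid frames; pairs must skip them explicitly")
    pairs = []
    for i in range(len(dof) - 1):
        p0 = Pose6DOF.from_array(dof[i])
        p1 = Pose6DOF.from_array(dof[i + 1])
        pairs.append((p0, p1, p1 - p0))
    return pairs


def pair_deltas(trace: PoseTrace) -> np.ndarray:
    """(N-1, 6) array of consecutive deltas (vectorised companion to make_pose_pairs)."""
    dof = trace.dof_array
    return np.diff(dof, axis=0)
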