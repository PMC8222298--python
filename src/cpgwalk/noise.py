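"""Band-limited, truncated Gaussian noise as smooth continuous-time signals.

Discrete zero-mean Gaussian white noise is drawn per channel on a uniform
grid (default frequency 16 in normalized units, well above the pendulum
bandwidth), clipped to +-3 standard deviations, and interpolated with a
cubic spline so the integrator sees a smooth function of time.  One child
RNG stream per channel is derived from the master seed, so process and
sensor noise are mutually independent and every trial is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline


@dataclass(frozen=True)
class NoiseSpec:
    """Reference noise condition: angular-acceleration SDs by leg role
    (stance, swing) and leg-angle sensor SDs."""

    process_sd: tuple[float, float] = (0.015, 0.16)
    sensor_sd: tuple[float, float] = (0.1, 0.1)
    sample_freq: float = 16.0
    truncation_sd: float = 3.0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.process_sd + self.sensor_sd):
            raise ValueError("noise SDs must be non-negative")
        if self.sample_freq <= 0 or self.truncation_sd <= 0:
            raise ValueError("sample_freq and truncation_sd must be positive")

    def scaled(self, process_var_mult: float = 1.0,
               sensor_var_mult: float = 1.0) -> "NoiseSpec":
        """Spec with covariances (variances) multiplied; SDs scale by sqrt."""
        pm = np.sqrt(process_var_mult)
        sm = np.sqrt(sensor_var_mult)
        return NoiseSpec(
            process_sd=tuple(pm * s for s in self.process_sd),
            sensor_sd=tuple(sm * s for s in self.sensor_sd),
            sample_freq=self.sample_freq,
            truncation_sd=self.truncation_sd,
        )

    @property
    def process_cov(self) -> np.ndarray:
        return np.diag(np.square(self.process_sd))

    @property
    def sensor_cov(self) -> np.ndarray:
        return np.diag(np.square(self.sensor_sd))


@dataclass
class NoiseSignal:
    """Sampled, truncated noise with its smooth interpolant."""

    times: np.ndarray
    samples: np.ndarray          # (n, channels)
    spline: CubicSpline
    seed_entropy: tuple

    def __call__(self, t):
        return self.spline(t)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def coefficients(self) -> np.ndarray:
        """(4, nseg, channels) piecewise-cubic coefficients (numba layout)."""
        return np.ascontiguousarray(self.spline.c)


def make_noise_signal(sds, duration: float, sample_freq: float = 16.0,
                      truncation_sd: float = 3.0,
                      seed=0) -> NoiseSignal:
    """Truncated Gaussian noise for `len(sds)` channels over [0, duration].

    `seed` may be an int or a numpy SeedSequence; each channel draws from
    its own child stream.  Channels with SD 0 are identically zero.
    Truncation is by clipping, which perturbs the sample SD by < 1% at the
    default +-3 SD bound.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    sds = np.atleast_1d(np.asarray(sds, dtype=float))
    n = int(np.ceil(duration * sample_freq)) + 2
    times = np.arange(n) / sample_freq
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = ss.spawn(len(sds))
    samples = np.zeros((n, len(sds)))
    for ch, (sd, child) in enumerate(zip(sds, children)):
        if sd == 0:
            continue
        x = np.random.default_rng(child).normal(0.0, sd, size=n)
        samples[:, ch] = np.clip(x, -truncation_sd * sd, truncation_sd * sd)
    spline = CubicSpline(times, samples, axis=0)
    entropy = ss.entropy
    if np.ndim(entropy) == 0:
        entropy = (int(entropy),)
    else:
        entropy = tuple(int(x) for x in entropy)
    return NoiseSignal(times=times, samples=samples, spline=spline,
                       seed_entropy=entropy)


def zero_signal(channels: int = 2) -> NoiseSignal:
    """Identically zero two-sample signal (placeholder for noiseless runs)."""
    times = np.array([0.0, 1.0])
    samples = np.zeros((2, channels))
    return NoiseSignal(times=times, samples=samples,
                       spline=CubicSpline(times, samples, axis=0),
                       seed_entropy=(0,))
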