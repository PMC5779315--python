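"""Monte-Carlo simulator of diffusive drift of a stored circular variable.

A continuous-attractor network holding an analog value is, under activity
noise, a Brownian motion along its manifold of stable states: the squared
displacement of the stored value grows as ``2*D*T`` until wrapping on the
circle saturates it at ``C^2/12`` (the variance of a uniform variable on a
circle of circumference C).  The simulator grounds the channel-noise model
used by the closed-form curves and validates the D*K/N resource-pooling rule.

No restoring force is applied: drift along a flat attractor manifold is pure
diffusion, so increments are exact Gaussians and a single-step sampler with
variance 2*D*T is statistically identical to a fine-step path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .theory import pooled_diffusivity

__all__ = [
    "DiffusionConfig",
    "DiffusionEnsemble",
    "simulate_diffusion",
    "sample_wrapped_displacement",
    "estimate_diffusivity",
    "simulate_direct_storage",
]


def wrap_displacement(x: np.ndarray, circumference: float) -> np.ndarray:
    """Wrap signed displacements into (-C/2, C/2]."""
    c = circumference
    wrapped = np.mod(x, c)
    return np.where(wrapped > c / 2.0, wrapped - c, wrapped)


@dataclass(frozen=True)
class DiffusionConfig:
    """Configuration of a wrapped Brownian-motion ensemble.

    diffusivity is in (normalized range)^2 / s; circumference 1.0 stands for
    the 180-degree orientation circle.  dt defaults to total_time/1000.
    """

    diffusivity: float
    total_time: float
    n_paths: int
    dt: float | None = None
    circumference: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.diffusivity < 0:
            raise ValueError("diffusivity must be nonnegative")
        if self.total_time <= 0:
            raise ValueError("total_time must be positive")
        if self.n_paths < 1:
            raise ValueError("n_paths must be >= 1")
        if self.circumference <= 0:
            raise ValueError("circumference must be positive")
        if self.dt is not None and not (0 < self.dt <= self.total_time):
            raise ValueError("dt must satisfy 0 < dt <= total_time")

    @property
    def step(self) -> float:
        return self.dt if self.dt is not None else self.total_time / 1000.0


@dataclass(frozen=True)
class DiffusionEnsemble:
    """Wrapped signed displacements (n_times, n_paths) at strictly increasing times."""

    times: np.ndarray
    displacements: np.ndarray
    circumference: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing and 1-D")
        d = np.asarray(self.displacements, float)
        if d.shape[0] != t.shape[0]:
            raise ValueError("displacements must have one row per sample time")
        half = self.circumference / 2.0
        if np.any(d > half) or np.any(d <= -half - 1e-12):
            raise ValueError("displacements must lie in (-C/2, C/2]")

    def mean_squared_displacement(self) -> np.ndarray:
        """Mean squared wrapped displacement at each sample time."""
        return np.mean(self.displacements**2, axis=1)

    def msd_standard_error(self) -> np.ndarray:
        """Monte-Carlo standard error of the mean squared displacement."""
        sq = self.displacements**2
        return np.std(sq, axis=1, ddof=1) / np.sqrt(sq.shape[1])


def simulate_diffusion(
    config: DiffusionConfig, sample_times: Sequence[float]
) -> DiffusionEnsemble:
    """Simulate wrapped Brownian paths and record them at `sample_times`.

    Increments over each step dt are i.i.d. N(0, 2*D*dt); positions are
    accumulated on the line and wrapped to (-C/2, C/2] at readout.  Sample
    times are snapped to the step grid (within one step).  Deterministic
    given `config.seed`.
    """
    times = np.asarray(sample_times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("sample_times must be a nonempty 1-D sequence")
    if np.any(times <= 0) or np.any(times > config.total_time + 1e-12):
        raise ValueError("sample times must lie in (0, total_time]")
    if np.any(np.diff(times) <= 0):
        raise ValueError("sample times must be strictly increasing")

    dt = config.step
    n_steps = int(round(config.total_time / dt))
    sample_steps = np.maximum(1, np.round(times / dt).astype(int))
    sample_steps = np.minimum(sample_steps, n_steps)

    rng = np.random.default_rng(config.seed)
    sigma = np.sqrt(2.0 * config.diffusivity * dt)
    positions = np.zeros(config.n_paths)
    out = np.empty((times.size, config.n_paths))
    next_idx = 0
    for step in range(1, n_steps + 1):
        positions = positions + sigma * rng.standard_normal(config.n_paths)
        while next_idx < times.size and sample_steps[next_idx] == step:
            out[next_idx] = wrap_displacement(positions, config.circumference)
            next_idx += 1
        if next_idx == times.size:
            break
    return DiffusionEnsemble(
        times=times, displacements=out, circumference=config.circumference
    )


def sample_wrapped_displacement(
    diffusivity: float,
    duration: float,
    size: int | tuple[int, ...],
    rng: np.random.Generator,
    circumference: float = 1.0,
) -> np.ndarray:
    """Exact single-step sampler of the wrapped displacement after time T.

    Brownian increments are Gaussian, so the displacement at T is exactly
    N(0, 2*D*T) wrapped to the circle — no path discretization needed.
    """
    sigma = np.sqrt(2.0 * diffusivity * duration)
    return wrap_displacement(sigma * rng.standard_normal(size), circumference)


def estimate_diffusivity(ensemble: DiffusionEnsemble) -> float:
    """Estimate D as half the slope of a through-origin fit of MSD on time.

    Valid in the early-time regime 2*D*T << C^2 where wrapping is negligible
    and the mean squared displacement grows linearly as 2*D*t.
    """
    if ensemble.times.size < 2:
        raise ValueError("need at least two sample times to estimate a slope")
    msd = ensemble.mean_squared_displacement()
    t = ensemble.times
    slope = float(np.dot(t, msd) / np.dot(t, t))
    return slope / 2.0


def simulate_direct_storage(
    n_items: int,
    n_channels: float,
    diffusivity: float,
    duration: float,
    n_trials: int,
    seed: int | None = None,
    circumference: float = 1.0,
) -> np.ndarray:
    """Per-item squared errors of direct storage of K items in K networks.

    Each of the K networks gets an N/K share of the resource pool, so each
    stored value diffuses with pooled diffusivity D*K/N.  Returns an array
    of shape (n_trials, n_items) of squared wrapped errors whose mean, in
    the unsaturated regime, converges to the direct-storage MSE curve.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if duration < 0:
        raise ValueError("duration must be nonnegative")
    if diffusivity == 0 or duration == 0:
        return np.zeros((n_trials, n_items))
    rng = np.random.default_rng(seed)
    d_bar = pooled_diffusivity(diffusivity, n_items, n_channels)
    disp = sample_wrapped_displacement(
        d_bar, duration, (n_trials, n_items), rng, circumference
    )
    return disp**2
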