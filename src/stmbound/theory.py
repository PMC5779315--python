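"""Closed-form memory-degradation curves for two storage architectures.

Two competing accounts of how recall error in visual short-term memory grows
with storage duration ``T`` and set size ``K``, given a fixed pool of neural
resources:

* **Direct storage** — each of the K circular variables is written, as is,
  into its own continuous-attractor network.  Splitting N resource units
  K ways leaves each network with diffusivity ``D*K/N``, so the mean squared
  error grows linearly: ``MSE = Phi^2 * 2*D*(K/N)*T``.

* **Coded storage** — the K variables are first jointly encoded into an
  N-dimensional codeword and stored across N unit-diffusivity channels.
  Joint source-channel coding theory gives a lower bound on the achievable
  distortion: ``MSE >= Phi^2/(2*pi*e) * (1 + 1/(2*D*T))^(-N/K)``.

All quantities are in *normalized* units: the stored variable lives on
``[0, Phi]`` with ``Phi = 1`` standing for the full 180-degree orientation
range, so MSE values are dimensionless fractions of the squared range.
Information rates are in nats (natural logarithms throughout; divide by
``ln 2`` for bits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ChannelSpec",
    "PowerAllocation",
    "RateResult",
    "DistortionBound",
    "direct_storage_mse",
    "pooled_diffusivity",
    "gaussian_capacity",
    "sum_rate_bound",
    "per_item_rate",
    "rate_distortion_interval",
    "coded_storage_mse_bound",
    "coded_storage_mse_grid",
    "heuristic_identity_check",
    "resource",
    "norm_to_deg2",
    "deg2_to_norm",
]

#: Full range of the stored orientation variable, in degrees.
RANGE_DEG = 180.0


@dataclass(frozen=True)
class ChannelSpec:
    """Parameter bundle shared by both model curves.

    Parameters
    ----------
    phi : float
        Range of the stored variable in normalized units (1.0 == 180 deg).
    n_items : float
        Set size K (number of simultaneously stored items), >= 1.
    n_channels : float
        Number of parallel memory channels N.  Real-valued: fitting
        explores a continuous grid; integer N is a presentation convention.
    diffusivity : float
        Diffusivity D in (normalized range)^2 per second.  Squared drift of
        a stored state grows as 2*D*T.
    duration : float
        Storage duration T in seconds, >= 0.
    """

    phi: float = 1.0
    n_items: float = 1.0
    n_channels: float = 1.0
    diffusivity: float = 1.0
    duration: float = 0.0

    def __post_init__(self) -> None:
        if not self.phi > 0:
            raise ValueError(f"phi must be positive, got {self.phi}")
        if not self.n_items >= 1:
            raise ValueError(f"n_items must be >= 1, got {self.n_items}")
        if not self.n_channels > 0:
            raise ValueError(f"n_channels must be positive, got {self.n_channels}")
        if not self.diffusivity > 0:
            raise ValueError(f"diffusivity must be positive, got {self.diffusivity}")
        if not self.duration >= 0:
            raise ValueError(f"duration must be >= 0, got {self.duration}")

    @property
    def snr(self) -> float:
        """Signal-to-noise ratio 1/(2*D*T) of one channel use."""
        if self.duration == 0:
            return math.inf
        return 1.0 / (2.0 * self.diffusivity * self.duration)


@dataclass(frozen=True)
class PowerAllocation:
    """Per-item codeword powers P^(k), nonnegative, summing to at most 1."""

    powers: tuple[float, ...]

    def __init__(self, powers: Sequence[float]) -> None:
        powers = tuple(float(p) for p in powers)
        if any(p < 0 for p in powers):
            raise ValueError("powers must be nonnegative")
        if sum(powers) > 1.0 + 1e-12:
            raise ValueError("total power must not exceed 1")
        object.__setattr__(self, "powers", powers)

    @classmethod
    def equal(cls, n_items: int) -> "PowerAllocation":
        """Equal K-way split P^(k) = 1/K (the continuous-resource case)."""
        return cls((1.0 / n_items,) * n_items)


@dataclass(frozen=True)
class RateResult:
    """Information rate in nats, per channel use and totalled over N uses."""

    per_use_rate: float
    total_rate: float


@dataclass(frozen=True)
class DistortionBound:
    """Rate-distortion interval: the achievable MSE lies in [lower, upper]."""

    lower: float
    upper: float


def direct_storage_mse(spec: ChannelSpec) -> float:
    """MSE of direct (uncoded) storage: ``Phi^2 * 2*D*(K/N)*T``.

    Linear in T and K, inverse in N; valid while the accrued error stays
    small relative to the squared range (no circular saturation).
    """
    return (
        spec.phi**2
        * 2.0
        * spec.diffusivity
        * (spec.n_items / spec.n_channels)
        * spec.duration
    )


def pooled_diffusivity(diffusivity: float, n_items: float, n_channels: float) -> float:
    """Effective diffusivity D*K/N of each network after a K-way resource split."""
    if diffusivity <= 0:
        raise ValueError("diffusivity must be positive")
    if n_items <= 0:
        raise ValueError("n_items must be positive")
    if n_channels <= 0:
        raise ValueError("n_channels must be positive")
    return diffusivity * n_items / n_channels


def gaussian_capacity(snr: float) -> float:
    """Capacity ``(1/2) ln(1 + snr)`` of the additive Gaussian channel, nats/use."""
    if snr < 0:
        raise ValueError(f"snr must be nonnegative, got {snr}")
    return 0.5 * math.log1p(snr)


def sum_rate_bound(
    alloc: PowerAllocation,
    subset: Sequence[int],
    diffusivity: float,
    duration: float,
) -> float:
    """Sum-rate bound over a subset S of items, nats per channel use.

    ``R_S <= (1/2) ln(1 + sum_{k in S} P^(k) / (2*D*T))``.  With the full
    item set and unit total power this reduces to the Gaussian capacity at
    snr = 1/(2*D*T).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if diffusivity <= 0:
        raise ValueError("diffusivity must be positive")
    k = len(alloc.powers)
    idx = list(subset)
    if any(i < 0 or i >= k for i in idx):
        raise IndexError(f"subset indices must lie in [0, {k})")
    total_power = sum(alloc.powers[i] for i in idx)
    return gaussian_capacity(total_power / (2.0 * diffusivity * duration))


def per_item_rate(spec: ChannelSpec) -> RateResult:
    """Per-item rate under the equal split P^(k)=1/K, R^(1)=...=R^(K).

    per_use_rate = ``(1/(2K)) ln(1 + 1/(2*D*T))``; total_rate = N times that,
    i.e. the (N/K)-fold Gaussian capacity shared by each item.
    """
    if spec.duration <= 0:
        raise ValueError("per-item rate is infinite at T = 0")
    per_use = gaussian_capacity(spec.snr) / spec.n_items
    return RateResult(per_use_rate=per_use, total_rate=spec.n_channels * per_use)


def rate_distortion_interval(rate: float, phi: float = 1.0) -> DistortionBound:
    """Distortion interval for a uniform source on [0, phi] at rate R nats.

    lower = ``phi^2 e^{-2R} / (2 pi e)`` (Shannon lower bound); upper =
    ``phi^2 e^{-2R} / 12`` (uniform-quantization achievability).  At R = 0
    the upper end is phi^2/12, the variance of a uniform variable on [0, phi].
    """
    if rate < 0:
        raise ValueError(f"rate must be nonnegative, got {rate}")
    if phi <= 0:
        raise ValueError("phi must be positive")
    shrink = math.exp(-2.0 * rate)
    return DistortionBound(
        lower=phi**2 * shrink / (2.0 * math.pi * math.e),
        upper=phi**2 * shrink / 12.0,
    )


def coded_storage_mse_bound(spec: ChannelSpec) -> float:
    """Lower bound on MSE with optimal coding: ``Phi^2/(2 pi e) (1+1/(2DT))^{-N/K}``.

    Evaluated in the log domain so large N/K or large snr cannot overflow.
    The T = 0 limit (infinite snr) is defined as 0 by continuity.
    """
    if spec.duration == 0:
        return 0.0
    log_prefactor = 2.0 * math.log(spec.phi) - math.log(2.0 * math.pi * math.e)
    exponent = -(spec.n_channels / spec.n_items) * math.log1p(spec.snr)
    return math.exp(log_prefactor + exponent)


def coded_storage_mse_grid(
    n_channels: np.ndarray,
    inv_2d: np.ndarray,
    n_items: float,
    duration: float,
    phi: float = 1.0,
) -> np.ndarray:
    """Vectorized coded-storage bound over broadcastable (N, 1/2D) arrays.

    Same quantity as :func:`coded_storage_mse_bound` with
    ``diffusivity = 1/(2*inv_2d)``; used by the fitting grid search.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    snr = np.asarray(inv_2d, dtype=float) / duration
    log_pref = 2.0 * math.log(phi) - math.log(2.0 * math.pi * math.e)
    return np.exp(log_pref - (np.asarray(n_channels, dtype=float) / n_items) * np.log1p(snr))


def heuristic_identity_check(
    snr: float, n_channels: float, n_items: float, rtol: float = 1e-12
) -> bool:
    """Check ``exp(-2 (N/K) C(snr)) == (1+snr)^{-N/K}`` to relative tolerance.

    The algebraic identity behind the capacity -> e^{-2I} shortcut derivation
    of the coded-storage bound.
    """
    ratio = n_channels / n_items
    lhs = math.exp(-2.0 * ratio * gaussian_capacity(snr))
    rhs = math.exp(-ratio * math.log1p(snr))
    return math.isclose(lhs, rhs, rel_tol=rtol)


def resource(n_channels: float, inv_2d: float) -> float:
    """Combined neural resource ``N * (1/2D)`` in seconds.

    Proportional to the total neuron count across the storage networks;
    invariant under the trade-off (N -> cN, 1/2D -> (1/c)/2D).
    """
    return n_channels * inv_2d


def norm_to_deg2(mse_norm: float | np.ndarray) -> float | np.ndarray:
    """Convert normalized MSE (range = 1) to squared degrees (range = 180)."""
    return mse_norm * RANGE_DEG**2


def deg2_to_norm(mse_deg2: float | np.ndarray) -> float | np.ndarray:
    """Convert squared-degree MSE to normalized units (exact inverse of above)."""
    return mse_deg2 / RANGE_DEG**2
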