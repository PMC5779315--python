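"""Synthetic delayed-estimation datasets with the experiment's design.

Emulates a delayed orientation-estimation study: 10 subjects each run 11-15
blocks of 80 trials; a block holds 20 trials per set size K in {1, 2, 4, 6},
split as 5 trials per delay T in {0.1, 1, 2, 3} s; targets are uniform on
[0, 180) degrees and the probed item's color is bookkeeping only.

The generative error model is the anchored counterpart of the theory curves:
a trial's response is the target plus wrapped-normal noise whose variance is

    baseline_mse(K) + [D_model(K, T) - D_model(K, T0)]

in normalized (range = 1) units, where D_model is the direct-storage or the
coded-storage curve and T0 = 0.1 s is the shortest delay.  Generated data
therefore satisfy the fitting stage's anchoring convention by construction.
Baseline errors are additive in variance, reflecting independence of
encoding-stage error from the error accrued during storage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .empirical import TRIAL_COLUMNS
from .theory import RANGE_DEG, ChannelSpec, coded_storage_mse_bound, direct_storage_mse

__all__ = [
    "ExperimentDesign",
    "GenerativeModel",
    "DEFAULT_BASELINE_MSE",
    "generate_dataset",
    "write_trials",
    "read_trials",
]

logger = logging.getLogger(__name__)

#: Circular MSE ceiling: variance of a uniform variable on a unit circle.
_WRAP_CEILING = 1.0 / 12.0


def _wrapped_mse(sigma: float) -> float:
    """E[wrap(X)^2] for X ~ N(0, sigma^2) wrapped to (-1/2, 1/2].

    Exact piecewise-Gaussian integral: sum over winding numbers k of
    int_{k-1/2}^{k+1/2} (x - k)^2 phi(x; sigma) dx.
    """
    if sigma <= 0:
        return 0.0
    from scipy.stats import norm

    k_max = int(np.ceil(8.0 * sigma)) + 1
    total = 0.0
    for k in range(-k_max, k_max + 1):
        a, b = (k - 0.5) / sigma, (k + 0.5) / sigma
        m0 = norm.cdf(b) - norm.cdf(a)
        ex1 = sigma * (norm.pdf(a) - norm.pdf(b))
        ex2 = sigma**2 * (m0 + a * norm.pdf(a) - b * norm.pdf(b))
        total += ex2 - 2 * k * ex1 + k**2 * m0
    return float(total)


def _calibrated_sigma(target_var: float) -> float:
    """Linear SD whose *wrapped* MSE equals `target_var` on the unit circle.

    Wrapping pulls the circular MSE below the linear variance, so the raw
    sqrt(variance) would undershoot the model curve at large cells.  Targets
    at or above the circular ceiling 1/12 are unreachable; they fall back to
    the raw SD with a saturation warning from the caller.
    """
    if target_var <= 0:
        return 0.0
    if target_var >= _WRAP_CEILING * (1.0 - 1e-9):
        return float(np.sqrt(target_var))
    sigma0 = float(np.sqrt(target_var))
    if target_var - _wrapped_mse(sigma0) < 1e-12:  # wrap bias negligible
        return sigma0
    from scipy.optimize import brentq

    return float(brentq(lambda s: _wrapped_mse(s) - target_var, sigma0, 10.0))

#: Per-set-size normalized MSE at the shortest delay: circular SDs of roughly
#: 8, 12, 18 and 25 degrees, typical of delayed orientation estimation.
DEFAULT_BASELINE_MSE: dict[int, float] = {
    1: (8.0 / 180.0) ** 2,
    2: (12.0 / 180.0) ** 2,
    4: (18.0 / 180.0) ** 2,
    6: (25.0 / 180.0) ** 2,
}


@dataclass(frozen=True)
class ExperimentDesign:
    """Trial bookkeeping of the delayed-estimation study being emulated."""

    n_subjects: int = 10
    set_sizes: tuple[int, ...] = (1, 2, 4, 6)
    delays: tuple[float, ...] = (0.1, 1.0, 2.0, 3.0)
    blocks_min: int = 11
    blocks_max: int = 15
    trials_per_cell_per_block: int = 5
    n_colors: int = 8

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.blocks_min > self.blocks_max or self.blocks_min < 1:
            raise ValueError("invalid block-count range")
        if self.n_colors < max(self.set_sizes):
            raise ValueError("need at least as many colors as the largest set size")
        if len(set(self.set_sizes)) != len(self.set_sizes):
            raise ValueError("set sizes must be unique")
        if len(set(self.delays)) != len(self.delays):
            raise ValueError("delays must be unique")

    @property
    def trials_per_set_size_per_block(self) -> int:
        return len(self.delays) * self.trials_per_cell_per_block

    @property
    def trials_per_block(self) -> int:
        return len(self.set_sizes) * self.trials_per_set_size_per_block

    @property
    def baseline_delay(self) -> float:
        return min(self.delays)


@dataclass(frozen=True)
class GenerativeModel:
    """Error model producing a trial's noise variance from its (K, T) cell.

    kind
        ``"direct"`` (linear MSE growth, parameter N/2D = n_channels*inv_2d),
        ``"coded"`` (information-theoretic bound, parameters N and 1/2D), or
        ``"custom"`` (explicit per-(K, T) MSE table in `custom_mse`).
    baseline_mse
        Normalized MSE at the shortest delay, per set size.
    n_channels, inv_2d
        N and 1/(2D) in seconds; the direct curve depends only on their
        product, the resource N/2D.
    subject_scale_sd
        SD of the lognormal per-subject multiplier on the noise variance
        (0 disables subject heterogeneity).
    """

    kind: str = "coded"
    baseline_mse: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_MSE)
    )
    n_channels: float = 10.0
    inv_2d: float = 2.28
    phi: float = 1.0
    custom_mse: Mapping[tuple[int, float], float] | None = None
    subject_scale_sd: float = 0.0
    baseline_delay: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in {"direct", "coded", "custom"}:
            raise ValueError(f"unknown model kind {self.kind!r}")
        for k, v in self.baseline_mse.items():
            if not 0 <= v < 0.25:
                raise ValueError(f"baseline MSE for K={k} outside [0, 1/4)")
        if self.kind == "custom" and self.custom_mse is None:
            raise ValueError("custom kind requires a custom_mse table")

    @property
    def diffusivity(self) -> float:
        return 1.0 / (2.0 * self.inv_2d)

    def delay_mse(self, set_size: int, delay_s: float) -> float:
        """The raw (un-anchored) model curve D_model(K, T)."""
        if self.kind == "custom":
            return float(self.custom_mse[(set_size, delay_s)])
        spec = ChannelSpec(
            phi=self.phi,
            n_items=set_size,
            n_channels=self.n_channels,
            diffusivity=self.diffusivity,
            duration=delay_s,
        )
        if self.kind == "direct":
            return direct_storage_mse(spec)
        return coded_storage_mse_bound(spec)

    def cell_variance(self, set_size: int, delay_s: float) -> float:
        """Target noise variance: baseline plus anchored delay increment."""
        increment = self.delay_mse(set_size, delay_s) - self.delay_mse(
            set_size, self.baseline_delay
        )
        return float(self.baseline_mse[set_size]) + increment


def generate_dataset(
    design: ExperimentDesign, model: GenerativeModel, seed: int | None = None
) -> pd.DataFrame:
    """Generate a trial table with exact per-cell counts.

    Per subject: a block count drawn uniformly from the design's range, and
    per block exactly `trials_per_cell_per_block` trials in every (K, T)
    cell, in shuffled order.  Responses are target + wrapped-normal noise
    whose linear SD is calibrated so the *circular* MSE equals the model's
    cell variance (times the subject's lognormal scale; the calibration is
    exact at unit scale and approximate otherwise).
    Angles are quantized to 4 decimal places, matching the CSV dialect.
    Deterministic given `seed`.
    """
    rng = np.random.default_rng(seed)
    cells = [(k, t) for k in design.set_sizes for t in design.delays]
    cell_sd: dict[tuple[int, float], float] = {}
    for k, t in cells:
        var = model.cell_variance(k, t)
        if var >= _WRAP_CEILING:
            logger.warning(
                "cell (K=%d, T=%.3g) variance %.3g saturates the circular range "
                "(ceiling 1/12); generating wrapped noise anyway",
                k,
                t,
                var,
            )
        cell_sd[(k, t)] = _calibrated_sigma(max(var, 0.0))

    frames = []
    for s in range(1, design.n_subjects + 1):
        n_blocks = int(rng.integers(design.blocks_min, design.blocks_max + 1))
        scale = (
            float(np.exp(rng.normal(0.0, model.subject_scale_sd)))
            if model.subject_scale_sd > 0
            else 1.0
        )
        for b in range(1, n_blocks + 1):
            ks, ts = zip(
                *[
                    (k, t)
                    for k, t in cells
                    for _ in range(design.trials_per_cell_per_block)
                ]
            )
            order = rng.permutation(len(ks))
            k_arr = np.asarray(ks)[order]
            t_arr = np.asarray(ts)[order]
            n = len(k_arr)
            targets = rng.uniform(0.0, RANGE_DEG, n)
            sds = np.array([cell_sd[(int(k), float(t))] for k, t in zip(k_arr, t_arr)])
            noise_deg = rng.standard_normal(n) * sds * np.sqrt(scale) * RANGE_DEG
            responses = np.mod(targets + noise_deg, RANGE_DEG)
            colors = rng.integers(0, design.n_colors, n)
            frames.append(
                pd.DataFrame(
                    {
                        "subject": s,
                        "block": b,
                        "trial": np.arange(n),
                        "set_size": k_arr,
                        "delay_s": t_arr,
                        "target_deg": np.mod(np.round(targets, 4), RANGE_DEG),
                        "response_deg": np.mod(np.round(responses, 4), RANGE_DEG),
                        "color": colors,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as CSV (angles with 4 decimal places)."""
    out = trials[TRIAL_COLUMNS].copy()
    out["target_deg"] = out["target_deg"].map(lambda x: f"{x:.4f}")
    out["response_deg"] = out["response_deg"].map(lambda x: f"{x:.4f}")
    out.to_csv(path, index=False)


def read_trials(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a trial table, validating ranges row by row.

    `column_map` renames foreign column names to the canonical dialect
    (e.g. ``{"subj": "subject"}``) so externally formatted tables can be
    ingested.  Malformed rows and out-of-range angles raise a ValueError
    carrying the offending row number.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    df = df[TRIAL_COLUMNS]
    if df.empty:
        return df
    for col in ("target_deg", "response_deg"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals >= RANGE_DEG)
        if bad.any():
            row = int(df.index[bad][0])
            raise ValueError(
                f"row {row}: {col}={df[col].iloc[row]!r} is not an angle in [0, 180)"
            )
        df[col] = vals
    for col in ("subject", "block", "trial", "set_size", "color"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(df.index[vals.isna()][0])
            raise ValueError(f"row {row}: malformed value in column {col!r}")
        df[col] = vals.astype(int)
    df["delay_s"] = pd.to_numeric(df["delay_s"])
    return df
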