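"""From trial tables to per-(set size, delay) performance summaries.

Delayed-estimation trials record a target orientation and the subject's
reproduced orientation, both on the 180-degree-periodic circle.  The summary
statistic the models are fitted to is the mean squared circular error,
normalized by the squared range (180 deg)^2, with its SEM taken across
participants: each subject contributes one mean per (K, T) cell, and the
cell value is the unweighted average of subject means so that the point
estimate lives on the same footing as its error bar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .theory import RANGE_DEG

__all__ = [
    "circular_error",
    "squared_error_norm",
    "performance_table",
    "PerformanceTable",
]

#: Canonical column names of a trial table.
TRIAL_COLUMNS = [
    "subject",
    "block",
    "trial",
    "set_size",
    "delay_s",
    "target_deg",
    "response_deg",
    "color",
]


def circular_error(
    target_deg: float | np.ndarray, response_deg: float | np.ndarray
) -> float | np.ndarray:
    """Signed angular error response - target on the 180-degree circle.

    Returns values in (-90, 90]; the measure-zero tie at exactly 90 degrees
    maps to +90 for determinism.  Antisymmetric up to that boundary tie.
    """
    t = np.asarray(target_deg, dtype=float)
    r = np.asarray(response_deg, dtype=float)
    if np.any(t < 0) or np.any(t >= RANGE_DEG) or np.any(r < 0) or np.any(r >= RANGE_DEG):
        raise ValueError("angles must lie in [0, 180)")
    d = np.mod(r - t, RANGE_DEG)
    out = np.where(d > RANGE_DEG / 2.0, d - RANGE_DEG, d)
    if np.isscalar(target_deg) and np.isscalar(response_deg):
        return float(out)
    return out


def squared_error_norm(target_deg, response_deg) -> np.ndarray:
    """Squared circular error normalized by (180 deg)^2; lies in [0, 0.25]."""
    err = np.asarray(circular_error(target_deg, response_deg), dtype=float)
    return (err / RANGE_DEG) ** 2


@dataclass(frozen=True)
class PerformanceTable:
    """Per-(K, T) recall-error summary.

    `points` has one row per (set_size, delay_s) cell with columns:

    - ``mse_norm`` — mean across subjects of per-subject mean normalized
      squared error;
    - ``sem_norm`` — SD of the subject means / sqrt(n_subjects) (NaN when a
      cell has a single subject);
    - ``var_norm`` — variance of the per-trial normalized squared errors
      pooled over all subjects (the Gaussian-likelihood variance);
    - ``n_trials``, ``n_subjects``.

    `baseline_delay` is the shortest delay present; its cells anchor the
    theory curves as a model-independent baseline.
    """

    points: pd.DataFrame
    baseline_delay: float

    def __post_init__(self) -> None:
        pts = self.points
        if pts.duplicated(subset=["set_size", "delay_s"]).any():
            raise ValueError("duplicate (set_size, delay_s) cells")
        for k in pts["set_size"].unique():
            delays = pts.loc[pts["set_size"] == k, "delay_s"]
            if self.baseline_delay not in delays.values:
                raise ValueError(
                    f"baseline delay {self.baseline_delay} missing for set size {k}"
                )

    @property
    def set_sizes(self) -> np.ndarray:
        return np.sort(self.points["set_size"].unique())

    @property
    def delays(self) -> np.ndarray:
        return np.sort(self.points["delay_s"].unique())

    def cell(self, set_size: int, delay_s: float) -> pd.Series:
        match = self.points[
            (self.points["set_size"] == set_size)
            & np.isclose(self.points["delay_s"], delay_s)
        ]
        if match.empty:
            raise KeyError(f"no cell (K={set_size}, T={delay_s})")
        return match.iloc[0]

    def baseline(self, set_size: int) -> float:
        """Empirical mse_norm at the shortest delay for this set size."""
        return float(self.cell(set_size, self.baseline_delay)["mse_norm"])

    def without_subjects(self, trials: pd.DataFrame, drop: list) -> "PerformanceTable":
        """Rebuild the table from `trials` with the given subjects removed."""
        kept = trials[~trials["subject"].isin(drop)]
        if kept.empty:
            raise ValueError("removing subjects emptied the trial table")
        return performance_table(kept)


def performance_table(
    trials: pd.DataFrame, pool_trials: bool = False
) -> PerformanceTable:
    """Summarize a trial table into per-(K, T) performance points.

    By default the cell MSE is the unweighted mean of per-subject means
    (matching an SEM defined across participants).  With ``pool_trials``
    the cell MSE is instead the plain mean over all trials pooled.
    """
    if trials.empty:
        raise ValueError("trial table is empty")
    df = trials.copy()
    df["sq_err_norm"] = squared_error_norm(
        df["target_deg"].to_numpy(), df["response_deg"].to_numpy()
    )

    rows = []
    for (k, t), cell in df.groupby(["set_size", "delay_s"], sort=True):
        subj_means = cell.groupby("subject")["sq_err_norm"].mean()
        n_subj = len(subj_means)
        if pool_trials:
            mse = float(cell["sq_err_norm"].mean())
        else:
            mse = float(subj_means.mean())
        sem = (
            float(subj_means.std(ddof=1) / np.sqrt(n_subj)) if n_subj > 1 else np.nan
        )
        var = float(cell["sq_err_norm"].var(ddof=1)) if len(cell) > 1 else np.nan
        rows.append(
            {
                "set_size": int(k),
                "delay_s": float(t),
                "mse_norm": mse,
                "sem_norm": sem,
                "var_norm": var,
                "n_trials": int(len(cell)),
                "n_subjects": n_subj,
            }
        )
    points = pd.DataFrame(rows)
    return PerformanceTable(points=points, baseline_delay=float(points["delay_s"].min()))
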