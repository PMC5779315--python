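"""Likelihood-based model comparison and pointwise goodness-of-fit.

Both storage models predict, for every (set size, delay) cell, the mean of
the per-trial normalized squared recall error.  The model likelihood treats
each trial's squared error as a Gaussian observation centered on the
model's anchored cell prediction, with variance equal to the *empirical*
variance of the squared errors in that cell — shared by both models, so the
comparison isolates how well the means are predicted.

The information criterion used is ``BIC = -2*L + k*ln(2*pi*n)``; a
``standard`` penalty flag swaps in the textbook ``k*ln(n)``.  Either way
the model *difference* is unaffected by adding the same number of nuisance
parameters (e.g. the four anchored baselines) to both models.  A positive
``delta_bic = BIC(direct) - BIC(coded)`` favors the coded model; a margin
above 10 is conventionally read as very strong evidence.

Pointwise p-values ask how probable each cell's observed mean would be
under a Gaussian centered on the model prediction with the cell's SEM as
its scale — small values flag cells the model cannot explain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .empirical import PerformanceTable, squared_error_norm
from .fitting import CodedFit, DirectFit

__all__ = [
    "BicReport",
    "ComparisonReport",
    "point_pvalues",
    "trial_log_likelihood",
    "bic",
    "compare_models",
]


@dataclass(frozen=True)
class BicReport:
    log_likelihood: float
    n_params: int
    n_obs: int
    penalty: str
    bic: float


@dataclass(frozen=True)
class ComparisonReport:
    bic_direct: BicReport
    bic_coded: BicReport
    pvalues_direct: pd.DataFrame
    pvalues_coded: pd.DataFrame

    @property
    def delta_bic(self) -> float:
        """BIC(direct) - BIC(coded); positive favors the coded model."""
        return self.bic_direct.bic - self.bic_coded.bic


def point_pvalues(table: PerformanceTable, predictions: pd.DataFrame) -> pd.DataFrame:
    """Two-sided Gaussian p-value of each cell mean against its prediction.

    z = (mse_norm - pred) / sem_norm per (K, T > T0) cell;
    p = 2 * (1 - Phi(|z|)).  Cells with zero or undefined SEM get NaN.
    """
    pred_map = {
        (int(r["set_size"]), float(r["delay_s"])): float(r["pred_norm"])
        for _, r in predictions.iterrows()
    }
    rows = []
    for _, c in table.points.iterrows():
        k, t = int(c["set_size"]), float(c["delay_s"])
        if t <= table.baseline_delay:
            continue
        if (k, t) not in pred_map:
            raise KeyError(f"no prediction for cell (K={k}, T={t})")
        sem = float(c["sem_norm"])
        if not np.isfinite(sem) or sem == 0:
            z, p = np.nan, np.nan
        else:
            z = (float(c["mse_norm"]) - pred_map[(k, t)]) / sem
            p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"set_size": k, "delay_s": t, "z": z, "p": p})
    return pd.DataFrame(rows)


def trial_log_likelihood(
    trials: pd.DataFrame, predictions: pd.DataFrame, table: PerformanceTable
) -> float:
    """Gaussian log-likelihood of per-trial squared errors under a model.

    Each trial in cell (K, T) contributes ``log phi(x; mu, sigma^2)`` with x
    its normalized squared error, mu the model's anchored prediction for the
    cell, and sigma^2 the empirical variance of squared errors in that cell.
    All cells, including the anchored baseline (where both models coincide
    with the data), are included; the baseline terms cancel in any model
    difference.
    """
    pred_map = {
        (int(r["set_size"]), float(r["delay_s"])): float(r["pred_norm"])
        for _, r in predictions.iterrows()
    }
    x = squared_error_norm(
        trials["target_deg"].to_numpy(), trials["response_deg"].to_numpy()
    )
    total = 0.0
    grouped = pd.DataFrame(
        {"set_size": trials["set_size"], "delay_s": trials["delay_s"], "x": x}
    ).groupby(["set_size", "delay_s"])
    for (k, t), cell in grouped:
        key = (int(k), float(t))
        if key not in pred_map:
            raise KeyError(f"no prediction for cell (K={k}, T={t})")
        var = float(table.cell(int(k), float(t))["var_norm"])
        if not np.isfinite(var) or var <= 0:
            raise ValueError(f"cell (K={k}, T={t}) has no usable empirical variance")
        mu = pred_map[key]
        xs = cell["x"].to_numpy(float)
        total += float(
            -0.5 * len(xs) * math.log(2.0 * math.pi * var)
            - 0.5 * np.sum((xs - mu) ** 2) / var
        )
    return total


def bic(
    log_likelihood: float, n_params: int, n_obs: int, penalty: str = "2pin"
) -> BicReport:
    """Bayesian information criterion.

    ``penalty="2pin"`` uses ``k * ln(2*pi*n)``; ``penalty="standard"`` uses
    the textbook ``k * ln(n)``.  Model differences at equal k are identical
    under either convention.
    """
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    if n_params < 0:
        raise ValueError("n_params must be >= 0")
    if penalty == "2pin":
        pen = n_params * math.log(2.0 * math.pi * n_obs)
    elif penalty == "standard":
        pen = n_params * math.log(n_obs)
    else:
        raise ValueError(f"unknown penalty convention {penalty!r}")
    return BicReport(
        log_likelihood=log_likelihood,
        n_params=n_params,
        n_obs=n_obs,
        penalty=penalty,
        bic=-2.0 * log_likelihood + pen,
    )


def compare_models(
    trials: pd.DataFrame,
    table: PerformanceTable,
    direct_fit: DirectFit,
    coded_fit: CodedFit,
    count_baselines: bool = False,
    n_obs: int | None = None,
    penalty: str = "2pin",
) -> ComparisonReport:
    """Assemble the BIC comparison and pointwise p-values for both models.

    Parameter counts default to 1 (direct: rho) and 2 (coded: N and 1/2D);
    `count_baselines` adds the four anchored baseline values to each, which
    leaves delta_bic exactly unchanged.  `n_obs` defaults to the number of
    trials entering the likelihood; pass a per-cell count to reproduce
    penalty conventions based on observations per (K, T) pair.
    """
    cells_d = set(
        map(tuple, direct_fit.predictions[["set_size", "delay_s"]].to_numpy())
    )
    cells_c = set(map(tuple, coded_fit.predictions[["set_size", "delay_s"]].to_numpy()))
    if cells_d != cells_c:
        raise ValueError("the two fits cover different (K, T) cells")

    ll_direct = trial_log_likelihood(trials, direct_fit.predictions, table)
    ll_coded = trial_log_likelihood(trials, coded_fit.predictions, table)
    k_direct, k_coded = 1, 2
    if count_baselines:
        n_baselines = len(table.set_sizes)
        k_direct += n_baselines
        k_coded += n_baselines
    n = int(n_obs) if n_obs is not None else int(len(trials))
    return ComparisonReport(
        bic_direct=bic(ll_direct, k_direct, n, penalty),
        bic_coded=bic(ll_coded, k_coded, n, penalty),
        pvalues_direct=point_pvalues(table, direct_fit.predictions),
        pvalues_coded=point_pvalues(table, coded_fit.predictions),
    )
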