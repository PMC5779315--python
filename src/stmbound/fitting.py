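"""Anchored weighted-least-squares fitting of both storage models.

Every theory curve is anchored: its value at the shortest delay T0 is pinned
to the empirical baseline for that set size, so the model only has to
explain the *increment* of error with storage time,

    pred(K, T) = mse(K, T0) + D_model(K, T) - D_model(K, T0).

The anchored cells contribute zero residual by construction and are excluded
from the objective.  The fit minimizes sum of w * (pred - mse)^2 over cells
with T > T0, where the default weight is the inverse SEM of the cell (an
inverse-variance option is provided).

The direct model has one free parameter, the resource rho = N/2D; the
residual is linear in theta = 1/rho, so the weighted fit has a closed form.
The coded model has two parameters (N, 1/2D); its objective is evaluated on
a log-spaced grid (the error surface), whose per-N column minima trace the
valley of near-optimal fits, and the grid argmin is refined by a local
simplex search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .empirical import PerformanceTable, performance_table
from .theory import coded_storage_mse_grid

__all__ = [
    "DirectFit",
    "CodedFit",
    "ErrorSurface",
    "anchored_prediction",
    "fit_direct",
    "fit_coded",
    "fit_direct_6item_ols",
    "jackknife_fits",
    "default_n_grid",
    "default_inv2d_grid",
]


def default_n_grid(n_points: int = 200) -> np.ndarray:
    """Log-spaced N grid on [1, 1e3]."""
    return np.logspace(0.0, 3.0, n_points)


def default_inv2d_grid(n_points: int = 200) -> np.ndarray:
    """Log-spaced 1/2D grid on [1e-2, 1e3] seconds."""
    return np.logspace(-2.0, 3.0, n_points)


@dataclass(frozen=True)
class DirectFit:
    """Direct-storage fit: single resource parameter rho = N/2D (seconds)."""

    rho: float
    wsse: float
    predictions: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise ValueError("fitted rho must be positive")


@dataclass(frozen=True)
class CodedFit:
    """Coded-storage fit: N networks of inverse diffusivity inv_2d seconds."""

    n_channels: float
    inv_2d: float
    wsse: float
    predictions: pd.DataFrame

    @property
    def resource(self) -> float:
        """Combined neural resource N/2D in seconds."""
        return self.n_channels * self.inv_2d


@dataclass(frozen=True)
class ErrorSurface:
    """WSSE landscape over the (N, 1/2D) grid with its valley.

    `wsse[i, j]` is the objective at ``(n_grid[i], inv2d_grid[j])``.  The
    valley is, for each N, the inv2D minimizing that row, tracing the
    one-dimensional locus of near-optimal trade-offs; `resource_curve`
    is N * inv2D along it.
    """

    n_grid: np.ndarray
    inv2d_grid: np.ndarray
    wsse: np.ndarray
    valley_inv2d: np.ndarray
    valley_wsse: np.ndarray

    @property
    def resource_curve(self) -> np.ndarray:
        return self.n_grid * self.valley_inv2d

    def argmin(self) -> tuple[float, float]:
        """Grid argmin; ties resolve to smallest N, then smallest 1/2D."""
        masked = np.where(np.isfinite(self.wsse), self.wsse, np.inf)
        i, j = np.unravel_index(np.argmin(masked), masked.shape)
        return float(self.n_grid[i]), float(self.inv2d_grid[j])


def _delay_increment_direct(
    theta: float, set_size: np.ndarray, delay: np.ndarray, t0: float, phi: float = 1.0
) -> np.ndarray:
    """D1(K,T) - D1(K,T0) = phi^2 * theta * K * (T - T0), theta = 2D/N."""
    return phi**2 * theta * set_size * (delay - t0)


def _delay_increment_coded(
    n_channels,
    inv_2d,
    set_size: int,
    delay: float,
    t0: float,
    phi: float = 1.0,
    anchor_mode: str = "difference",
):
    if anchor_mode == "difference":
        return coded_storage_mse_grid(
            n_channels, inv_2d, set_size, delay, phi
        ) - coded_storage_mse_grid(n_channels, inv_2d, set_size, t0, phi)
    if anchor_mode == "shifted-time":
        shifted = delay - t0
        if shifted <= 0:
            return np.zeros(np.broadcast(n_channels, inv_2d).shape)
        return coded_storage_mse_grid(n_channels, inv_2d, set_size, shifted, phi)
    raise ValueError(f"unknown anchor_mode {anchor_mode!r}")


def anchored_prediction(
    model_kind: str,
    params: dict,
    table: PerformanceTable,
    set_size: int,
    delay_s: float,
    anchor_mode: str = "difference",
) -> float:
    """Anchored model prediction for one (K, T) cell.

    `params` holds ``{"rho": ...}`` for the direct model or
    ``{"n_channels": ..., "inv_2d": ...}`` for the coded model.  At the
    baseline delay the prediction equals the empirical value exactly.
    """
    base = table.baseline(set_size)
    t0 = table.baseline_delay
    phi = params.get("phi", 1.0)
    if model_kind == "direct":
        theta = 1.0 / params["rho"]
        if anchor_mode not in {"difference", "shifted-time"}:
            raise ValueError(f"unknown anchor_mode {anchor_mode!r}")
        # the two anchoring conventions coincide for a curve linear in T
        inc = float(
            _delay_increment_direct(
                theta, np.asarray(set_size, float), np.asarray(delay_s, float), t0, phi
            )
        )
    elif model_kind == "coded":
        inc = float(
            _delay_increment_coded(
                np.asarray(params["n_channels"], float),
                np.asarray(params["inv_2d"], float),
                set_size,
                delay_s,
                t0,
                phi,
                anchor_mode,
            )
        )
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")
    return base + inc


def _fit_cells(
    table: PerformanceTable, weight: str, sem_floor: float, set_sizes=None
) -> pd.DataFrame:
    """Cells entering the objective (T > T0) with their weights."""
    pts = table.points
    mask = pts["delay_s"] > table.baseline_delay
    if set_sizes is not None:
        mask &= pts["set_size"].isin(set_sizes)
    cells = pts[mask].copy()
    if cells.empty:
        raise ValueError("no cells beyond the baseline delay to fit")
    if weight == "unit":
        cells["weight"] = 1.0
        return cells
    sem = cells["sem_norm"].to_numpy(float)
    if np.any(~np.isfinite(sem)) or np.any(sem + sem_floor <= 0):
        raise ValueError(
            "a cell has zero or undefined SEM; pass sem_floor > 0 to add a "
            "pseudocount to the weights"
        )
    sem = sem + sem_floor
    if weight == "inv_sem":
        cells["weight"] = 1.0 / sem
    elif weight == "inv_var":
        cells["weight"] = 1.0 / sem**2
    else:
        raise ValueError(f"unknown weight scheme {weight!r}")
    return cells


def _prediction_frame(
    table: PerformanceTable, model_kind: str, params: dict, anchor_mode: str
) -> pd.DataFrame:
    rows = []
    for _, p in table.points.iterrows():
        k, t = int(p["set_size"]), float(p["delay_s"])
        pred = anchored_prediction(model_kind, params, table, k, t, anchor_mode)
        rows.append(
            {
                "set_size": k,
                "delay_s": t,
                "mse_norm": p["mse_norm"],
                "pred_norm": pred,
                "residual": p["mse_norm"] - pred,
            }
        )
    return pd.DataFrame(rows)


def fit_direct(
    table: PerformanceTable,
    weight: str = "inv_sem",
    sem_floor: float = 0.0,
    phi: float = 1.0,
) -> DirectFit:
    """Fit the direct-storage model by anchored WLS; closed form.

    The anchored residual is linear in theta = 2D/N, so the weighted
    normal equation gives ``theta = sum(w x y) / sum(w x^2)`` with
    x = phi^2 K (T - T0) and y the empirical increment over baseline.
    Returns rho = 1/theta.
    """
    cells = _fit_cells(table, weight, sem_floor)
    t0 = table.baseline_delay
    k = cells["set_size"].to_numpy(float)
    t = cells["delay_s"].to_numpy(float)
    w = cells["weight"].to_numpy(float)
    y = cells["mse_norm"].to_numpy(float) - np.array(
        [table.baseline(int(kk)) for kk in k]
    )
    x = phi**2 * k * (t - t0)
    theta = float(np.sum(w * x * y) / np.sum(w * x * x))
    if theta <= 0:
        raise ValueError(
            "weighted fit gives a non-positive error growth rate; the data "
            "show no degradation with delay"
        )
    rho = 1.0 / theta
    resid = y - theta * x
    wsse = float(np.sum(w * resid**2))
    preds = _prediction_frame(table, "direct", {"rho": rho, "phi": phi}, "difference")
    return DirectFit(rho=rho, wsse=wsse, predictions=preds)


def fit_direct_6item_ols(
    table: PerformanceTable, set_size: int = 6, phi: float = 1.0
) -> DirectFit:
    """Direct-storage fit by ordinary least squares to one set-size curve only.

    Unit weights and residuals restricted to K = `set_size`, T > T0;
    predictions are still produced for every cell, which exposes how a fit
    driven by the steep large-K curve over-predicts small-K error.
    """
    cells = _fit_cells(table, "unit", 0.0, set_sizes=[set_size])
    t0 = table.baseline_delay
    k = cells["set_size"].to_numpy(float)
    t = cells["delay_s"].to_numpy(float)
    y = cells["mse_norm"].to_numpy(float) - table.baseline(set_size)
    x = phi**2 * k * (t - t0)
    theta = float(np.sum(x * y) / np.sum(x * x))
    if theta <= 0:
        raise ValueError("no degradation with delay in the selected curve")
    rho = 1.0 / theta
    wsse = float(np.sum((y - theta * x) ** 2))
    preds = _prediction_frame(table, "direct", {"rho": rho, "phi": phi}, "difference")
    return DirectFit(rho=rho, wsse=wsse, predictions=preds)


def _coded_wsse_grid(
    table: PerformanceTable,
    n_arr: np.ndarray,
    inv2d_arr: np.ndarray,
    cells: pd.DataFrame,
    phi: float,
    anchor_mode: str,
) -> np.ndarray:
    """Vectorized WSSE over broadcastable (N, 1/2D) arrays."""
    t0 = table.baseline_delay
    total = np.zeros(np.broadcast(n_arr, inv2d_arr).shape)
    for _, c in cells.iterrows():
        k, t = int(c["set_size"]), float(c["delay_s"])
        pred = table.baseline(k) + _delay_increment_coded(
            n_arr, inv2d_arr, k, t, t0, phi, anchor_mode
        )
        total = total + c["weight"] * (pred - c["mse_norm"]) ** 2
    return total


def fit_coded(
    table: PerformanceTable,
    n_grid: np.ndarray | None = None,
    inv2d_grid: np.ndarray | None = None,
    weight: str = "inv_sem",
    sem_floor: float = 0.0,
    phi: float = 1.0,
    anchor_mode: str = "difference",
    refine: bool = True,
) -> tuple[ErrorSurface, CodedFit]:
    """Fit the coded-storage bound by grid search plus local refinement.

    Evaluates the WSSE on the full log-spaced (N, 1/2D) grid, extracts the
    per-N valley, and refines the grid argmin with a Nelder-Mead search in
    log-parameters.  Non-finite grid entries are excluded from the argmin.
    """
    if n_grid is None:
        n_grid = default_n_grid()
    if inv2d_grid is None:
        inv2d_grid = default_inv2d_grid()
    n_grid = np.asarray(n_grid, float)
    inv2d_grid = np.asarray(inv2d_grid, float)
    if n_grid.size == 0 or inv2d_grid.size == 0:
        raise ValueError("grids must be nonempty")

    cells = _fit_cells(table, weight, sem_floor)
    wsse = _coded_wsse_grid(
        table, n_grid[:, None], inv2d_grid[None, :], cells, phi, anchor_mode
    )
    masked = np.where(np.isfinite(wsse), wsse, np.inf)
    valley_j = np.argmin(masked, axis=1)
    surface = ErrorSurface(
        n_grid=n_grid,
        inv2d_grid=inv2d_grid,
        wsse=wsse,
        valley_inv2d=inv2d_grid[valley_j],
        valley_wsse=masked[np.arange(n_grid.size), valley_j],
    )

    n0, v0 = surface.argmin()
    best_n, best_v = n0, v0
    best_wsse = float(np.min(masked))
    if refine:

        def objective(log_params: np.ndarray) -> float:
            n, v = np.exp(log_params)
            val = _coded_wsse_grid(
                table, np.asarray(n), np.asarray(v), cells, phi, anchor_mode
            )
            return float(val) if np.isfinite(val) else 1e300

        res = optimize.minimize(
            objective,
            x0=np.log([n0, v0]),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-14, "maxiter": 2000},
        )
        if res.fun <= best_wsse:
            best_n, best_v = np.exp(res.x)
            best_wsse = float(res.fun)

    params = {"n_channels": float(best_n), "inv_2d": float(best_v), "phi": phi}
    preds = _prediction_frame(table, "coded", params, anchor_mode)
    fit = CodedFit(
        n_channels=float(best_n),
        inv_2d=float(best_v),
        wsse=best_wsse,
        predictions=preds,
    )
    return surface, fit


def jackknife_fits(
    trials: pd.DataFrame,
    model_kind: str,
    n_grid: np.ndarray | None = None,
    inv2d_grid: np.ndarray | None = None,
    weight: str = "inv_sem",
) -> pd.DataFrame:
    """Leave-one-subject-out refits.

    Returns one row per left-out subject with the refit parameters; the
    jackknife standard error of each parameter is attached as
    ``frame.attrs["jackknife_se"]``.
    """
    subjects = sorted(trials["subject"].unique())
    if len(subjects) < 3:
        raise ValueError("jackknife needs at least 3 subjects")
    rows = []
    for s in subjects:
        kept = trials[trials["subject"] != s]
        sub_table = performance_table(kept)
        if model_kind == "direct":
            f = fit_direct(sub_table, weight=weight)
            rows.append({"left_out": s, "rho": f.rho, "wsse": f.wsse})
        elif model_kind == "coded":
            _, f = fit_coded(sub_table, n_grid, inv2d_grid, weight=weight)
            rows.append(
                {
                    "left_out": s,
                    "n_channels": f.n_channels,
                    "inv_2d": f.inv_2d,
                    "resource": f.resource,
                    "wsse": f.wsse,
                }
            )
        else:
            raise ValueError(f"unknown model kind {model_kind!r}")
    frame = pd.DataFrame(rows)
    n = len(subjects)
    se = {}
    for col in frame.columns:
        if col in ("left_out", "wsse"):
            continue
        vals = frame[col].to_numpy(float)
        se[col] = math.sqrt((n - 1) / n * float(np.sum((vals - vals.mean()) ** 2)))
    frame.attrs["jackknife_se"] = se
    return frame
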