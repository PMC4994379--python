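"""Empirical fire-induced biomass-loss model.

Remaining live aboveground biomass after a single fire is modelled as
proportional to the pre-fire biomass, ``B_after = alpha * B_initial`` with
``alpha`` fitted on literature before/after census-plot pairs. Because the
compiled plot data carry measurement error on both axes, the slope and its
standard deviation are estimated with the York errors-in-variables
regression rather than ordinary least squares.

The through-origin York iteration used here updates

    W_i   = 1 / (sd_y_i^2 + b^2 sd_x_i^2)
    beta_i = W_i (x_i sd_y_i^2 + b y_i sd_x_i^2)      (adjusted abscissa)
    b     <- sum(W_i beta_i y_i) / sum(W_i beta_i x_i)

whose fixed point is the exact stationary point of the York chi-square
``sum_i W_i(b) (y_i - b x_i)^2``; the slope variance is
``1 / sum(W_i beta_i^2)``. With negligible x-errors this reduces to weighted
least squares through the origin; with dominant x-errors it reduces to the
inverse-regression limit ``sum y^2 / sum x y``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import BurnScarMap, Raster, check_shared_grid

CONVERGENCE_TOL = 1e-10
MAX_ITER = 500


@dataclass(frozen=True)
class PlotPair:
    """One before/after-fire biomass observation (Mg ha^-1) with 1-sigma errors."""

    b_initial: float
    b_after: float
    sd_initial: float
    sd_after: float

    def __post_init__(self):
        if self.b_initial < 0 or self.b_after < 0:
            raise ValueError("biomass values must be >= 0")
        if self.sd_initial <= 0 or self.sd_after <= 0:
            raise ValueError("error sds must be > 0 for the weighted fit")


@dataclass(frozen=True)
class LossModel:
    """Fitted biomass-retention slope alpha with uncertainty.

    ``alpha`` is the fraction of pre-fire biomass remaining alive after the
    fire (Mg Mg^-1); the fire-induced loss fraction is ``1 - alpha``.
    """

    alpha: float
    alpha_sd: float
    intercept: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha={self.alpha} outside the physical range (0, 1)")

    @property
    def alpha_bounds(self) -> tuple[float, float]:
        return (self.alpha - self.alpha_sd, self.alpha + self.alpha_sd)


def york_chi_square(pairs: list[PlotPair], slope: float, intercept: float = 0.0) -> float:
    """The errors-in-both-variables chi-square at a given line (oracle hook)."""
    x = np.array([p.b_initial for p in pairs])
    y = np.array([p.b_after for p in pairs])
    sx = np.array([p.sd_initial for p in pairs])
    sy = np.array([p.sd_after for p in pairs])
    w = 1.0 / (sy**2 + slope**2 * sx**2)
    return float(np.sum(w * (y - slope * x - intercept) ** 2))


def fit_york(pairs: list[PlotPair], through_origin: bool = True) -> LossModel:
    """Fit the retention slope with errors in both variables.

    Iterates until the slope changes by less than 1e-10; raises if the
    iteration has not converged after 500 steps or the x-spread is
    degenerate.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 plot pairs")
    x = np.array([p.b_initial for p in pairs], dtype=float)
    y = np.array([p.b_after for p in pairs], dtype=float)
    sx = np.array([p.sd_initial for p in pairs], dtype=float)
    sy = np.array([p.sd_after for p in pairs], dtype=float)
    if np.ptp(x) == 0 and (through_origin and np.all(x == 0)):
        raise ValueError("degenerate x-spread")
    if not through_origin and np.ptp(x) == 0:
        raise ValueError("degenerate x-spread")

    wx = 1.0 / sx**2
    wy = 1.0 / sy**2

    # OLS start
    if through_origin:
        b = float(np.dot(x, y) / np.dot(x, x))
    else:
        b = float(np.polyfit(x, y, 1)[0])

    for _ in range(MAX_ITER):
        w = wx * wy / (wx + b**2 * wy)
        if through_origin:
            beta = w * (x / wy + b * y / wx)
            denom = np.sum(w * beta * x)
            if denom == 0:
                raise ValueError("degenerate x-spread")
            b_new = float(np.sum(w * beta * y) / denom)
        else:
            xbar = np.sum(w * x) / np.sum(w)
            ybar = np.sum(w * y) / np.sum(w)
            u = x - xbar
            v = y - ybar
            beta = w * (u / wy + b * v / wx)
            denom = np.sum(w * beta * u)
            if denom == 0:
                raise ValueError("degenerate x-spread")
            b_new = float(np.sum(w * beta * v) / denom)
        if abs(b_new - b) < CONVERGENCE_TOL:
            b = b_new
            break
        b = b_new
    else:
        raise RuntimeError(f"York iteration did not converge in {MAX_ITER} steps")

    w = wx * wy / (wx + b**2 * wy)
    if through_origin:
        beta = w * (x / wy + b * y / wx)
        var_b = 1.0 / np.sum(w * beta**2)
        intercept = 0.0
    else:
        xbar = np.sum(w * x) / np.sum(w)
        ybar = np.sum(w * y) / np.sum(w)
        beta = w * ((x - xbar) / wy + b * (y - ybar) / wx)
        x_adj = xbar + beta
        xbar_adj = np.sum(w * x_adj) / np.sum(w)
        var_b = 1.0 / np.sum(w * (x_adj - xbar_adj) ** 2)
        intercept = float(ybar - b * xbar)

    return LossModel(alpha=b, alpha_sd=float(np.sqrt(var_b)), intercept=intercept)


def apply_loss(
    biomass: Raster, model: LossModel | float, burn: BurnScarMap
) -> tuple[Raster, Raster]:
    """Per-pixel after-fire biomass and fire-induced loss (Mg ha^-1).

    Burned pixels retain ``alpha`` of their pre-fire biomass and lose
    ``1 - alpha``; unburned pixels are untouched (loss 0). Returns
    ``(b_after, loss)`` rasters on the input grid.
    """
    alpha = model if isinstance(model, (int, float)) else model.alpha
    check_shared_grid(biomass, burn.as_raster())
    b = np.asarray(biomass.data, dtype=float)
    if np.any(b < 0):
        raise ValueError("negative biomass input")
    burned = burn.burned
    b_after = np.where(burned, alpha * b, b)
    loss = np.where(burned, (1.0 - alpha) * b, 0.0)
    return biomass.with_data(b_after), biomass.with_data(loss)


def read_plot_pairs(path) -> list[PlotPair]:
    """Load plot pairs from CSV (columns b_initial, b_after, sd_initial, sd_after)."""
    df = pd.read_csv(path)
    return [
        PlotPair(r.b_initial, r.b_after, r.sd_initial, r.sd_after)
        for r in df.itertuples()
    ]


def write_plot_pairs(pairs: list[PlotPair], path) -> None:
    pd.DataFrame(
        [(p.b_initial, p.b_after, p.sd_initial, p.sd_after) for p in pairs],
        columns=["b_initial", "b_after", "sd_initial", "sd_after"],
    ).to_csv(path, index=False)


def model_report(model: LossModel) -> str:
    lo, hi = model.alpha_bounds
    return (
        "fire-induced biomass-loss model\n"
        f"  retention slope alpha : {model.alpha:.4f} Mg Mg^-1\n"
        f"  slope sd              : {model.alpha_sd:.4f}\n"
        f"  slope bounds          : ({lo:.4f}, {hi:.4f})\n"
        f"  intercept             : {model.intercept:.4f} Mg ha^-1\n"
        f"  loss fraction (1-a)   : {1 - model.alpha:.4f}\n"
    )
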