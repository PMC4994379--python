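"""Monte Carlo propagation of input uncertainties through the emission model.

Continuous inputs (the biomass-retention slope and the per-pixel biomass)
are perturbed with Gaussian draws at their stated 1-sigma errors;
categorical inputs (land-cover class, burned/unburned flag) are perturbed
by a uniform-threshold rule at the map accuracies: a pixel keeps its class
with probability equal to the land-cover accuracy (otherwise it is
reassigned frequency-weighted among the other classes, preserving the
marginal class distribution), and a burned pixel keeps its flag with the
class-appropriate burn-map accuracy (omission only — commission locations
are not invented). Each repetition reruns the full per-class bookkeeping;
the trace yields means and standard deviations per class and for totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .emissions import EmissionConfig, compute_class_emissions, records_to_frame
from .grids import BurnScarMap, Raster
from .lossmodel import LossModel, apply_loss


@dataclass
class McConfig:
    """Repetition count, input standard errors and map accuracies."""

    n_reps: int = 100
    slope_sd: float = reference.LOSS_SLOPE_SD
    landcover_accuracy: float = reference.LANDCOVER_ACCURACY
    burn_accuracy_forest: float = reference.BURN_ACCURACY_FOREST
    burn_accuracy_nonforest: float = reference.BURN_ACCURACY_NONFOREST
    vary_slope: bool = True
    vary_biomass: bool = True
    vary_landcover: bool = True
    vary_burn: bool = True
    forest_classes: frozenset[int] = field(default_factory=reference.forest_classes)
    seed: int = 0

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        for acc in (self.landcover_accuracy, self.burn_accuracy_forest,
                    self.burn_accuracy_nonforest):
            if not (0.0 < acc <= 1.0):
                raise ValueError("accuracies must lie in (0, 1]")


@dataclass
class McResult:
    """Per-rep trace plus mean/sd summaries (Tg C)."""

    trace: pd.DataFrame  # index rep, columns (class_code|total, metric)
    summary: pd.DataFrame  # index class_code|'total', columns mean/sd per metric

    def total_sd(self, metric: str = "total_c_tg") -> float:
        return float(self.summary.loc["total", (metric, "sd")])

    def total_mean(self, metric: str = "total_c_tg") -> float:
        return float(self.summary.loc["total", (metric, "mean")])


def perturb_continuous(
    alpha: float,
    biomass: Raster,
    error: Raster,
    rng: np.random.Generator,
    slope_sd: float = reference.LOSS_SLOPE_SD,
    vary_slope: bool = True,
    vary_biomass: bool = True,
) -> tuple[float, Raster]:
    """Gaussian draws of the slope and the per-pixel biomass (truncated at 0)."""
    if np.any(error.data < 0):
        raise ValueError("error raster must be >= 0")
    a = alpha
    if vary_slope and slope_sd > 0:
        a = float(rng.normal(alpha, slope_sd))
    b = biomass
    if vary_biomass and np.any(error.data > 0):
        draws = rng.normal(biomass.data, error.data)
        b = biomass.with_data(np.clip(draws, 0.0, None))
    return a, b


def perturb_categorical(
    landcover: Raster,
    burn: BurnScarMap,
    config: McConfig,
    rng: np.random.Generator,
) -> tuple[Raster, BurnScarMap]:
    """Uniform-threshold misclassification of class labels and burn flags."""
    lc = landcover.data
    new_lc = lc
    if config.vary_landcover and config.landcover_accuracy < 1.0:
        codes, counts = np.unique(lc, return_counts=True)
        freq = counts / counts.sum()
        flip = rng.uniform(size=lc.shape) > config.landcover_accuracy
        new_lc = lc.copy()
        if len(codes) > 1:
            flat = np.flatnonzero(flip)
            for i, code in enumerate(codes):
                # reassign among the *other* classes, weighted by their share
                sel = flat[lc.ravel()[flat] == code]
                if len(sel) == 0:
                    continue
                p = freq.copy()
                p[i] = 0.0
                p /= p.sum()
                new_lc.ravel()[sel] = rng.choice(codes, size=len(sel), p=p)
    month = burn.month
    new_month = month
    if config.vary_burn and (
        config.burn_accuracy_forest < 1.0 or config.burn_accuracy_nonforest < 1.0
    ):
        is_forest = np.isin(new_lc, list(config.forest_classes))
        acc = np.where(is_forest, config.burn_accuracy_forest,
                       config.burn_accuracy_nonforest)
        clear = (month > 0) & (rng.uniform(size=month.shape) > acc)
        new_month = month.copy()
        new_month[clear] = 0
    return (
        landcover.with_data(new_lc),
        BurnScarMap(new_month, burn.pixel_size_m, burn.origin),
    )


_METRICS = ("gross_c_tg", "committed_c_tg", "total_c_tg")


def run_mc(
    landcover: Raster,
    biomass: Raster,
    biomass_error: Raster,
    burn: BurnScarMap,
    loss_model: LossModel | float,
    mc_config: McConfig | None = None,
    emission_config: EmissionConfig | None = None,
) -> McResult:
    """Repeat the full emission computation on independently perturbed inputs."""
    mc_config = mc_config or McConfig()
    emission_config = emission_config or EmissionConfig()
    alpha = loss_model if isinstance(loss_model, (int, float)) else loss_model.alpha
    ss = np.random.SeedSequence([mc_config.seed, 7])
    rep_seeds = ss.spawn(mc_config.n_reps)
    rows = []
    for rep in range(mc_config.n_reps):
        rng = np.random.default_rng(rep_seeds[rep])
        try:
            a, b = perturb_continuous(
                alpha, biomass, biomass_error, rng,
                slope_sd=mc_config.slope_sd,
                vary_slope=mc_config.vary_slope,
                vary_biomass=mc_config.vary_biomass,
            )
            lc, bn = perturb_categorical(landcover, burn, mc_config, rng)
            # draws outside (0,1) are unphysical retention values; clamp into
            # the open interval rather than discard the repetition
            a = min(max(a, 1e-6), 1.0 - 1e-6)
            _, loss = apply_loss(b, a, bn)
            records = compute_class_emissions(loss, lc, bn, emission_config, biomass=b)
        except Exception as exc:  # pragma: no cover
            raise RuntimeError(f"Monte Carlo repetition {rep} failed") from exc
        row = {}
        for r in records:
            for m in _METRICS:
                row[(r.class_code, m)] = getattr(r, m)
        for m in _METRICS:
            row[("total", m)] = sum(getattr(r, m) for r in records)
        rows.append(row)
    trace = pd.DataFrame(rows)
    trace.columns = pd.MultiIndex.from_tuples(trace.columns, names=["class_code", "metric"])
    trace.index.name = "rep"
    summary = pd.concat(
        {"mean": trace.mean(axis=0), "sd": trace.std(axis=0, ddof=1)}, axis=1
    )
    summary.index = pd.MultiIndex.from_tuples(summary.index)
    summary = summary.unstack(level=1)
    # columns -> (metric, mean|sd)
    summary.columns = summary.columns.swaplevel(0, 1)
    summary = summary.sort_index(axis=1)
    return McResult(trace=trace, summary=summary)


def deterministic_records(
    landcover: Raster,
    biomass: Raster,
    burn: BurnScarMap,
    loss_model: LossModel | float,
    emission_config: EmissionConfig | None = None,
):
    """The unperturbed emission computation the MC is centred on."""
    _, loss = apply_loss(biomass, loss_model, burn)
    return compute_class_emissions(
        loss, landcover, burn, emission_config or EmissionConfig(), biomass=biomass
    )


def summary_to_csv(result: McResult, path) -> None:
    flat = result.summary.copy()
    flat.columns = [f"{metric}_{stat}" for metric, stat in flat.columns]
    flat.index.name = "class_code"
    flat.to_csv(path)
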