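"""Active-fire filtering and fire-count -> burned-area regional scaling.

High-confidence active-fire detections (confidence strictly above 80) that
fall inside mapped burn scars are counted per land-cover class and month.
Per burned-forest polygon, the pair (fire count, burned area in ha) feeds a
weighted least squares (WLS) regression whose weights come from a
preliminary ordinary least squares fit: samples are grouped by fitted
value, each group is weighted by the inverse of its residual variance, and
the weighted refit yields the slope, intercept and prediction intervals
used to extrapolate old-growth-forest burned area (and hence emissions)
beyond the mapped region.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage

from . import reference
from .grids import STRUCT_4, BurnScarMap, Raster, check_shared_grid

DEFAULT_MIN_CONFIDENCE = 80.0
DEFAULT_N_GROUPS = 5


@dataclass(frozen=True)
class ActiveFireRecord:
    """One thermal-anomaly detection: map coordinates, date, confidence."""

    x: float
    y: float
    month: int
    day: int
    confidence: float

    def __post_init__(self):
        if not (0.0 <= self.confidence <= 100.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 100]")


def _to_rowcol(rec: ActiveFireRecord, pixel_size_m: float,
               origin: tuple[float, float]) -> tuple[int, int]:
    col = int((rec.x - origin[0]) // pixel_size_m)
    row = int((rec.y - origin[1]) // pixel_size_m)
    return row, col


def filter_fires(
    records: list[ActiveFireRecord],
    burn: BurnScarMap,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> list[ActiveFireRecord]:
    """Retain detections with confidence strictly above the threshold that
    fall on a burned pixel."""
    rows, cols = burn.shape
    burned = burn.burned
    out = []
    for rec in records:
        if rec.confidence <= min_confidence:
            continue
        r, c = _to_rowcol(rec, burn.pixel_size_m, burn.origin)
        if 0 <= r < rows and 0 <= c < cols and burned[r, c]:
            out.append(rec)
    return out


def count_by_class_month(
    records: list[ActiveFireRecord], landcover: Raster
) -> pd.DataFrame:
    """Detection counts per land-cover class (rows) and month (columns),
    with marginal totals in a ``total`` row/column."""
    rows, cols = landcover.shape
    entries = []
    for rec in records:
        r, c = _to_rowcol(rec, landcover.pixel_size_m, landcover.origin)
        if 0 <= r < rows and 0 <= c < cols:
            entries.append((int(landcover.data[r, c]), rec.month))
    if entries:
        df = pd.DataFrame(entries, columns=["class_code", "month"])
        table = pd.crosstab(df["class_code"], df["month"])
    else:
        table = pd.DataFrame()
    table["total"] = table.sum(axis=1) if len(table.columns) else 0
    table.loc["total"] = table.sum(axis=0)
    return table


@dataclass
class WlsModel:
    """Fitted fire-count -> burned-area (ha) regression with group weights."""

    slope: float
    intercept: float
    slope_sd: float
    intercept_sd: float
    group_weights: np.ndarray  # weight of each group, 1/residual-variance
    group_edges: np.ndarray  # x-boundaries between groups (len n_groups-1)
    n_groups: int
    confidence: float = 0.95
    exact_fit: bool = False
    _results: object = field(default=None, repr=False)

    def slope_interval(self) -> tuple[float, float]:
        from scipy import stats

        df = int(self._results.df_resid)
        t = stats.t.ppf(0.5 + self.confidence / 2.0, df)
        return (self.slope - t * self.slope_sd, self.slope + t * self.slope_sd)

    def weight_for(self, fire_count: float) -> float:
        g = int(np.searchsorted(self.group_edges, fire_count, side="right"))
        return float(self.group_weights[g])


def fit_wls(
    samples: list[tuple[float, float]] | np.ndarray,
    n_groups: int = DEFAULT_N_GROUPS,
    confidence: float = 0.95,
) -> WlsModel:
    """Weighted least squares with OLS-derived inverse-variance group weights.

    A preliminary OLS fit orders the samples by fitted value; they are split
    into ``n_groups`` equal-size groups and each group's weight is the
    reciprocal of its OLS residual variance. If every group's residual
    variance is ~0 (an exact line) the fit degenerates gracefully to uniform
    weights with ``exact_fit`` set; a mix of zero- and nonzero-variance
    groups raises.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("samples must be (fire_count, burned_area_ha) pairs")
    if arr.shape[0] < 2 * n_groups:
        raise ValueError(f"need >= {2 * n_groups} samples for {n_groups} groups")
    x, y = arr[:, 0], arr[:, 1]
    X = sm.add_constant(x)
    ols = sm.OLS(y, X).fit()
    resid = ols.resid
    order = np.argsort(ols.fittedvalues, kind="stable")
    groups = np.array_split(order, n_groups)
    gvar = np.array([np.var(resid[g], ddof=1) for g in groups])
    scale = np.mean(np.abs(y)) if np.mean(np.abs(y)) > 0 else 1.0
    tiny = (1e-12 * scale) ** 2
    if np.all(gvar <= tiny):
        weights_g = np.ones(n_groups)
        exact = True
        gvar = np.ones(n_groups)
    elif np.any(gvar <= tiny):
        raise ValueError("a group has zero residual variance: degenerate grouping")
    else:
        weights_g = 1.0 / gvar
        exact = False
    w = np.empty(len(x))
    for gi, g in enumerate(groups):
        w[g] = weights_g[gi]
    wls = sm.WLS(y, X, weights=w).fit()
    # x-boundaries between consecutive groups (fitted value is monotone in x
    # up to the OLS slope sign)
    gx_sorted = [np.sort(x[g]) for g in groups]
    group_order = np.argsort([gx.mean() for gx in gx_sorted])
    edges = []
    for a, b in zip(group_order[:-1], group_order[1:]):
        edges.append(0.5 * (gx_sorted[a][-1] + gx_sorted[b][0]))
    return WlsModel(
        slope=float(wls.params[1]),
        intercept=float(wls.params[0]),
        slope_sd=float(wls.bse[1]),
        intercept_sd=float(wls.bse[0]),
        group_weights=weights_g[group_order],
        group_edges=np.array(edges),
        n_groups=n_groups,
        confidence=confidence,
        exact_fit=exact,
        _results=wls,
    )


def predict_area(model: WlsModel, fire_count: float) -> tuple[float, tuple[float, float]]:
    """Extrapolated burned area (ha) and its prediction interval.

    The new observation's variance uses the weight of the fitted-value group
    its count falls into; the extrapolated area is floored at zero.
    """
    if fire_count < 0:
        raise ValueError("fire count must be >= 0")
    exog = np.array([[1.0, fire_count]])
    w = model.weight_for(fire_count)
    pred = model._results.get_prediction(exog, weights=np.array([w]))
    frame = pred.summary_frame(alpha=1.0 - model.confidence)
    area = float(frame["mean"].iloc[0])
    lo = float(frame["obs_ci_lower"].iloc[0])
    hi = float(frame["obs_ci_upper"].iloc[0])
    return max(area, 0.0), (max(lo, 0.0), max(hi, 0.0))


@dataclass
class ScaledEmissions:
    """Extrapolated forest fire emissions with slope-bound uncertainty (Tg C)."""

    area_ha: float
    total_c_tg: float
    total_bounds_tg: tuple[float, float]
    gross_c_tg: float
    gross_bounds_tg: tuple[float, float]


def scale_emissions(
    area_ha: float,
    mean_forest_biomass: float,
    alpha: float = reference.LOSS_SLOPE,
    slope_bounds: tuple[float, float] = reference.LOSS_SLOPE_BOUNDS,
    carbon_fraction: float = reference.CARBON_FRACTION,
    decay_rate_k: float = reference.DECAY_RATE_K,
) -> ScaledEmissions:
    """Carbon emissions of extrapolated old-growth-forest burned area.

    Total C (Tg) = carbon_fraction x (1 - alpha) x biomass x area / 1e6;
    the forest pathway is decay-only, so the in-year gross flux is
    total x (1 - exp(-k)). Bounds vary the retention slope over its
    fitted range (a smaller slope means more loss, hence the upper bound).
    """
    if area_ha < 0 or mean_forest_biomass < 0:
        raise ValueError("area and biomass must be >= 0")

    def total_for(a: float) -> float:
        return carbon_fraction * (1.0 - a) * mean_forest_biomass * area_ha / 1e6

    year1 = 1.0 - math.exp(-decay_rate_k)
    total = total_for(alpha)
    t_hi = total_for(min(slope_bounds))
    t_lo = total_for(max(slope_bounds))
    return ScaledEmissions(
        area_ha=area_ha,
        total_c_tg=total,
        total_bounds_tg=(t_lo, t_hi),
        gross_c_tg=total * year1,
        gross_bounds_tg=(t_lo * year1, t_hi * year1),
    )


def forest_polygon_samples(
    burn: BurnScarMap,
    landcover: Raster,
    records: list[ActiveFireRecord],
    forest_classes: frozenset[int] | None = None,
) -> np.ndarray:
    """(fire count, burned area ha) per burned-forest polygon.

    Burned connected components whose majority class is forest form the
    regression sampling units; each polygon's count is the number of
    filtered detections falling on it.
    """
    check_shared_grid(burn.as_raster(), landcover)
    forest_classes = forest_classes or reference.forest_classes()
    labels, n = ndimage.label(burn.burned, structure=STRUCT_4)
    if n == 0:
        return np.empty((0, 2))
    counts = np.zeros(n + 1)
    rows, cols = burn.shape
    for rec in records:
        r, c = _to_rowcol(rec, burn.pixel_size_m, burn.origin)
        if 0 <= r < rows and 0 <= c < cols and labels[r, c] > 0:
            counts[labels[r, c]] += 1
    samples = []
    for comp in range(1, n + 1):
        mask = labels == comp
        codes, cnt = np.unique(landcover.data[mask], return_counts=True)
        if int(codes[np.argmax(cnt)]) in forest_classes:
            samples.append((counts[comp], float(mask.sum()) * burn.pixel_area_ha))
    return np.asarray(samples)


# --- fire record I/O ----------------------------------------------------

def read_fires_csv(path) -> list[ActiveFireRecord]:
    df = pd.read_csv(path)
    return [
        ActiveFireRecord(r.x, r.y, int(r.month), int(r.day), r.confidence)
        for r in df.itertuples()
    ]


def write_fires_csv(records: list[ActiveFireRecord], path) -> None:
    pd.DataFrame(
        [(r.x, r.y, r.month, r.day, r.confidence) for r in records],
        columns=["x", "y", "month", "day", "confidence"],
    ).to_csv(path, index=False)


def write_fires_geojson(records: list[ActiveFireRecord], path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [r.x, r.y]},
            "properties": {"month": r.month, "day": r.day, "confidence": r.confidence},
        }
        for r in records
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_fires_geojson(path) -> list[ActiveFireRecord]:
    with open(path) as fh:
        doc = json.load(fh)
    out = []
    for feat in doc.get("features", []):
        x, y = feat["geometry"]["coordinates"]
        p = feat["properties"]
        out.append(ActiveFireRecord(x, y, int(p["month"]), int(p["day"]),
                                    float(p["confidence"])))
    return out
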