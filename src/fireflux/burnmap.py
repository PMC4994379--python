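"""Burn-scar mapping from multi-date RED/NIR/SWIR reflectance.

The chain per acquisition date: (1) linear spectral unmixing of each pixel
into vegetation / soil / shade endmember fractions under sum-to-one and
non-negativity constraints; (2) region-growing segmentation of the shade
fraction (fresh burn scars are dark, so shade is the diagnostic band);
(3) unsupervised two-cluster labelling of region mean shade, with the
high-shade cluster labelled burned subject to an absolute shade floor; and
(4) accumulation across dates into a cumulative map holding each pixel's
first-burn month. A minimum mapping unit (4 pixels = 25 ha at 250 m)
removes sub-resolution speckle.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import PIXEL_AREA_HA, STRUCT_4, BurnScarMap, Raster

BANDS = ("RED", "NIR", "SWIR")

#: difference threshold on the 0-255 rescaled shade image ("similarity up to eighth")
DEFAULT_SIMILARITY_DN = 8

#: minimum region / mapping-unit size in pixels (25 ha at 250 m)
DEFAULT_MIN_AREA_PX = 4

#: shade fraction below which no region is called burned
DEFAULT_BURN_SHADE_FLOOR = 0.5


@dataclass(frozen=True)
class EndmemberSet:
    """Reference spectra of the three scene components, reflectance per band.

    Rows are (vegetation, soil, shade); columns are (RED, NIR, SWIR).
    """

    vegetation: tuple[float, float, float]
    soil: tuple[float, float, float]
    shade: tuple[float, float, float]

    def matrix(self) -> np.ndarray:
        """Bands x endmembers mixing matrix E, so reflectance = E @ fractions."""
        return np.column_stack([self.vegetation, self.soil, self.shade]).astype(float)

    def validate(self) -> None:
        m = self.matrix()
        if m.shape != (3, 3):
            raise ValueError("need 3 endmembers with 3 bands each")
        if np.linalg.matrix_rank(m) < 3:
            raise ValueError("endmember matrix is rank deficient")


#: default spectra: green vegetation, dry bright soil, dark shade/burn
DEFAULT_ENDMEMBERS = EndmemberSet(
    vegetation=(0.04, 0.45, 0.20),
    soil=(0.25, 0.35, 0.42),
    shade=(0.02, 0.03, 0.02),
)


@dataclass
class FractionImage:
    """Per-pixel (f_veg, f_soil, f_shade), each in [0,1], summing to 1."""

    fractions: np.ndarray  # (rows, cols, 3)
    pixel_size_m: float = 250.0
    origin: tuple[float, float] = (0.0, 0.0)

    @property
    def shade(self) -> np.ndarray:
        return self.fractions[..., 2]

    @property
    def vegetation(self) -> np.ndarray:
        return self.fractions[..., 0]

    @property
    def soil(self) -> np.ndarray:
        return self.fractions[..., 1]


def unmix(image: Raster, endmembers: EndmemberSet = DEFAULT_ENDMEMBERS) -> FractionImage:
    """Constrained linear spectral unmixing of a 3-band raster.

    Minimises the squared reflectance residual per pixel subject to the
    fractions being non-negative and summing to one. The solution is exact:
    the equality-constrained minimiser is taken where it is feasible, and
    otherwise the best point on the boundary of the 2-simplex (an edge
    between two endmembers, with clipping to the vertices).
    """
    endmembers.validate()
    if image.n_bands != 3:
        raise ValueError(f"expected 3 bands (RED, NIR, SWIR), got {image.n_bands}")
    E = endmembers.matrix()
    rows, cols = image.shape
    r = image.data.reshape(-1, 3).astype(float)  # (n, bands)

    # interior: minimise ||E f - r|| s.t. 1'f = 1 via KKT (4x4 system)
    EtE = E.T @ E
    kkt = np.zeros((4, 4))
    kkt[:3, :3] = 2.0 * EtE
    kkt[:3, 3] = 1.0
    kkt[3, :3] = 1.0
    rhs = np.empty((4, r.shape[0]))
    rhs[:3] = 2.0 * (E.T @ r.T)
    rhs[3] = 1.0
    f = np.linalg.solve(kkt, rhs)[:3].T  # (n, 3)

    infeasible = (f < -1e-12).any(axis=1)
    if infeasible.any():
        ri = r[infeasible]
        best_f = None
        best_res = np.full(ri.shape[0], np.inf)
        # each edge of the simplex: f = t e_j + (1-t) e_k, t clipped to [0,1]
        for j, k in ((0, 1), (0, 2), (1, 2)):
            d = E[:, j] - E[:, k]
            t = (ri - E[:, k]) @ d / (d @ d)
            t = np.clip(t, 0.0, 1.0)
            cand = np.zeros((ri.shape[0], 3))
            cand[:, j] = t
            cand[:, k] = 1.0 - t
            res = np.sum((cand @ E.T - ri) ** 2, axis=1)
            better = res < best_res
            if best_f is None:
                best_f = cand
                best_res = res
            else:
                best_f[better] = cand[better]
                best_res[better] = res[better]
        f[infeasible] = best_f

    f = np.clip(f, 0.0, 1.0)
    f /= f.sum(axis=1, keepdims=True)
    return FractionImage(
        fractions=f.reshape(rows, cols, 3),
        pixel_size_m=image.pixel_size_m,
        origin=image.origin,
    )


@dataclass
class RegionMap:
    """Segmentation result: per-pixel region id (1-based) and a region table.

    The table is indexed by region id with columns ``count``, ``mean_shade``
    and ``var_shade``. Region ids partition the grid (no pixel unassigned
    after the minimum-area merge).
    """

    labels: np.ndarray
    table: pd.DataFrame


def _region_stats(labels: np.ndarray, shade: np.ndarray) -> pd.DataFrame:
    ids = np.arange(1, labels.max() + 1)
    count = np.bincount(labels.ravel(), minlength=labels.max() + 1)[1:]
    sums = np.bincount(labels.ravel(), weights=shade.ravel(), minlength=labels.max() + 1)[1:]
    sq = np.bincount(labels.ravel(), weights=(shade**2).ravel(), minlength=labels.max() + 1)[1:]
    keep = count > 0
    mean = np.where(keep, sums / np.maximum(count, 1), np.nan)
    var = np.where(keep, sq / np.maximum(count, 1) - mean**2, np.nan)
    df = pd.DataFrame(
        {"count": count, "mean_shade": mean, "var_shade": np.maximum(var, 0.0)},
        index=pd.Index(ids, name="region_id"),
    )
    return df[keep]


def segment_shade(
    shade: np.ndarray,
    min_area: int = DEFAULT_MIN_AREA_PX,
    similarity: float = DEFAULT_SIMILARITY_DN,
) -> RegionMap:
    """Region-growing segmentation of the shade-fraction grid.

    The shade image is rescaled to 0-255 digital numbers; a region grows
    over 4-connected neighbours whose DN differs from the running region
    mean by at most ``similarity``. Regions smaller than ``min_area`` pixels
    are merged into the adjacent region with the closest mean shade.
    """
    if min_area <= 0:
        raise ValueError("min_area must be positive")
    shade = np.asarray(shade, dtype=float)
    if not np.all(np.isfinite(shade)):
        raise ValueError("shade grid contains non-finite values")
    dn = np.rint(np.clip(shade, 0.0, 1.0) * 255.0)
    rows, cols = dn.shape
    labels = np.zeros((rows, cols), dtype=np.int32)
    next_id = 0

    for start in range(rows * cols):
        si, sj = divmod(start, cols)
        if labels[si, sj]:
            continue
        next_id += 1
        labels[si, sj] = next_id
        total, n = dn[si, sj], 1
        queue = deque([(si, sj)])
        while queue:
            i, j = queue.popleft()
            mean = total / n
            for ni, nj in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
                if 0 <= ni < rows and 0 <= nj < cols and not labels[ni, nj]:
                    if abs(dn[ni, nj] - mean) <= similarity:
                        labels[ni, nj] = next_id
                        total += dn[ni, nj]
                        n += 1
                        queue.append((ni, nj))

    labels = _merge_small_regions(labels, shade, min_area)
    return RegionMap(labels=labels, table=_region_stats(labels, shade))


def _adjacency_pairs(labels: np.ndarray) -> np.ndarray:
    """Unique (a, b) pairs of 4-adjacent distinct region ids."""
    pairs = []
    h = np.stack([labels[:, :-1].ravel(), labels[:, 1:].ravel()], axis=1)
    v = np.stack([labels[:-1, :].ravel(), labels[1:, :].ravel()], axis=1)
    for p in (h, v):
        p = p[p[:, 0] != p[:, 1]]
        pairs.append(p)
    if not pairs:
        return np.empty((0, 2), dtype=int)
    allp = np.vstack(pairs)
    allp = np.sort(allp, axis=1)
    return np.unique(allp, axis=0)


def _merge_small_regions(labels: np.ndarray, shade: np.ndarray, min_area: int) -> np.ndarray:
    """Absorb regions below min_area into the most-similar adjacent region.

    Each sweep merges every small region into its closest-mean neighbour
    simultaneously (merge targets resolved by pointer jumping, cycles
    collapsed to their smallest id), so the sweep count grows only
    logarithmically even on heavily fragmented noisy images.
    """
    while True:
        n = int(labels.max())
        count = np.bincount(labels.ravel(), minlength=n + 1)
        sums = np.bincount(labels.ravel(), weights=shade.ravel(), minlength=n + 1)
        mean = np.divide(sums, count, out=np.zeros(n + 1), where=count > 0)
        small = (count > 0) & (count < min_area)
        small[0] = False
        if not small.any() or (count > 0).sum() <= 1:
            break
        pairs = _adjacency_pairs(labels)
        if len(pairs) == 0:
            break
        edges = np.vstack([pairs, pairs[:, ::-1]])
        src, dst = edges[:, 0], edges[:, 1]
        keep = small[src]
        src, dst = src[keep], dst[keep]
        if len(src) == 0:
            break  # every small region is isolated (grid smaller than min_area)
        diff = np.abs(mean[src] - mean[dst])
        order = np.lexsort((diff, src))
        src_o, dst_o = src[order], dst[order]
        first = np.ones(len(src_o), dtype=bool)
        first[1:] = src_o[1:] != src_o[:-1]
        target = np.arange(n + 1)
        target[src_o[first]] = dst_o[first]
        # collapse mutual (2-cycle) merges to the smaller id
        mutual = (target[target] == np.arange(n + 1)) & (target != np.arange(n + 1))
        target[mutual] = np.minimum(target[mutual], np.arange(n + 1)[mutual])
        for _ in range(64):  # pointer jumping to fixed points
            nxt = target[target]
            if np.array_equal(nxt, target):
                break
            target = nxt
        else:  # rare longer cycles: walk them out explicitly
            for rid in np.flatnonzero(target[target] != target):
                seen = []
                r = rid
                while r not in seen:
                    seen.append(r)
                    r = target[r]
                root = min(seen)
                for s in seen:
                    target[s] = root
        labels = target[labels]
    # compact ids to 1..n
    uniq = np.unique(labels)
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    lut[uniq] = np.arange(1, len(uniq) + 1)
    return lut[labels]


def classify_regions(
    regions: RegionMap,
    shade: np.ndarray,
    floor: float = DEFAULT_BURN_SHADE_FLOOR,
    max_iter: int = 100,
) -> np.ndarray:
    """Label each region burned/unburned from its mean shade.

    Region means are split into two clusters by an iterative centroid
    procedure (1-D two-means, centroids initialised at the extremes);
    regions in the high-shade cluster whose own mean exceeds ``floor`` are
    burned. Returns a boolean per-pixel mask.
    """
    table = regions.table
    if len(table) == 0:
        raise ValueError("empty region table")
    means = table["mean_shade"].to_numpy()
    if means.max() < floor:
        return np.zeros_like(regions.labels, dtype=bool)
    c_lo, c_hi = float(means.min()), float(means.max())
    if c_hi - c_lo < 1e-12:
        high = np.ones(len(means), dtype=bool)
    else:
        for _ in range(max_iter):
            high = np.abs(means - c_hi) < np.abs(means - c_lo)
            new_lo = means[~high].mean() if (~high).any() else c_lo
            new_hi = means[high].mean() if high.any() else c_hi
            if abs(new_lo - c_lo) < 1e-12 and abs(new_hi - c_hi) < 1e-12:
                break
            c_lo, c_hi = float(new_lo), float(new_hi)
    burned_ids = table.index[high & (means >= floor)]
    burned_lut = np.zeros(regions.labels.max() + 1, dtype=bool)
    burned_lut[burned_ids] = True
    return burned_lut[regions.labels]


def accumulate(
    maps_by_date: list[tuple[int, np.ndarray]],
    pixel_size_m: float = 250.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> BurnScarMap:
    """Combine per-date burn masks into a cumulative first-burn-month map.

    ``maps_by_date`` is an ordered list of (month, mask); months must be
    strictly increasing. A pixel's first-burn month is the earliest date at
    which it is flagged; later flags are ignored, so repeated burns of the
    same pixel are counted once.
    """
    if not maps_by_date:
        raise ValueError("no masks to accumulate")
    months = [m for m, _ in maps_by_date]
    if any(b <= a for a, b in zip(months, months[1:])):
        raise ValueError(f"dates not strictly increasing: {months}")
    first = maps_by_date[0][1]
    month_grid = np.zeros(first.shape, dtype=np.uint8)
    for month, mask in maps_by_date:
        if mask.shape != first.shape:
            raise ValueError("masks on different grids")
        newly = mask & (month_grid == 0)
        month_grid[newly] = month
    return BurnScarMap(month=month_grid, pixel_size_m=pixel_size_m, origin=origin)


def apply_min_mapping_unit(burn: BurnScarMap, min_ha: float = 25.0) -> BurnScarMap:
    """Remove burned connected components (4-connectivity) below ``min_ha``."""
    labels, n = ndimage.label(burn.burned, structure=STRUCT_4)
    if n == 0:
        return burn
    areas_ha = np.bincount(labels.ravel())[1:] * burn.pixel_area_ha
    drop = np.flatnonzero(areas_ha < min_ha) + 1
    month = burn.month.copy()
    if len(drop):
        month[np.isin(labels, drop)] = 0
    return BurnScarMap(month=month, pixel_size_m=burn.pixel_size_m, origin=burn.origin)


def map_burn_scars(
    images_by_month: list[tuple[int, Raster]],
    endmembers: EndmemberSet = DEFAULT_ENDMEMBERS,
    similarity: float = DEFAULT_SIMILARITY_DN,
    min_area: int = DEFAULT_MIN_AREA_PX,
    floor: float = DEFAULT_BURN_SHADE_FLOOR,
    min_mapping_unit_ha: float = 25.0,
) -> BurnScarMap:
    """Full chain: unmix -> segment -> classify per date, then accumulate."""
    masks = []
    pixel_size, origin = None, None
    for month, image in images_by_month:
        fr = unmix(image, endmembers)
        regions = segment_shade(fr.shade, min_area=min_area, similarity=similarity)
        masks.append((month, classify_regions(regions, fr.shade, floor=floor)))
        pixel_size, origin = image.pixel_size_m, image.origin
    burn = accumulate(masks, pixel_size_m=pixel_size, origin=origin)
    return apply_min_mapping_unit(burn, min_ha=min_mapping_unit_ha)
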