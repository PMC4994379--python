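"""Synthetic fire-season scene generator with known ground truth.

Builds complete scenes — land cover, aboveground biomass with an error map,
burn patches with first-burn months, multi-date RED/NIR/SWIR reflectance
composed from known endmember fractions, active-fire point records and
before/after-fire plot pairs — so that every downstream stage (unmixing,
segmentation, loss model, emission bookkeeping, Monte Carlo, scaling) can
be tested against exact truth without any satellite download.

Defaults reproduce the study conditions of the 2010 Mato Grosso fire
season: the 15-class legend with its published area shares and per-class
burned fractions, the published class biomass means and errors, a
September-dominated burn calendar, and 250 m pixels (6.25 ha).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import reference
from .burnmap import DEFAULT_ENDMEMBERS, EndmemberSet
from .grids import FIRE_SEASON_MONTHS, BurnScarMap, Raster
from .lossmodel import PlotPair
from .scaling import ActiveFireRecord

#: truth endmember fractions (veg, soil, shade) of unburned pixels per class
DEFAULT_CLASS_FRACTIONS: dict[int, tuple[float, float, float]] = {
    1: (0.80, 0.02, 0.18),
    2: (0.55, 0.25, 0.20),
    3: (0.50, 0.40, 0.10),
    4: (0.52, 0.38, 0.10),
    5: (0.48, 0.42, 0.10),
    6: (0.46, 0.44, 0.10),
    7: (0.20, 0.70, 0.10),
    8: (0.40, 0.50, 0.10),
    9: (0.42, 0.48, 0.10),
    10: (0.38, 0.52, 0.10),
    11: (0.36, 0.54, 0.10),
    12: (0.60, 0.28, 0.12),
    13: (0.75, 0.10, 0.15),
    14: (0.70, 0.15, 0.15),
    15: (0.30, 0.60, 0.10),
}

#: truth fractions of a fresh burn scar: shade-dominated
BURNED_FRACTIONS = (0.05, 0.05, 0.90)


@dataclass
class LandscapeConfig:
    """All knobs of the scene generator; identical seed => identical scene."""

    grid_rows: int = 400
    grid_cols: int = 400
    pixel_size_m: float = 250.0
    class_proportions: dict[int, float] = field(default_factory=reference.class_proportions)
    class_biomass_mean: dict[int, float] = field(
        default_factory=lambda: reference.class_table()["biomass_mean"].to_dict()
    )
    class_biomass_sd: dict[int, float] = field(
        default_factory=lambda: reference.class_table()["biomass_sd"].to_dict()
    )
    burn_fraction_by_class: dict[int, float] = field(
        default_factory=reference.burn_fraction_by_class
    )
    month_weights: dict[int, float] = field(default_factory=reference.month_weights)
    class_fractions: dict[int, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    # lognormal burn-patch sizes in pixels: heavy-tailed mix dominated by
    # large (>5 km^2 = 80 px) patches, as observed
    patch_size_log_mean: float = 3.5
    patch_size_log_sd: float = 1.2
    min_patch_px: int = 4
    mean_patch_px_landcover: float = 160.0  # ~10 km^2 land-cover polygons
    reflectance_noise_sd: float = 0.01
    fire_rate_per_patch: float = 5.0
    false_fire_fraction: float = 0.02
    confidence_range: tuple[float, float] = (50.0, 100.0)
    seed: int = 0

    def validate(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ValueError("empty grid")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        if any(m < 0 for m in self.class_biomass_mean.values()):
            raise ValueError("biomass means must be >= 0")
        if any(not (0.0 <= f <= 1.0) for f in self.burn_fraction_by_class.values()):
            raise ValueError("burn fractions must lie in [0, 1]")


@dataclass
class BurnPatch:
    """One connected truth burn patch."""

    class_code: int
    month: int
    pixels: np.ndarray  # flat indices into the grid

    @property
    def n_px(self) -> int:
        return len(self.pixels)


@dataclass
class SyntheticScene:
    """A complete scene with ground truth for every pipeline stage."""

    config: LandscapeConfig
    landcover: Raster
    biomass: Raster
    biomass_error: Raster
    truth_burn: BurnScarMap
    truth_fractions: np.ndarray  # unburned (rows, cols, 3)
    reflectance_by_month: list[tuple[int, Raster]]
    fires: list[ActiveFireRecord]
    patches: list[BurnPatch]

    def class_areas_km2(self) -> dict[int, float]:
        px_km2 = self.landcover.pixel_area_ha / 100.0
        codes, counts = np.unique(self.landcover.data, return_counts=True)
        return {int(c): float(n) * px_km2 for c, n in zip(codes, counts)}


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stage]))


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer quotas summing exactly to ``total``, proportional to weights."""
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base


def generate_landcover(config: LandscapeConfig) -> Raster:
    """Patchy class mosaic by quota-capped multi-source region growing.

    Seeds are placed on a jittered grid (blue-noise spacing), assigned
    class codes by exact quota, and grown breadth-first with randomised
    frontiers; a class stops claiming pixels once its area quota is met, so
    realised class shares track the requested proportions closely while the
    map stays spatially coherent.
    """
    config.validate()
    rows, cols = config.grid_rows, config.grid_cols
    n_px = rows * cols
    codes = np.array(sorted(config.class_proportions))
    props = np.array([config.class_proportions[c] for c in codes], dtype=float)
    rng = _rng(config.seed, 1)

    if len(codes) == 1:
        return Raster(np.full((rows, cols), codes[0], dtype=np.int16),
                      pixel_size_m=config.pixel_size_m)

    n_seeds = max(len(codes), int(round(n_px / config.mean_patch_px_landcover)))
    k = max(1, int(math.ceil(math.sqrt(n_seeds))))
    cell_r, cell_c = rows / k, cols / k
    seed_rc = []
    for i in range(k):
        for j in range(k):
            r = min(rows - 1, int(i * cell_r + rng.uniform(0, cell_r)))
            c = min(cols - 1, int(j * cell_c + rng.uniform(0, cell_c)))
            seed_rc.append((r, c))
    seed_rc = list(dict.fromkeys(seed_rc))  # dedupe collisions

    seed_quota = _largest_remainder(props, len(seed_rc))
    seed_classes = np.repeat(codes, seed_quota)
    rng.shuffle(seed_classes)

    quota = _largest_remainder(props, n_px)
    quota_by_code = dict(zip(codes.tolist(), quota.tolist()))

    lc = np.zeros((rows, cols), dtype=np.int16)
    count = {int(c): 0 for c in codes}
    from collections import deque

    queue = deque()
    order = rng.permutation(len(seed_rc))
    for idx in order:
        r, c = seed_rc[idx]
        queue.append((r, c, int(seed_classes[idx])))
    offsets = ((-1, 0), (1, 0), (0, -1), (0, 1))
    while queue:
        r, c, code = queue.popleft()
        if lc[r, c] != 0 or count[code] >= quota_by_code[code]:
            continue
        lc[r, c] = code
        count[code] += 1
        rot = int(rng.integers(4))
        for di, dj in offsets[rot:] + offsets[:rot]:
            nr, nc = r + di, c + dj
            if 0 <= nr < rows and 0 <= nc < cols and lc[nr, nc] == 0:
                queue.append((nr, nc, code))

    # pixels stranded by exhausted quotas: absorb into neighbouring classes
    while (lc == 0).any():
        grown = ndimage.grey_dilation(lc, footprint=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        fill = (lc == 0) & (grown > 0)
        if not fill.any():
            lc[lc == 0] = codes[np.argmax(props)]
            break
        lc[fill] = grown[fill]

    return Raster(lc, pixel_size_m=config.pixel_size_m)


def generate_biomass(landcover: Raster, config: LandscapeConfig) -> tuple[Raster, Raster]:
    """Per-pixel biomass from the class truncated-normal law, plus its 1-sigma map."""
    lc = landcover.data
    rng = _rng(config.seed, 2)
    biomass = np.zeros(lc.shape, dtype=float)
    error = np.zeros(lc.shape, dtype=float)
    for code in np.unique(lc):
        code = int(code)
        if code not in config.class_biomass_mean:
            raise KeyError(f"no biomass parameters for class {code}")
        mask = lc == code
        mean, sd = config.class_biomass_mean[code], config.class_biomass_sd[code]
        draws = rng.normal(mean, sd, size=int(mask.sum())) if sd > 0 else np.full(
            int(mask.sum()), mean
        )
        biomass[mask] = np.clip(draws, 0.0, None)
        error[mask] = sd
    return (
        landcover.with_data(biomass),
        landcover.with_data(error),
    )


def generate_burns(
    landcover: Raster, config: LandscapeConfig
) -> tuple[BurnScarMap, list[BurnPatch]]:
    """Connected burn patches with lognormal sizes and per-patch months.

    Patches grow inside their land-cover class until the class's requested
    burned fraction is met; every patch has at least ``min_patch_px``
    pixels. Months are drawn per patch from the (September-heavy) month
    weights.
    """
    lc = landcover.data
    rows, cols = lc.shape
    rng = _rng(config.seed, 3)
    month_codes = np.array(sorted(config.month_weights))
    month_p = np.array([config.month_weights[m] for m in month_codes], dtype=float)
    month_p /= month_p.sum()

    month_grid = np.zeros((rows, cols), dtype=np.uint8)
    patches: list[BurnPatch] = []
    flat_lc = lc.ravel()
    burned_flat = np.zeros(rows * cols, dtype=bool)

    for code in sorted(config.burn_fraction_by_class):
        frac = config.burn_fraction_by_class[code]
        if frac == 0:
            continue
        if frac > 1:
            raise ValueError(f"burn fraction {frac} exceeds class area for class {code}")
        class_idx = np.flatnonzero(flat_lc == code)
        if len(class_idx) == 0:
            continue
        target = int(round(frac * len(class_idx)))
        placed, failures = 0, 0
        while placed < target and failures < 50:
            remaining = target - placed
            if remaining < config.min_patch_px:
                break
            size = int(round(rng.lognormal(config.patch_size_log_mean,
                                           config.patch_size_log_sd)))
            size = max(config.min_patch_px, min(size, remaining))
            free = class_idx[~burned_flat[class_idx]]
            if len(free) < config.min_patch_px:
                break
            seed_px = int(rng.choice(free))
            patch = _grow_patch(seed_px, size, flat_lc, burned_flat, code, rows, cols, rng)
            if len(patch) < config.min_patch_px:
                failures += 1
                continue
            burned_flat[patch] = True
            month = int(rng.choice(month_codes, p=month_p))
            patches.append(BurnPatch(class_code=code, month=month,
                                     pixels=np.array(patch, dtype=np.int64)))
            placed += len(patch)

    for p in patches:
        month_grid.ravel()[p.pixels] = p.month

    # The burn map cannot represent features below the minimum mapping unit,
    # so the truth must not contain sub-minimum unburned enclaves: fill any
    # unburned island smaller than min_patch_px with the month of the patch
    # that surrounds it (attached to that patch).
    burned_mask = month_grid > 0
    if burned_mask.any():
        from .grids import STRUCT_4

        px_to_patch = {}
        for pi, p in enumerate(patches):
            for px in p.pixels:
                px_to_patch[int(px)] = pi
        unb_labels, k = ndimage.label(~burned_mask, structure=STRUCT_4.astype(int))
        sizes = np.bincount(unb_labels.ravel())
        for comp in range(1, k + 1):
            if sizes[comp] >= config.min_patch_px:
                continue
            hole = unb_labels == comp
            ring = ndimage.binary_dilation(hole, structure=STRUCT_4) & burned_mask
            ring_months = month_grid[ring]
            if len(ring_months) == 0:
                continue
            vals, cnts = np.unique(ring_months, return_counts=True)
            month = int(vals[np.argmax(cnts)])
            month_grid[hole] = month
            host = next(
                (px_to_patch[int(px)] for px in np.flatnonzero(ring.ravel())
                 if int(px) in px_to_patch and patches[px_to_patch[int(px)]].month == month),
                None,
            )
            hole_px = np.flatnonzero(hole.ravel())
            if host is not None:
                patches[host].pixels = np.concatenate([patches[host].pixels, hole_px])
            burned_mask |= hole

    burn = BurnScarMap(month=month_grid, pixel_size_m=config.pixel_size_m)
    return burn, patches


def _grow_patch(seed_px, size, flat_lc, burned_flat, code, rows, cols, rng) -> list[int]:
    """Randomised BFS growth of one patch inside its class, skipping burned px."""
    patch = [seed_px]
    in_patch = {seed_px}
    frontier = [seed_px]
    while len(patch) < size and frontier:
        i = int(rng.integers(len(frontier)))
        px = frontier[i]
        r, c = divmod(px, cols)
        nbrs = []
        for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= nr < rows and 0 <= nc < cols:
                npx = nr * cols + nc
                if npx not in in_patch and flat_lc[npx] == code and not burned_flat[npx]:
                    nbrs.append(npx)
        if not nbrs:
            frontier[i] = frontier[-1]
            frontier.pop()
            continue
        pick = nbrs[int(rng.integers(len(nbrs)))]
        patch.append(pick)
        in_patch.add(pick)
        frontier.append(pick)
    return patch


def truth_fraction_image(landcover: Raster, config: LandscapeConfig) -> np.ndarray:
    """Unburned truth (veg, soil, shade) fractions per pixel from the class table."""
    lc = landcover.data
    out = np.zeros((*lc.shape, 3), dtype=float)
    for code in np.unique(lc):
        fr = config.class_fractions[int(code)]
        out[lc == code] = fr
    return out


def generate_reflectance(
    truth_fractions: np.ndarray,
    burn: BurnScarMap,
    month: int,
    endmembers: EndmemberSet = DEFAULT_ENDMEMBERS,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    pixel_size_m: float = 250.0,
) -> Raster:
    """Compose a 3-band raster for one date from truth fractions.

    Pixels burned on or before ``month`` carry the dark burn-scar
    signature; reflectance is the fraction-weighted sum of the endmember
    spectra plus zero-mean Gaussian noise.
    """
    endmembers.validate()
    sums = truth_fractions.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise ValueError("truth fractions must sum to 1 per pixel")
    fr = truth_fractions.copy()
    burned_now = (burn.month > 0) & (burn.month <= month)
    fr[burned_now] = BURNED_FRACTIONS
    E = endmembers.matrix()
    refl = fr @ E.T
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        refl = refl + rng.normal(0.0, noise_sd, size=refl.shape)
    return Raster(refl, pixel_size_m=pixel_size_m)


def generate_active_fires(
    truth_burn: BurnScarMap,
    patches: list[BurnPatch],
    rate_per_patch: float,
    false_fraction: float = 0.0,
    confidence_range: tuple[float, float] = (50.0, 100.0),
    rng: np.random.Generator | None = None,
) -> list[ActiveFireRecord]:
    """Thermal-anomaly point records concentrated inside burn patches.

    Each patch yields a Poisson number of detections with mean
    ``rate_per_patch`` scaled by the patch's relative area (so the expected
    total is rate x number of patches and counts grow with patch size),
    placed uniformly over the patch in its burn month. A ``false_fraction``
    share of extra detections falls outside any burn scar.
    """
    if rate_per_patch < 0:
        raise ValueError("rate must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    rows, cols = truth_burn.shape
    px = truth_burn.pixel_size_m
    records: list[ActiveFireRecord] = []
    if patches and rate_per_patch > 0:
        mean_px = np.mean([p.n_px for p in patches])
        for p in patches:
            n = rng.poisson(rate_per_patch * p.n_px / mean_px)
            if n == 0:
                continue
            chosen = rng.choice(p.pixels, size=n, replace=True)
            for flat in chosen:
                r, c = divmod(int(flat), cols)
                records.append(
                    ActiveFireRecord(
                        x=(c + 0.5) * px,
                        y=(r + 0.5) * px,
                        month=p.month,
                        day=int(rng.integers(1, 29)),
                        confidence=float(rng.uniform(*confidence_range)),
                    )
                )
    if false_fraction > 0 and records:
        unburned = np.flatnonzero(~truth_burn.burned.ravel())
        n_false = rng.poisson(false_fraction * len(records))
        if n_false and len(unburned):
            chosen = rng.choice(unburned, size=n_false, replace=True)
            for flat in chosen:
                r, c = divmod(int(flat), cols)
                records.append(
                    ActiveFireRecord(
                        x=(c + 0.5) * px,
                        y=(r + 0.5) * px,
                        month=int(rng.choice(list(FIRE_SEASON_MONTHS))),
                        day=int(rng.integers(1, 29)),
                        confidence=float(rng.uniform(*confidence_range)),
                    )
                )
    return records


def generate_plot_pairs(
    n: int,
    true_slope: float = reference.LOSS_SLOPE,
    x_error_sd: float = 15.0,
    y_error_sd: float = 15.0,
    seed: int = 0,
    biomass_range: tuple[float, float] = (20.0, 350.0),
) -> list[PlotPair]:
    """Before/after-fire plot pairs around a proportional retention law.

    Latent pre-fire biomass is uniform over ``biomass_range`` (Mg ha^-1);
    the observed pair is (latent + x-noise, slope*latent + y-noise) with the
    per-point error sds recorded for the errors-in-variables fit.
    """
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))
    latent = rng.uniform(*biomass_range, size=n)
    x = latent + (rng.normal(0, x_error_sd, n) if x_error_sd > 0 else 0.0)
    y = true_slope * latent + (rng.normal(0, y_error_sd, n) if y_error_sd > 0 else 0.0)
    x = np.clip(x, 0.0, None)
    y = np.clip(y, 0.0, None)
    sx = max(x_error_sd, 1e-6)
    sy = max(y_error_sd, 1e-6)
    return [PlotPair(float(xi), float(yi), sx, sy) for xi, yi in zip(x, y)]


def generate_scene(config: LandscapeConfig | None = None) -> SyntheticScene:
    """Assemble a full multi-date scene from one config (pure in the seed)."""
    config = config or LandscapeConfig()
    config.validate()
    landcover = generate_landcover(config)
    biomass, biomass_error = generate_biomass(landcover, config)
    truth_burn, patches = generate_burns(landcover, config)
    fractions = truth_fraction_image(landcover, config)
    refl_rng = _rng(config.seed, 4)
    reflectance = [
        (
            month,
            generate_reflectance(
                fractions,
                truth_burn,
                month,
                noise_sd=config.reflectance_noise_sd,
                rng=refl_rng,
                pixel_size_m=config.pixel_size_m,
            ),
        )
        for month in FIRE_SEASON_MONTHS
    ]
    fires = generate_active_fires(
        truth_burn,
        patches,
        rate_per_patch=config.fire_rate_per_patch,
        false_fraction=config.false_fire_fraction,
        confidence_range=config.confidence_range,
        rng=_rng(config.seed, 5),
    )
    return SyntheticScene(
        config=config,
        landcover=landcover,
        biomass=biomass,
        biomass_error=biomass_error,
        truth_burn=truth_burn,
        truth_fractions=fractions,
        reflectance_by_month=reflectance,
        fires=fires,
        patches=patches,
    )
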