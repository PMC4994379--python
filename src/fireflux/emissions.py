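"""Gross and committed carbon-emission bookkeeping by land-cover pathway.

Fire-induced biomass loss is converted to carbon with a fixed carbon
fraction of dry biomass (0.48) and split between the 2010 "gross" flux
(combustion plus first-year decomposition) and the "committed" flux
(decomposition in later years) according to the land cover:

* COMBUST     — grasslands/cerrado and productive lands: all loss is
                combusted in-year; committed = 0.
* DEFOR_SPLIT — fresh deforestation: 50% of the removed biomass is
                combusted, 50% enters the decay pool.
* DECAY       — standing forest and forest regrowth killed by fire: no
                direct combustion; first-year release fraction is
                1 - exp(-k) with decay rate k = 0.17 yr^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import reference
from .grids import STRUCT_4, BurnScarMap, Raster, check_shared_grid

#: patch-size histogram bin edges, km^2
SIZE_BINS_KM2 = (1.0, 2.0, 3.0, 5.0)
SIZE_BIN_LABELS = ("<1", "1-2", "2-3", "3-5", ">5")


@dataclass(frozen=True)
class PathwaySpec:
    """How one land-cover class partitions carbon loss between years."""

    pathway: str  # COMBUST | DEFOR_SPLIT | DECAY
    combustion_fraction: float
    decay_rate_k: float
    year1_release_fraction: float

    @classmethod
    def for_pathway(cls, pathway: str, decay_rate_k: float = reference.DECAY_RATE_K):
        if pathway == reference.COMBUST:
            return cls(pathway, combustion_fraction=1.0, decay_rate_k=0.0,
                       year1_release_fraction=1.0)
        if pathway == reference.DEFOR_SPLIT:
            # the combusted half is the 2010 gross flux; the dead half is all committed
            return cls(pathway, combustion_fraction=0.5, decay_rate_k=0.0,
                       year1_release_fraction=0.5)
        if pathway == reference.DECAY:
            return cls(pathway, combustion_fraction=0.0, decay_rate_k=decay_rate_k,
                       year1_release_fraction=1.0 - math.exp(-decay_rate_k))
        raise ValueError(f"unknown pathway {pathway!r}")


@dataclass
class EmissionConfig:
    """Constants of the carbon accounting."""

    carbon_fraction: float = reference.CARBON_FRACTION
    decay_rate_k: float = reference.DECAY_RATE_K
    npcc_annual_target_pg: float = reference.NPCC_ANNUAL_TARGET_PG
    class_pathways: dict[int, str] = field(default_factory=reference.pathway_by_class)
    class_names: dict[int, str] = field(
        default_factory=lambda: reference.class_table()["name"].to_dict()
    )

    def __post_init__(self):
        if not (0.0 < self.carbon_fraction < 1.0):
            raise ValueError("carbon_fraction must be in (0, 1)")


def pathway_for_class(class_code: int, config: EmissionConfig) -> PathwaySpec:
    """The emission pathway of one land-cover class."""
    try:
        name = config.class_pathways[class_code]
    except KeyError:
        raise KeyError(f"no pathway configured for class {class_code}") from None
    return PathwaySpec.for_pathway(name, decay_rate_k=config.decay_rate_k)


@dataclass
class EmissionRecord:
    """Per-class burned area and carbon bookkeeping result."""

    class_code: int
    name: str
    pathway: str
    burned_area_km2: float
    mean_biomass: float  # Mg ha^-1 over burned pixels
    mean_loss: float  # Mg ha^-1 over burned pixels
    gross_c_tg: float
    committed_c_tg: float
    total_c_tg: float
    percent_of_total: float = float("nan")


def split_total(total_c_tg: float, spec: PathwaySpec) -> tuple[float, float]:
    """(gross, committed) carbon for a class total under its pathway."""
    gross = total_c_tg * spec.year1_release_fraction
    return gross, total_c_tg - gross


def compute_class_emissions(
    loss: Raster,
    landcover: Raster,
    burn: BurnScarMap,
    config: EmissionConfig | None = None,
    biomass: Raster | None = None,
) -> list[EmissionRecord]:
    """Zonal carbon bookkeeping over burned pixels of each land-cover class.

    Unit chain per class: burned pixels x 6.25 ha x loss (Mg ha^-1) gives Mg
    of dry biomass; x 0.48 gives Mg C; /1e6 gives Tg C, split by pathway.
    """
    config = config or EmissionConfig()
    check_shared_grid(loss, landcover, burn.as_raster())
    lc = landcover.data
    burned = burn.burned
    px_ha = burn.pixel_area_ha
    records: list[EmissionRecord] = []
    for code in sorted(config.class_pathways):
        spec = pathway_for_class(code, config)
        mask = burned & (lc == code)
        n = int(mask.sum())
        area_km2 = n * px_ha / 100.0
        if n:
            mean_loss = float(loss.data[mask].mean())
            total_mg_c = config.carbon_fraction * float(loss.data[mask].sum()) * px_ha
            mean_b = float(biomass.data[mask].mean()) if biomass is not None else float("nan")
        else:
            mean_loss, total_mg_c, mean_b = 0.0, 0.0, float("nan")
        total_tg = total_mg_c / 1e6
        gross, committed = split_total(total_tg, spec)
        records.append(
            EmissionRecord(
                class_code=code,
                name=config.class_names.get(code, str(code)),
                pathway=spec.pathway,
                burned_area_km2=area_km2,
                mean_biomass=mean_b,
                mean_loss=mean_loss,
                gross_c_tg=gross,
                committed_c_tg=committed,
                total_c_tg=total_tg,
            )
        )
    present = [c for c in np.unique(lc[burned]) if c not in config.class_pathways]
    if present:
        raise KeyError(f"burned pixels in classes without a pathway: {present}")
    grand = sum(r.total_c_tg for r in records)
    for r in records:
        r.percent_of_total = 100.0 * r.total_c_tg / grand if grand > 0 else 0.0
    return records


@dataclass
class EmissionSummary:
    """Aggregates of the per-class records (all in Tg C).

    RR ("rapidly reversible") emissions come from grass-like vegetation —
    cerrado, productive lands and cerrado regrowth — whose biomass regrows
    within about a year; LTR ("long-term reversible") emissions come from
    forest, forest regrowth and deforestation classes.
    """

    total_c_tg: float
    gross_c_tg: float
    committed_c_tg: float
    intact_total_tg: float
    rr_gross_tg: float
    ltr_gross_tg: float
    ltr_committed_tg: float
    percent_burned_by_class: dict[int, float]


_INTACT = {1, 2}
_RR = {2, 3, 4, 5, 6, 8, 9, 10, 11, 12}
_LTR = {1, 7, 13, 14, 15}


def summarize(
    records: list[EmissionRecord],
    class_areas_km2: dict[int, float] | None = None,
) -> EmissionSummary:
    """Totals and the intact / RR / LTR subtotals of the per-class records."""
    total = sum(r.total_c_tg for r in records)
    gross = sum(r.gross_c_tg for r in records)
    committed = sum(r.committed_c_tg for r in records)
    intact = sum(r.total_c_tg for r in records if r.class_code in _INTACT)
    rr = sum(r.gross_c_tg for r in records if r.class_code in _RR)
    ltr = sum(r.gross_c_tg for r in records if r.class_code in _LTR)
    ltr_committed = sum(r.committed_c_tg for r in records if r.class_code in _LTR)
    pct = {}
    if class_areas_km2:
        for r in records:
            area = class_areas_km2.get(r.class_code)
            if area:
                pct[r.class_code] = percent_burned(r.burned_area_km2, area)
    return EmissionSummary(
        total_c_tg=total,
        gross_c_tg=gross,
        committed_c_tg=committed,
        intact_total_tg=intact,
        rr_gross_tg=rr,
        ltr_gross_tg=ltr,
        ltr_committed_tg=ltr_committed,
        percent_burned_by_class=pct,
    )


def percent_burned(burned_area_km2: float, class_area_km2: float) -> float:
    """Percentage of a class's area burned, reported to 2 decimals."""
    if class_area_km2 <= 0:
        raise ValueError("class area must be > 0")
    return round(100.0 * burned_area_km2 / class_area_km2, 2)


def npcc_ratio(total_c_tg: float, config: EmissionConfig | None = None) -> float:
    """Carbon loss as a percentage of the annual national reduction target."""
    config = config or EmissionConfig()
    if config.npcc_annual_target_pg <= 0:
        raise ValueError("target must be > 0")
    return 100.0 * (total_c_tg / 1e3) / config.npcc_annual_target_pg


def patch_size_distribution(burn: BurnScarMap, landcover: Raster) -> pd.DataFrame:
    """Share of each class's burned area by patch-size bin.

    Burned connected components (4-connectivity) are attributed to their
    majority land-cover class and binned by area (<1, 1-2, 2-3, 3-5, >5
    km^2). Rows are class codes, columns the size bins; each row sums to
    100 (classes with no burned area are omitted).
    """
    check_shared_grid(burn.as_raster(), landcover)
    labels, n = ndimage.label(burn.burned, structure=STRUCT_4)
    px_km2 = burn.pixel_area_ha / 100.0
    shares: dict[int, np.ndarray] = {}
    for comp in range(1, n + 1):
        mask = labels == comp
        npx = int(mask.sum())
        area = npx * px_km2
        codes, counts = np.unique(landcover.data[mask], return_counts=True)
        cls = int(codes[np.argmax(counts)])
        b = np.searchsorted(SIZE_BINS_KM2, area, side="right")
        shares.setdefault(cls, np.zeros(len(SIZE_BIN_LABELS)))
        shares[cls][b] += area
    rows = {}
    for cls, areas in sorted(shares.items()):
        tot = areas.sum()
        rows[cls] = 100.0 * areas / tot if tot > 0 else areas
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(SIZE_BIN_LABELS))


def records_to_frame(records: list[EmissionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "class_code": r.class_code,
                "name": r.name,
                "pathway": r.pathway,
                "burned_area_km2": r.burned_area_km2,
                "mean_biomass": r.mean_biomass,
                "mean_loss": r.mean_loss,
                "gross_c_tg": r.gross_c_tg,
                "committed_c_tg": r.committed_c_tg,
                "total_c_tg": r.total_c_tg,
                "percent_of_total": r.percent_of_total,
            }
            for r in records
        ]
    ).set_index("class_code")


def records_from_frame(df: pd.DataFrame) -> list[EmissionRecord]:
    return [
        EmissionRecord(
            class_code=int(code),
            name=row["name"],
            pathway=row["pathway"],
            burned_area_km2=float(row["burned_area_km2"]),
            mean_biomass=float(row["mean_biomass"]),
            mean_loss=float(row["mean_loss"]),
            gross_c_tg=float(row["gross_c_tg"]),
            committed_c_tg=float(row["committed_c_tg"]),
            total_c_tg=float(row["total_c_tg"]),
            percent_of_total=float(row["percent_of_total"]),
        )
        for code, row in df.iterrows()
    ]
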