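"""Published Mato Grosso 2010 fire-season class statistics.

These are the study's input constants: the 15-class land-cover legend with
2010 class areas, high-confidence active-fire counts, mapped cumulative
burned areas, class-mean aboveground biomass (AGB) with 1-sigma errors, and
the per-class carbon-loss bookkeeping results as printed. They drive the
synthetic-landscape defaults (so simulated scenes reproduce the study
conditions) and the published-table arithmetic checks.

Class codes are stable integers 1..15. ``pathway`` is the land-cover-specific
emission pathway: COMBUST (all loss combusted in-year), DEFOR_SPLIT (50%
combusted / 50% to the decay pool) and DECAY (all loss to the decay pool,
released at 0.17 yr^-1).
"""

from __future__ import annotations

import pandas as pd

COMBUST = "COMBUST"
DEFOR_SPLIT = "DEFOR_SPLIT"
DECAY = "DECAY"

# code, name, group, pathway, is_forest (for burn-map accuracy class),
# fire_count, area_km2, burned_km2, biomass_mean, biomass_sd,
# loss_mean, gross_tg, committed_tg, total_tg
_ROWS = [
    (1, "old_growth_forest", "intact", DECAY, True,
     2326, 289_358, 12_975.0, 176.3, 34.63, 51.63, 5.05, 27.2, 32.3),
    (2, "old_growth_cerrado", "intact", COMBUST, False,
     6467, 220_928, 60_507.0, 40.23, 33.43, 11.71, 34.1, 0.0, 34.1),
    (3, "forest_productive_30yr_plus", "productive_forest", COMBUST, False,
     118, 8_710, 619.0, 53.69, 33.27, 15.65, 0.46, 0.0, 0.46),
    (4, "forest_productive_max30yr", "productive_forest", COMBUST, False,
     171, 31_760, 1_033.0, 68.42, 33.67, 19.95, 0.99, 0.0, 0.99),
    (5, "forest_productive_max20yr", "productive_forest", COMBUST, False,
     686, 58_184, 3_460.0, 105.0, 34.62, 30.61, 5.13, 0.0, 5.13),
    (6, "forest_consolidation_10yr", "productive_forest", COMBUST, False,
     1638, 57_093, 5_974.0, 105.0, 34.76, 17.29, 5.02, 0.0, 5.02),
    (7, "deforestation_2010", "productive_forest", DEFOR_SPLIT, True,
     1, 83, 3.2, 208.9, 33.24, 60.91, 4.78e-3, 3.01e-2, 9.56e-3),
    (8, "cerrado_productive_30yr_plus", "productive_cerrado", COMBUST, False,
     183, 30_192, 2_630.0, 27.17, 32.09, 7.92, 1.00, 0.0, 1.00),
    (9, "cerrado_productive_max30yr", "productive_cerrado", COMBUST, False,
     268, 67_678, 2_563.0, 33.5, 32.39, 9.76, 1.22, 0.0, 1.22),
    (10, "cerrado_productive_max20yr", "productive_cerrado", COMBUST, False,
     489, 87_251, 4_551.0, 31.14, 32.22, 9.08, 1.99, 0.0, 1.99),
    (11, "cerrado_consolidation_10yr", "productive_cerrado", COMBUST, False,
     186, 29_878, 1_325.0, 31.14, 32.61, 9.29, 9.75e-2, 0.0, 9.75e-2),
    (12, "cerrado_regrowth", "regrowth", COMBUST, False,
     30, 1_777, 196.0, 37.51, 32.55, 9.42, 9.21e-2, 0.0, 9.21e-2),
    (13, "forest_regrowth_20yr", "regrowth", DECAY, True,
     1, 50, 3.1, 208.1, 34.11, 43.38, 1.03e-3, 5.53e-3, 6.56e-3),
    (14, "forest_regrowth_10yr", "regrowth", DECAY, True,
     128, 14_178, 795.0, 148.8, 34.82, 49.74, 0.30, 1.64, 1.95),
    (15, "deforestation_2010_on_regrowth", "regrowth", DEFOR_SPLIT, True,
     32, 2_524, 221.0, 131.2, 34.76, 85.27, 0.45, 0.45, 0.91),
]

_COLUMNS = [
    "class_code", "name", "group", "pathway", "is_forest",
    "fire_count", "area_km2", "burned_km2", "biomass_mean", "biomass_sd",
    "loss_mean", "gross_tg", "committed_tg", "total_tg",
]

#: statewide totals of the published table
TOTAL_AREA_KM2 = 899_645
TOTAL_BURNED_KM2 = 96_855.0
TOTAL_FIRE_COUNT = 12_724

#: statewide burned area per month (km2), June..October
MONTHLY_BURNED_KM2 = {6: 6_924.0, 7: 3_982.0, 8: 17_237.0, 9: 65_835.0, 10: 2_878.0}

#: fitted slope of remaining-vs-initial biomass after a single fire, and its
#: standard deviation / bounds from the errors-in-variables fit
LOSS_SLOPE = 0.7084
LOSS_SLOPE_SD = 0.034
LOSS_SLOPE_BOUNDS = (0.6744, 0.7424)

#: carbon fraction of dry biomass
CARBON_FRACTION = 0.48

#: annual decay rate of fire-killed wood, yr^-1
DECAY_RATE_K = 0.17

#: annualised national emission-reduction target for Amazonia, Pg C yr^-1
NPCC_ANNUAL_TARGET_PG = 0.11

#: map accuracies used by the Monte Carlo perturbations
LANDCOVER_ACCURACY = 0.80
LANDCOVER_ACCURACY_CI = (0.74, 0.87)
BURN_ACCURACY_FOREST = 0.992
BURN_ACCURACY_NONFOREST = 0.9693

#: BLA extrapolation context: published total carbon loss of old-growth
#: forest fires scaled beyond the mapped state
BLA_FOREST_TOTAL_TG = 62.4
BLA_FOREST_FIRE_COUNT = 13_667


def class_table() -> pd.DataFrame:
    """The 15-class legend and published per-class statistics."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS).set_index("class_code")


def class_proportions() -> dict[int, float]:
    """Published class-area shares of the state (sum to 1)."""
    t = class_table()
    return (t["area_km2"] / float(t["area_km2"].sum())).to_dict()


def burn_fraction_by_class() -> dict[int, float]:
    """Published burned fraction of each class's area."""
    t = class_table()
    return (t["burned_km2"] / t["area_km2"]).to_dict()


def month_weights() -> dict[int, float]:
    """Share of burned area per fire-season month (September-dominated)."""
    total = sum(MONTHLY_BURNED_KM2.values())
    return {m: a / total for m, a in MONTHLY_BURNED_KM2.items()}


def pathway_by_class() -> dict[int, str]:
    return class_table()["pathway"].to_dict()


def forest_classes() -> frozenset[int]:
    t = class_table()
    return frozenset(t.index[t["is_forest"]])
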