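"""Registry of model input features and output growth factors.

The simulator abstracts the crop as "one big organ" per organ type: all
leaves, stem segments, petioles and harvested fruits of a plant are summed
into per-plant totals.  Output factors are grouped into six decoder groups
(status, property, leaf, stem, petiole, harvest); the grouping is
configurable but the default below covers every factor exactly once.
"""

from __future__ import annotations

# Hourly / daily input features fed to the encoder, fixed order.
FEATURES: tuple[str, ...] = (
    "temperature_c",
    "relative_humidity_pct",
    "radiation_w_m2",
    "dif_c",                    # daily day-night temperature difference
    "daily_cum_radiation_kj",   # kJ m-2 day-1
    "cum_gdd",                  # running growing degree days
    "daily_vpd_kpa",            # from daily mean T and RH
)

# Input features that are daily-resolution (broadcast to all 24 hours).
DAILY_FEATURES: tuple[str, ...] = FEATURES[3:]

# Output growth factors per decoder group (per-plant totals).
DECODER_MAP: dict[str, tuple[str, ...]] = {
    "status": ("cum_radiation_mj", "cum_gdd"),
    "property": ("plant_height_m", "max_nodes_per_stem"),
    "leaf": ("leaf_area_m2", "leaf_count", "leaf_fw_g", "leaf_dw_g"),
    "stem": (
        "node_length_sum_cm",
        "node_diameter_sum_mm",
        "stem_count",
        "stem_fw_g",
        "stem_dw_g",
    ),
    "petiole": ("petiole_count", "petiole_fw_g", "petiole_dw_g"),
    "harvest": (
        "fruit_height_sum_cm",
        "fruit_width_sum_cm",
        "harvest_count",
        "harvest_fw_g",
        "harvest_dw_g",
    ),
}

FACTORS: tuple[str, ...] = tuple(f for group in DECODER_MAP.values() for f in group)

# Factors that are cumulative over the season (non-decreasing in truth).
CUMULATIVE_FACTORS: tuple[str, ...] = (
    "cum_radiation_mj",
    "cum_gdd",
    "fruit_height_sum_cm",
    "fruit_width_sum_cm",
    "harvest_count",
    "harvest_fw_g",
    "harvest_dw_g",
)

# (fresh weight, dry weight) factor pairs; FW >= DW always holds in data.
FW_DW_PAIRS: tuple[tuple[str, str], ...] = (
    ("leaf_fw_g", "leaf_dw_g"),
    ("stem_fw_g", "stem_dw_g"),
    ("petiole_fw_g", "petiole_dw_g"),
    ("harvest_fw_g", "harvest_dw_g"),
)

# Vegetative organ weights whose sums enter the two conservation losses.
VEGETATIVE_FW: tuple[str, ...] = ("leaf_fw_g", "stem_fw_g", "petiole_fw_g")
VEGETATIVE_DW: tuple[str, ...] = ("leaf_dw_g", "stem_dw_g", "petiole_dw_g")


def factor_index(factors: tuple[str, ...] = FACTORS) -> dict[str, int]:
    """Map factor name -> column index."""
    return {f: i for i, f in enumerate(factors)}


def validate_decoder_map(
    decoder_map: dict[str, tuple[str, ...]], factors: tuple[str, ...]
) -> None:
    """Check the decoder grouping is a disjoint cover of ``factors``."""
    seen: list[str] = []
    for name, group in decoder_map.items():
        if not group:
            raise ValueError(f"decoder {name!r} has no factors")
        seen.extend(group)
    if len(seen) != len(set(seen)):
        dupes = {f for f in seen if seen.count(f) > 1}
        raise ValueError(f"factors assigned to multiple decoders: {sorted(dupes)}")
    if set(seen) != set(factors):
        missing = set(factors) - set(seen)
        extra = set(seen) - set(factors)
        raise ValueError(
            f"decoder map does not cover factors (missing={sorted(missing)}, "
            f"unknown={sorted(extra)})"
        )
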