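"""Configuration: every numeric criterion and model parameter, named once.

``ThresholdConfig`` gathers the regulatory screening criteria (half-life
cut-offs, BCF limits, toxicity thresholds, the exposure bins, use-index
map and hazard-by-exposure risk matrix).  ``FateParameters`` describes
the evaluative regional environment of the multimedia fate model.  Both
can be materialised from a single YAML file; keys not present fall back
to the documented defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["ThresholdConfig", "FateParameters", "load_config", "config_digest"]


def _default_risk_matrix() -> dict[int, dict[int, int]]:
    # risk_matrix[hazard][exposure] -> risk score 1 (highest priority) .. 5
    return {
        4: {4: 1, 3: 1, 2: 2, 1: 3, 0: 5},
        3: {4: 1, 3: 2, 2: 2, 1: 3, 0: 5},
        2: {4: 2, 3: 2, 2: 3, 1: 4, 0: 5},
        1: {4: 3, 3: 3, 2: 4, 1: 4, 0: 5},
        0: {4: 5, 3: 5, 2: 5, 1: 5, 0: 5},
    }


def _default_use_index_map() -> dict[str, float]:
    return {
        "controlled_intermediate": 0.1,
        "industrial_nondispersive_or_matrix": 0.2,
        "wide_dispersive": 0.5,
        "environmental_use": 1.0,
        "pesticide": 1.0,
        "cosmetic": 1.0,
        "pharmaceutical": 1.0,
    }


def _default_biowin3_halflife_map() -> list[tuple[float, float]]:
    # (lower bound on the ultimate-biodegradation survey score, water
    # half-life in days); bins are left-closed, descending.
    return [
        (4.75, 0.17),
        (4.25, 1.25),
        (3.75, 2.33),
        (3.25, 8.67),
        (2.75, 15.0),
        (2.25, 37.5),
        (1.75, 60.0),
        (float("-inf"), 180.0),
    ]


@dataclass
class ThresholdConfig:
    """Named screening criteria and scoring tables."""

    # Persistence screening (biodegradation-model cut-offs)
    biowin3_cut: float = 2.2
    biowin6_cut: float = 0.5
    # Half-life based persistence criteria (days)
    t_half_fresh_water: float = 40.0
    t_half_marine_water: float = 60.0
    t_half_fresh_sediment: float = 120.0
    t_half_marine_sediment: float = 180.0
    # Overall persistence / long-range-transport boundaries
    pov_cut_days: float = 195.0
    ctd_cut_km: float = 5097.0
    te_cut_percent: float = 2.25
    # Bioaccumulation
    bcf_b: float = 2000.0       # L/kg; above -> B
    bcf_vb: float = 5000.0      # L/kg; at or above -> vB
    logkow_screen: float = 4.5  # at or below, with no BCF -> not B
    # Toxicity
    noec_t: float = 0.01        # mg/L, chronic
    ec50_screen: float = 0.1    # mg/L, acute
    qsar_t_votes_needed: int = 3
    qsar_t_votes_total: int = 4
    # PNEC assessment factors, keyed on chronic trophic-level coverage
    af_three_trophic: int = 10
    af_two_trophic: int = 50
    af_one_trophic: int = 100
    af_acute_or_qsar: int = 1000
    # Exposure
    use_index_map: dict[str, float] = field(default_factory=_default_use_index_map)
    exposure_bins: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0)  # t/y, half-open
    spin_population_factor: float = 20.0
    # Risk characterisation
    dilution_volume_m3_per_year: float = 25e9
    risk_matrix: dict[int, dict[int, int]] = field(default_factory=_default_risk_matrix)
    # Half-life derivation
    biowin3_halflife_map: list[tuple[float, float]] = field(
        default_factory=_default_biowin3_halflife_map)
    sediment_water_halflife_ratio: float = 2.0
    # Floors/ceilings for inputs outside the model's normal range
    log_kaw_min: float = -12.0
    log_kaw_max: float = 4.0
    t_half_air_floor_days: float = 0.05
    t_half_ceiling_days: float = 1e5
    # Which emission scenario supplies the water distribution fraction
    pec_emission_scenario: str = "water"


@dataclass
class FateParameters:
    """Evaluative regional environment for the multimedia fate model.

    Defaults describe a 1000 km x 1000 km region: 1000 m air column,
    water covering 10% of the area at 20 m depth, soil the remaining
    90% at 0.1 m.  Interfacial transfer velocities are bulk one-way
    exchange velocities typical of regional multimedia screening
    models.
    """

    area_m2: float = 1e12
    box_length_m: float = 1e6
    air_height_m: float = 1000.0
    water_area_fraction: float = 0.1
    water_depth_m: float = 20.0
    soil_area_fraction: float = 0.9
    soil_depth_m: float = 0.1
    wind_speed_m_s: float = 4.0
    water_current_m_s: float = 0.2
    # Interfacial transfer velocities, m/h
    u_air_water: float = 30.0   # absorption + wet/dry deposition to water
    u_air_soil: float = 30.0    # absorption + deposition to soil
    u_water_air: float = 0.05   # volatilisation (scaled by Kaw)
    u_soil_water: float = 1e-4  # runoff/leaching of dissolved fraction
    u_soil_air: float = 0.02    # soil volatilisation (scaled by Kaw)
    foc: float = 0.02           # soil organic-carbon fraction
    koc_coefficient: float = 0.41  # Koc = coefficient * Kow (L/kg)
    soil_bulk_density_kg_L: float = 1.5
    temperature_K: float = 298.15


def _apply(obj, mapping: dict):
    valid = {f.name for f in dataclasses.fields(obj)}
    for k, v in mapping.items():
        if k not in valid:
            raise KeyError(f"unknown configuration key {k!r} for {type(obj).__name__}")
        if k == "risk_matrix":
            v = {int(h): {int(e): int(s) for e, s in row.items()} for h, row in v.items()}
        elif k == "use_index_map":
            v = {str(c): float(i) for c, i in v.items()}
        elif k == "biowin3_halflife_map":
            v = [(float(lo), float(hl)) for lo, hl in v]
        elif k == "exposure_bins":
            v = tuple(float(b) for b in v)
        setattr(obj, k, v)
    return obj


def load_config(path: str | Path | None = None) -> tuple[ThresholdConfig, FateParameters]:
    """Load thresholds and fate parameters from YAML; absent keys keep defaults.

    Schema: two optional top-level mappings, ``thresholds`` and
    ``fate``, whose keys are the dataclass field names.
    """
    thresholds = ThresholdConfig()
    fate = FateParameters()
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("configuration file must contain a mapping")
        _apply(thresholds, data.get("thresholds", {}) or {})
        _apply(fate, data.get("fate", {}) or {})
    return thresholds, fate


def config_digest(thresholds: ThresholdConfig, fate: FateParameters) -> str:
    """Stable hexadecimal digest of the full configuration."""
    blob = json.dumps(
        {"thresholds": dataclasses.asdict(thresholds), "fate": dataclasses.asdict(fate)},
        sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
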