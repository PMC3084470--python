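"""Exposure assessment: production tonnage, use index, annual use, score.

The annual use of a substance is its total production (t/y) times a
dimensionless use index between 0.1 (controlled intermediate in a
closed system) and 1.0 (used directly in the environment), reflecting
how dispersively it is used.  The use score bins annual use on a
decade scale from 0 (< 1 t/y) to 4 (>= 1000 t/y).

Primary (industry-dossier style) tonnage records take precedence;
Nordic product-registry volumes are extrapolated to the European scale
(mean over reported years times a population factor of 20) only when
no primary record exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .config import ThresholdConfig
from .substances import ProductionRecord, UseData

__all__ = [
    "ExposureProfile",
    "assign_use_index",
    "extrapolate_spin",
    "total_production",
    "exposure_score",
    "assess_exposure",
]


@dataclass
class ExposureProfile:
    cas: str = ""
    total_production: Optional[float] = None   # t/y
    use_index_max: Optional[float] = None
    use_index_min: Optional[float] = None
    annual_use: Optional[float] = None         # t/y = production * max use index
    score: Optional[int] = None                # 0-4, absent when not rankable
    provenance: dict[str, str] = field(default_factory=dict)


def assign_use_index(use_entries: list[str],
                     thresholds: ThresholdConfig | None = None
                     ) -> Optional[tuple[float, float]]:
    """Map use-pattern categories to (max, min) use indices.

    Pesticide, cosmetic and pharmaceutical uses are environmental by
    nature and carry index 1.0.  An empty list yields ``None`` (the
    substance cannot be exposure-scored).  Unknown categories raise.
    """
    t = thresholds or ThresholdConfig()
    if not use_entries:
        return None
    indices = []
    for entry in use_entries:
        if entry not in t.use_index_map:
            raise ValueError(f"unknown use category {entry!r}")
        indices.append(t.use_index_map[entry])
    return max(indices), min(indices)


def extrapolate_spin(volumes_by_year: dict[int, float],
                     population_factor: float = 20.0) -> Optional[float]:
    """Scale Nordic registry volumes to the European level.

    The reported yearly volumes are averaged and multiplied by the
    population factor (the two-year case is the printed "divide by 2,
    multiply by 20" rule).  Empty input yields ``None``.
    """
    if not volumes_by_year:
        return None
    if any(v < 0 for v in volumes_by_year.values()):
        raise ValueError("registry volumes must be non-negative")
    mean = sum(volumes_by_year.values()) / len(volumes_by_year)
    return mean * population_factor


def total_production(production_records: list[ProductionRecord],
                     spin_volumes: dict[int, float] | None = None,
                     population_factor: float = 20.0) -> Optional[float]:
    """Total production (t/y) with primary records taking precedence.

    Primary (iuclid-like) tonnages are summed; registry (spin-like)
    data contribute only via extrapolation and only when no primary
    record exists.
    """
    primary = [r.tonnage for r in production_records if r.source == "iuclid-like"]
    if primary:
        return float(sum(primary))
    if spin_volumes:
        return extrapolate_spin(spin_volumes, population_factor)
    registry = [r.tonnage for r in production_records if r.source == "spin-like"]
    if registry:
        # pre-extrapolated registry tonnage supplied directly
        return float(sum(registry))
    return None


def exposure_score(annual_use: Optional[float],
                   thresholds: ThresholdConfig | None = None) -> Optional[int]:
    """Bin annual use (t/y) into the 0-4 exposure score.

    Bins are half-open on the left edge: [0,1) -> 0, [1,10) -> 1,
    [10,100) -> 2, [100,1000) -> 3, >= 1000 -> 4.  Absent input yields
    ``None`` (not rankable).
    """
    t = thresholds or ThresholdConfig()
    if annual_use is None:
        return None
    if annual_use < 0:
        raise ValueError("annual use must be non-negative")
    score = 0
    for bound in t.exposure_bins:
        if annual_use >= bound:
            score += 1
    return score


def assess_exposure(cas: str, use: UseData,
                    thresholds: ThresholdConfig | None = None) -> ExposureProfile:
    """Full exposure assessment for one substance.

    The score is always computed from production times the *maximum*
    use index; the minimum index is carried for reporting only.
    """
    t = thresholds or ThresholdConfig()
    prof = ExposureProfile(cas=cas)
    prof.total_production = total_production(
        use.production_records, use.spin_volumes, t.spin_population_factor)
    if prof.total_production is not None:
        has_primary = any(r.source == "iuclid-like" for r in use.production_records)
        prof.provenance["production"] = "primary" if has_primary else "registry"
    idx = assign_use_index(use.use_entries, t)
    if idx is not None:
        prof.use_index_max, prof.use_index_min = idx
    if prof.total_production is not None and prof.use_index_max is not None:
        prof.annual_use = prof.total_production * prof.use_index_max
        prof.score = exposure_score(prof.annual_use, t)
    return prof
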