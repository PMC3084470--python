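"""Risk characterisation: risk matrix, PEC, PNEC and the ranked list.

The 1-5 risk score (1 = highest priority) is a matrix lookup over the
0-4 hazard and exposure scores.  For the highest-priority stratum a
quantitative ranking is built from the risk characterisation ratio
PEC / PNEC:

* PEC (mg/L) — total production (converted to g/y) times the use
  index times the fraction of the emission partitioning to water in
  the multimedia model, diluted into 25e9 m3/y of receiving water
  (1 g/m3 = 1 mg/L);
* PNEC (mg/L) — the most sensitive toxicity endpoint divided by an
  assessment factor: lowest chronic NOEC with AF 10/50/100 depending
  on how many of the three standard trophic levels (fish,
  invertebrate, algae) are covered, else lowest measured acute EC50
  with AF 1000, else the mean of the QSAR-predicted EC50s with
  AF 1000.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .config import FateParameters, ThresholdConfig, config_digest
from .exposure import ExposureProfile, assess_exposure
from .fate import FateInputError, FateResult, run_fate
from .hazard import HazardProfile, assess_hazard
from .substances import SubstanceRecord, ToxicityDataset, validate_record

__all__ = [
    "PnecResult",
    "RiskResult",
    "PipelineReport",
    "combine_risk_score",
    "derive_pnec",
    "compute_pec",
    "risk_ratio",
    "display_ratio",
    "rank_substances",
    "run_pipeline",
]

_STANDARD_TROPHIC = ("fish", "invertebrate", "algae")


@dataclass
class PnecResult:
    pnec: float                 # mg/L
    basis: str                  # chronic_noec | acute_ec50 | qsar_mean
    af_used: int
    basis_value: float          # mg/L, the endpoint before the AF


@dataclass
class RiskResult:
    cas: str
    name: str = ""
    hazard_score: Optional[int] = None
    exposure_score: Optional[int] = None
    risk_score: Optional[int] = None
    pec: Optional[float] = None     # mg/L
    pnec: Optional[float] = None    # mg/L
    ratio: Optional[float] = None
    rank: Optional[int] = None


def combine_risk_score(hazard_score: int, exposure_score: int,
                       thresholds: ThresholdConfig | None = None) -> int:
    """Risk score 1-5 from the hazard-by-exposure combination matrix."""
    t = thresholds or ThresholdConfig()
    if hazard_score not in t.risk_matrix:
        raise ValueError(f"hazard score {hazard_score} outside 0-4")
    row = t.risk_matrix[hazard_score]
    if exposure_score not in row:
        raise ValueError(f"exposure score {exposure_score} outside 0-4")
    return row[exposure_score]


def derive_pnec(tox: ToxicityDataset,
                thresholds: ThresholdConfig | None = None) -> Optional[PnecResult]:
    """Predicted no-effect concentration with the assessment-factor ladder.

    Preference order: chronic NOECs (AF 10 with all three standard
    trophic levels covered, 50 with two, 100 with one), measured acute
    EC50s (AF 1000), QSAR-predicted EC50 mean (AF 1000).  ``None``
    when no usable toxicity value exists.
    """
    t = thresholds or ThresholdConfig()
    if tox.chronic_noecs:
        levels = {v.taxon for v in tox.chronic_noecs if v.taxon in _STANDARD_TROPHIC}
        if len(levels) >= 3:
            af = t.af_three_trophic
        elif len(levels) == 2:
            af = t.af_two_trophic
        else:
            af = t.af_one_trophic
        basis_value = min(v.value for v in tox.chronic_noecs)
        return PnecResult(basis_value / af, "chronic_noec", af, basis_value)
    acute = tox.experimental_acute()
    if acute:
        basis_value = min(v.value for v in acute)
        return PnecResult(basis_value / t.af_acute_or_qsar, "acute_ec50",
                          t.af_acute_or_qsar, basis_value)
    qsar = tox.qsar_acute()
    if qsar:
        basis_value = sum(v.value for v in qsar) / len(qsar)
        return PnecResult(basis_value / t.af_acute_or_qsar, "qsar_mean",
                          t.af_acute_or_qsar, basis_value)
    return None


def compute_pec(total_production_tpy: Optional[float],
                use_index: Optional[float],
                water_fraction: Optional[float],
                dilution_volume_m3_per_year: float = 25e9) -> Optional[float]:
    """Predicted environmental concentration in surface water, mg/L.

    Production (t/y) is converted to g/y and the fraction reaching
    water is diluted into the receiving volume; 1 g/m3 equals 1 mg/L.
    Any absent factor makes the PEC absent.
    """
    if total_production_tpy is None or use_index is None or water_fraction is None:
        return None
    if total_production_tpy < 0 or use_index < 0:
        raise ValueError("production and use index must be non-negative")
    if not 0.0 <= water_fraction <= 1.0:
        raise ValueError("water fraction must lie in [0, 1]")
    grams_per_year = total_production_tpy * 1e6
    return grams_per_year * use_index * water_fraction / dilution_volume_m3_per_year


def risk_ratio(pec: float, pnec: float) -> float:
    """Risk characterisation ratio PEC / PNEC (dimensionless)."""
    if pnec <= 0:
        raise ValueError("PNEC must be strictly positive")
    return pec / pnec


def display_ratio(ratio: float) -> float | int:
    """Display form of a ratio: nearest integer (half away from zero)
    at or above 1, two significant digits below 1."""
    if ratio >= 1.0:
        return int(math.floor(ratio + 0.5))
    return float(f"{ratio:.2g}")


def rank_substances(results: list[RiskResult]) -> tuple[list[RiskResult], list[RiskResult]]:
    """Order by descending ratio (ties by ascending CAS) and assign ranks.

    Ranks are 1-based and dense: equal ratios share a rank.  Results
    lacking a PEC or PNEC are returned separately, unranked.
    """
    rankable = [r for r in results if r.ratio is not None]
    unrankable = [r for r in results if r.ratio is None]
    ordered = sorted(rankable, key=lambda r: (-r.ratio, r.cas))
    rank = 0
    previous = None
    for r in ordered:
        if previous is None or r.ratio != previous:
            rank += 1
            previous = r.ratio
        r.rank = rank
    return ordered, sorted(unrankable, key=lambda r: r.cas)


@dataclass
class SubstanceReport:
    """Everything the pipeline computed for one substance."""

    record: SubstanceRecord
    validation_ok: bool = True
    hazard: Optional[HazardProfile] = None
    fate_summary: Optional[FateResult] = None
    fate_scenarios: dict[str, FateResult] = field(default_factory=dict)
    exposure: Optional[ExposureProfile] = None
    pnec: Optional[PnecResult] = None
    risk: Optional[RiskResult] = None
    exclusion_reasons: list[str] = field(default_factory=list)


@dataclass
class PipelineReport:
    substances: list[SubstanceReport]
    ranked: list[RiskResult]
    unranked: list[RiskResult]
    manifest: dict


def run_pipeline(records: list[SubstanceRecord],
                 thresholds: ThresholdConfig | None = None,
                 fate_params: FateParameters | None = None,
                 seed: Optional[int] = None,
                 rank_all: bool = False) -> PipelineReport:
    """End-to-end prioritisation over a substance table.

    Every substance is hazard- and exposure-assessed; those with both
    scores get a risk score; the highest-priority stratum (risk score
    1, or every scored substance with ``rank_all``) is ranked by
    PEC/PNEC.  One bad record never aborts the run — it is excluded
    with a reason.  The manifest records the configuration digest,
    seed and per-stage counts, so identical inputs reproduce identical
    reports.
    """
    t = thresholds or ThresholdConfig()
    p = fate_params or FateParameters()
    reports: list[SubstanceReport] = []
    candidates: list[RiskResult] = []

    for record in records:
        sub = SubstanceReport(record=record)
        reports.append(sub)
        validation = validate_record(record)
        sub.validation_ok = validation.ok
        if not validation.ok:
            sub.exclusion_reasons.append(
                "validation failed: " + "; ".join(
                    f"{i.field}: {i.message}" for i in validation.issues
                    if i.severity == "error"))
            continue

        try:
            sub.fate_scenarios, sub.fate_summary = run_fate(record, p, t)
        except FateInputError as exc:
            sub.exclusion_reasons.append(f"fate model unavailable: {exc}")

        vp = None
        if sub.fate_summary is not None:
            vp = sub.fate_summary.region == "A"
        sub.hazard = assess_hazard(record, vp_flag=vp, thresholds=t)
        sub.exposure = assess_exposure(record.cas, record.use, t)
        sub.pnec = derive_pnec(record.tox, t)

        risk = RiskResult(cas=record.cas, name=record.name,
                          hazard_score=sub.hazard.score,
                          exposure_score=sub.exposure.score)
        sub.risk = risk
        if sub.exposure.score is None:
            sub.exclusion_reasons.append("no production/use data; not rankable")
            continue
        risk.risk_score = combine_risk_score(sub.hazard.score, sub.exposure.score, t)

        water_fraction = sub.fate_summary.f_water if sub.fate_summary else None
        risk.pec = compute_pec(sub.exposure.total_production,
                               sub.exposure.use_index_max,
                               water_fraction,
                               t.dilution_volume_m3_per_year)
        if sub.pnec is not None:
            risk.pnec = sub.pnec.pnec
        if risk.pec is None:
            sub.exclusion_reasons.append("PEC unavailable (missing fate or use data)")
        if risk.pnec is None:
            sub.exclusion_reasons.append("PNEC unavailable (no toxicity data)")
        if risk.pec is not None and risk.pnec is not None:
            risk.ratio = risk_ratio(risk.pec, risk.pnec)
            if rank_all or risk.risk_score == 1:
                candidates.append(risk)

    ranked, unranked = rank_substances(candidates)
    n_excluded = sum(1 for s in reports if s.exclusion_reasons)
    n_below_priority = sum(
        1 for s in reports
        if s.risk is not None and s.risk.ratio is not None
        and s.risk not in candidates)
    manifest = {
        "config_digest": config_digest(t, p),
        "seed": seed,
        "n_input": len(records),
        "n_hazard_assessed": sum(1 for s in reports if s.hazard is not None),
        "n_fate_modelled": sum(1 for s in reports if s.fate_summary is not None),
        "n_exposure_scored": sum(
            1 for s in reports if s.exposure is not None and s.exposure.score is not None),
        "n_ranked": len(ranked),
        "n_below_priority": n_below_priority,
        "n_excluded": n_excluded,
        "exclusions": {
            s.record.cas: s.exclusion_reasons for s in reports if s.exclusion_reasons},
        "rank_all": rank_all,
    }
    return PipelineReport(substances=reports, ranked=ranked,
                          unranked=unranked, manifest=manifest)
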