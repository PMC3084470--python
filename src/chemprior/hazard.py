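"""PBT/vPvB hazard assessment and the 0-4 hazard score.

Flags are tri-state: ``True``, ``False`` or ``None`` (unknown, i.e. the
data do not allow a conclusion).  Experimental evidence always takes
precedence over screening-level evidence (biodegradation-model scores,
predicted BCFs, QSAR toxicity votes); the provenance of each resolved
flag is recorded.

The total hazard score is the sum of the persistence (P),
bioaccumulation (B), toxicity (T) and endocrine-disruption (ED)
indicators (1 each when the flag is true, 0 otherwise), plus a bonus
point when all three PBT screening criteria are met simultaneously or
the substance is vPvB, capped at 4.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Optional

from .config import ThresholdConfig
from .substances import SubstanceRecord, ToxicityDataset

__all__ = [
    "BcfConsensus",
    "HazardProfile",
    "assess_p_screen",
    "assess_p_halflife",
    "aggregate_bcf",
    "classify_b",
    "compute_baf",
    "assess_t_definitive",
    "assess_t_screen",
    "compute_hazard_score",
    "assess_hazard",
]


@dataclass
class BcfConsensus:
    """Aggregate of predicted bioconcentration factors from several models.

    The maximum is the worst-case value used for classification; mean
    and sample standard deviation measure prediction coherence.
    """

    bcf_max: float
    bcf_mean: float
    bcf_stddev: float
    n_models: int


@dataclass
class HazardProfile:
    cas: str = ""
    p_flag: Optional[bool] = None
    vp_flag: Optional[bool] = None
    b_flag: Optional[bool] = None
    vb_flag: Optional[bool] = None
    t_flag: Optional[bool] = None
    ed_flag: Optional[bool] = None
    all_screening_criteria_met: bool = False
    pbt_or_vpvb: bool = False
    score: int = 0
    provenance: dict[str, str] = field(default_factory=dict)  # flag -> tag


def assess_p_screen(biowin3: Optional[float], biowin6: Optional[float],
                    thresholds: ThresholdConfig | None = None) -> Optional[bool]:
    """Screening persistence call from biodegradation-model scores.

    Persistent at screening level iff the ultimate-biodegradation
    survey score is below 2.2 (degradation timeframe of months or
    longer) AND the probability of fast biodegradation is below 0.5.
    Unknown if either score is absent.
    """
    t = thresholds or ThresholdConfig()
    if biowin3 is None or biowin6 is None:
        return None
    return biowin3 < t.biowin3_cut and biowin6 < t.biowin6_cut


def assess_p_halflife(t_half_water: Optional[float] = None,
                      t_half_sediment: Optional[float] = None,
                      marine_water: bool = False,
                      marine_sediment: bool = False,
                      thresholds: ThresholdConfig | None = None) -> Optional[bool]:
    """Definitive persistence call from measured degradation half-lives.

    Persistent iff fresh/estuarine water t1/2 > 40 d, marine water
    t1/2 > 60 d, fresh sediment t1/2 > 120 d or marine sediment
    t1/2 > 180 d (all strict).  Unknown when no half-life is present.
    """
    t = thresholds or ThresholdConfig()
    for v in (t_half_water, t_half_sediment):
        if v is not None and v <= 0:
            raise ValueError("half-lives must be strictly positive")
    if t_half_water is None and t_half_sediment is None:
        return None
    if t_half_water is not None:
        cut = t.t_half_marine_water if marine_water else t.t_half_fresh_water
        if t_half_water > cut:
            return True
    if t_half_sediment is not None:
        cut = t.t_half_marine_sediment if marine_sediment else t.t_half_fresh_sediment
        if t_half_sediment > cut:
            return True
    return False


def aggregate_bcf(bcf_predictions: list[float]) -> Optional[BcfConsensus]:
    """Worst-case/mean/spread aggregate over model-predicted BCFs.

    Empty input yields ``None`` (the caller treats bioaccumulation as
    unknown).  The standard deviation is the sample value, zero for a
    single model.
    """
    if not bcf_predictions:
        return None
    n = len(bcf_predictions)
    return BcfConsensus(
        bcf_max=max(bcf_predictions),
        bcf_mean=sum(bcf_predictions) / n,
        bcf_stddev=statistics.stdev(bcf_predictions) if n > 1 else 0.0,
        n_models=n,
    )


def classify_b(bcf_experimental: Optional[float],
               bcf_consensus: Optional[BcfConsensus],
               log_kow: Optional[float],
               thresholds: ThresholdConfig | None = None) -> str:
    """Bioaccumulation class: ``not_B``, ``B``, ``vB`` or ``unknown``.

    Precedence: measured BCF, then the worst-case predicted BCF, then
    the log Kow rule-out (no BCF and log Kow <= 4.5 -> not B).  BCF at
    or below 2000 L/kg is not B; strictly between 2000 and 5000 is B;
    at or above 5000 is vB (the upper boundary is resolved to the more
    severe class).
    """
    t = thresholds or ThresholdConfig()
    bcf = bcf_experimental
    if bcf is None and bcf_consensus is not None:
        bcf = bcf_consensus.bcf_max
    if bcf is not None:
        if bcf >= t.bcf_vb:
            return "vB"
        if bcf > t.bcf_b:
            return "B"
        return "not_B"
    if log_kow is not None and log_kow <= t.logkow_screen:
        return "not_B"
    return "unknown"


def compute_baf(bcf: float, bmf_chain: list[float]) -> float:
    """Bioaccumulation factor along a food chain: BCF times the product
    of the biomagnification factors; an empty chain returns the BCF."""
    if bcf <= 0 or any(b <= 0 for b in bmf_chain):
        raise ValueError("BCF and all BMFs must be strictly positive")
    return bcf * math.prod(bmf_chain)


def assess_t_definitive(tox: ToxicityDataset,
                        thresholds: ThresholdConfig | None = None) -> Optional[bool]:
    """Definitive toxicity call from chronic data and classifications.

    Toxic iff the lowest chronic NOEC is below 0.01 mg/L, or the
    substance is classified carcinogenic (cat 1/2), mutagenic (cat
    1/2), toxic to reproduction (cat 1/2/3), or carries a chronic
    R48 classification.  Not toxic when chronic data exist and nothing
    triggers; unknown with neither chronic data nor classifications.
    """
    t = thresholds or ThresholdConfig()
    classified = (
        tox.carcinogen_cat in (1, 2)
        or tox.mutagen_cat in (1, 2)
        or tox.repro_cat in (1, 2, 3)
        or tox.r48_t or tox.r48_xn
    )
    if classified:
        return True
    if tox.chronic_noecs:
        return min(v.value for v in tox.chronic_noecs) < t.noec_t
    has_any_classification_data = any(
        c is not None for c in (tox.carcinogen_cat, tox.mutagen_cat, tox.repro_cat))
    if has_any_classification_data:
        # explicit non-triggering categories, no chronic data: not T definitively
        return False
    return None


def assess_t_screen(tox: ToxicityDataset,
                    thresholds: ThresholdConfig | None = None) -> Optional[bool]:
    """Screening toxicity call from acute data or QSAR consensus.

    Potentially toxic iff the lowest measured acute EC50/EL50 is below
    0.1 mg/L; with no measured acute data, iff at least 3 of the 4
    independent QSAR classifications vote toxic.  Unknown when neither
    acute data nor a full set of votes exists.
    """
    t = thresholds or ThresholdConfig()
    acute = tox.experimental_acute()
    if acute:
        return min(v.value for v in acute) < t.ec50_screen
    if len(tox.qsar_t_votes) >= t.qsar_t_votes_total:
        return sum(tox.qsar_t_votes) >= t.qsar_t_votes_needed
    return None


def compute_hazard_score(p: Optional[bool], b: Optional[bool], t: Optional[bool],
                         ed: Optional[bool], bonus: bool) -> int:
    """Total hazard score: P + B + T + ED (+1 bonus), capped at 4.

    Unknown flags contribute 0 — data-poor substances sink in the
    ranking rather than disappearing from it.
    """
    total = sum(1 for flag in (p, b, t, ed) if flag is True)
    if bonus:
        total += 1
    return min(total, 4)


def assess_hazard(record: SubstanceRecord,
                  vp_flag: Optional[bool] = None,
                  thresholds: ThresholdConfig | None = None) -> HazardProfile:
    """Resolve all hazard flags for one substance and score it.

    ``vp_flag`` is the very-persistent call from the multimedia fate
    module (overall-persistence/LRTP region A), which is the single
    source of truth for vP; pass ``None`` when fate metrics could not
    be computed.
    """
    t = thresholds or ThresholdConfig()
    prof = HazardProfile(cas=record.cas)
    props = record.props

    # Persistence: measured half-lives take precedence over screening.
    p_def = assess_p_halflife(props.t_half_water, props.t_half_sediment,
                              props.marine_water, props.marine_sediment, t)
    if p_def is not None:
        prof.p_flag = p_def
        prof.provenance["P"] = "experimental"
    else:
        prof.p_flag = assess_p_screen(props.biowin3, props.biowin6, t)
        prof.provenance["P"] = "screening" if prof.p_flag is not None else "unknown"
    prof.vp_flag = vp_flag
    if vp_flag is True and prof.p_flag is not True:
        # vP implies P by definition
        prof.p_flag = True
        prof.provenance["P"] = "screening"

    # Bioaccumulation.
    consensus = aggregate_bcf(record.bioacc.bcf_predictions)
    b_class = classify_b(record.bioacc.bcf_experimental, consensus, props.log_kow, t)
    if b_class == "unknown":
        prof.b_flag = None
        prof.vb_flag = None
        prof.provenance["B"] = "unknown"
    else:
        prof.b_flag = b_class in ("B", "vB")
        prof.vb_flag = b_class == "vB"
        if record.bioacc.bcf_experimental is not None:
            prof.provenance["B"] = "experimental"
        elif consensus is not None:
            prof.provenance["B"] = "qsar"
        else:
            prof.provenance["B"] = "screening"  # log Kow rule-out

    # Toxicity: definitive (chronic/classification) first, then screening.
    t_def = assess_t_definitive(record.tox, t)
    if t_def is not None:
        prof.t_flag = t_def
        prof.provenance["T"] = "experimental"
    else:
        prof.t_flag = assess_t_screen(record.tox, t)
        if prof.t_flag is None:
            prof.provenance["T"] = "unknown"
        elif record.tox.experimental_acute():
            prof.provenance["T"] = "experimental"
        else:
            prof.provenance["T"] = "qsar"

    # Endocrine disruption is a direct list-membership input.
    prof.ed_flag = record.ed_flag
    prof.provenance["ED"] = "experimental" if record.ed_flag is not None else "unknown"

    prof.all_screening_criteria_met = (
        prof.p_flag is True and prof.b_flag is True and prof.t_flag is True)
    vpvb = prof.vp_flag is True and prof.vb_flag is True
    prof.pbt_or_vpvb = prof.all_screening_criteria_met or vpvb
    prof.score = compute_hazard_score(
        prof.p_flag, prof.b_flag, prof.t_flag, prof.ed_flag,
        bonus=prof.all_screening_criteria_met or vpvb)
    return prof
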