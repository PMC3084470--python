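"""PBT/vPvB flag assignment and the hazard score."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from chemprior.hazard import (aggregate_bcf, assess_hazard, assess_p_halflife,
                              assess_p_screen, assess_t_definitive,
                              assess_t_screen, classify_b, compute_baf,
                              compute_hazard_score)
from chemprior.substances import (BioaccumulationData, PropertySet,
                                  SubstanceRecord, ToxicityDataset, ToxValue)


@pytest.mark.parametrize("b3, b6, expected", [
    (2.0, 0.4, True),       # both below the cut-offs
    (2.2, 0.4, False),      # strict inequality at the survey-score boundary
    (2.0, 0.5, False),      # strict inequality at the probability boundary
    (2.0, None, None),
    (None, 0.4, None),
])
def test_persistence_screen(b3, b6, expected):
    assert assess_p_screen(b3, b6) is expected


@pytest.mark.parametrize("kwargs, expected", [
    (dict(t_half_water=45.0), True),
    (dict(t_half_water=40.0), False),                           # strict boundary
    (dict(t_half_water=45.0, marine_water=True), False),        # marine cut is 60
    (dict(t_half_water=61.0, marine_water=True), True),
    (dict(t_half_sediment=200.0, marine_sediment=True), True),
    (dict(t_half_sediment=150.0, marine_sediment=True), False),
    (dict(t_half_sediment=121.0), True),
    (dict(), None),
])
def test_persistence_from_halflives(kwargs, expected):
    assert assess_p_halflife(**kwargs) is expected


def test_negative_halflife_rejected():
    with pytest.raises(ValueError):
        assess_p_halflife(t_half_water=-1.0)


def test_bcf_aggregation():
    c = aggregate_bcf([500.0, 2500.0, 1500.0])
    assert (c.bcf_max, c.bcf_mean, c.bcf_stddev) == (2500.0, 1500.0, 1000.0)
    single = aggregate_bcf([3000.0])
    assert (single.bcf_max, single.bcf_mean, single.bcf_stddev) == (3000.0, 3000.0, 0.0)
    assert aggregate_bcf([]) is None


@pytest.mark.parametrize("exp, preds, log_kow, expected", [
    (3000.0, None, None, "B"),
    (None, [6000.0, 100.0], None, "vB"),        # worst-case prediction governs
    (None, None, 4.0, "not_B"),                 # rule-out at low hydrophobicity
    (None, None, 4.5, "not_B"),                 # boundary inclusive for rule-out
    (None, None, 5.0, "unknown"),
    (2000.0, None, None, "not_B"),              # lower boundary open
    (5000.0, None, None, "vB"),                 # upper boundary: severe class
    (1000.0, [9000.0], None, "not_B"),          # measured BCF overrides predictions
    (None, None, None, "unknown"),
])
def test_bioaccumulation_classes(exp, preds, log_kow, expected):
    consensus = aggregate_bcf(preds) if preds else None
    assert classify_b(exp, consensus, log_kow) == expected


def test_baf_is_bcf_times_bmf_product():
    assert compute_baf(1000.0, [2.0, 1.5]) == 3000.0
    assert compute_baf(1000.0, []) == 1000.0
    assert compute_baf(2000.0, [1.0]) == 2000.0
    with pytest.raises(ValueError):
        compute_baf(1000.0, [0.0])


def _tox(noecs=(), acutes=(), votes=(), **kw):
    return ToxicityDataset(
        chronic_noecs=[ToxValue(t, v) for t, v in noecs],
        acute_ec50s=[ToxValue(t, v, s) for t, v, s in acutes],
        qsar_t_votes=list(votes), **kw)


def test_toxicity_definitive():
    assert assess_t_definitive(_tox(noecs=[("fish", 0.005)])) is True
    assert assess_t_definitive(_tox(noecs=[("fish", 0.02)])) is False
    assert assess_t_definitive(_tox(noecs=[("fish", 0.01)])) is False  # strict
    assert assess_t_definitive(ToxicityDataset(carcinogen_cat=1)) is True
    assert assess_t_definitive(ToxicityDataset(mutagen_cat=2)) is True
    assert assess_t_definitive(ToxicityDataset(repro_cat=3)) is True
    assert assess_t_definitive(ToxicityDataset(r48_t=True)) is True
    assert assess_t_definitive(ToxicityDataset(carcinogen_cat=3)) is False
    assert assess_t_definitive(ToxicityDataset()) is None


def test_toxicity_screen():
    acute = [("fish", 0.05, "experimental")]
    assert assess_t_screen(_tox(acutes=acute)) is True
    assert assess_t_screen(_tox(acutes=[("fish", 0.1, "experimental")])) is False
    # QSAR consensus: at least 3 of 4 votes
    assert assess_t_screen(_tox(votes=[True, True, True, False])) is True
    assert assess_t_screen(_tox(votes=[True, True, False, False])) is False
    assert assess_t_screen(_tox(votes=[True, True, True])) is None  # incomplete panel
    assert assess_t_screen(ToxicityDataset()) is None
    # measured acute data override the QSAR vote
    mixed = _tox(acutes=[("fish", 5.0, "experimental")],
                 votes=[True, True, True, True])
    assert assess_t_screen(mixed) is False


@pytest.mark.parametrize("flags, bonus, expected", [
    ((True, True, True, False), True, 4),     # PBT with bonus: the maximum
    ((False, False, False, False), False, 0),  # the minimum
    ((True, True, True, True), True, 4),      # capped at 4
    ((True, False, False, True), False, 2),
    ((None, True, None, False), False, 1),    # unknown contributes 0
])
def test_hazard_score(flags, bonus, expected):
    assert compute_hazard_score(*flags, bonus=bonus) == expected


@given(st.lists(st.sampled_from([True, False, None]), min_size=4, max_size=4),
       st.booleans(), st.integers(0, 3))
def test_hazard_score_monotone_in_flags(flags, bonus, i):
    """Raising any flag from false/unknown to true never lowers the score."""
    base = compute_hazard_score(*flags, bonus=bonus)
    raised = list(flags)
    raised[i] = True
    assert compute_hazard_score(*raised, bonus=bonus) >= base
    assert 0 <= base <= 4


def _pbt_record():
    return SubstanceRecord(
        cas="2921-88-2",
        props=PropertySet(log_kow=6.0, log_kaw=-4.0, t_half_water=300.0,
                          t_half_air=50.0),
        tox=_tox(noecs=[("fish", 0.001)]),
        bioacc=BioaccumulationData(bcf_experimental=6000.0),
        ed_flag=False)


def test_assess_hazard_full_pbt():
    prof = assess_hazard(_pbt_record())
    assert prof.p_flag and prof.b_flag and prof.t_flag and prof.vb_flag
    assert prof.all_screening_criteria_met
    assert prof.score == 4
    assert prof.provenance["P"] == "experimental"
    assert prof.provenance["B"] == "experimental"


def test_experimental_precedence_over_screening():
    """Perturbing QSAR-level inputs never changes flags backed by data."""
    rec = _pbt_record()
    base = assess_hazard(rec)
    rec.props.biowin3, rec.props.biowin6 = 5.0, 0.99   # says fast-degrading
    rec.bioacc.bcf_predictions = [1.0, 2.0]            # says non-accumulating
    rec.tox.qsar_t_votes = [False, False, False, False]
    perturbed = assess_hazard(rec)
    assert (perturbed.p_flag, perturbed.b_flag, perturbed.t_flag) == \
        (base.p_flag, base.b_flag, base.t_flag)
    assert perturbed.score == base.score


def test_vp_from_fate_implies_p():
    rec = SubstanceRecord(cas="50-29-3", props=PropertySet(log_kow=6.0))
    prof = assess_hazard(rec, vp_flag=True)
    assert prof.p_flag is True and prof.vp_flag is True


def test_vpvb_bonus_without_t():
    """A vPvB substance reaches the top score even when T is unknown."""
    rec = SubstanceRecord(
        cas="50-29-3",
        props=PropertySet(log_kow=6.0, t_half_water=300.0, t_half_air=10.0,
                          log_kaw=-4.0),
        bioacc=BioaccumulationData(bcf_experimental=6000.0),
        ed_flag=True)
    prof = assess_hazard(rec, vp_flag=True)
    assert prof.t_flag is None
    assert prof.pbt_or_vpvb
    # P + B + ED + bonus = 4
    assert prof.score == 4
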