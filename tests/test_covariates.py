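import itertools

import pytest
from hypothesis import given, settings, strategies as st

from trunkgait.covariates import (
    DOMAINS,
    IpaqResponse,
    MET_COEFFICIENTS,
    aggregate_strength,
    score_ipaq,
)


def test_met_coefficients_are_standard():
    assert MET_COEFFICIENTS == {"vigorous": 8.0, "moderate": 4.0, "walking": 3.3}


@pytest.mark.parametrize(
    "intensity,days,minutes,expected",
    [
        ("vigorous", 3, 30, 720.0),   # 3 x 30 x 8.0
        ("walking", 7, 60, 1386.0),   # 7 x 60 x 3.3
        ("moderate", 5, 40, 800.0),   # 5 x 40 x 4.0
    ],
)
def test_single_activity_scoring(intensity, days, minutes, expected):
    resp = IpaqResponse(days={("leisure", intensity): days},
                        minutes={("leisure", intensity): minutes})
    assert score_ipaq(resp).met_total == pytest.approx(expected)


def test_all_zero_response_is_low():
    score = score_ipaq(IpaqResponse())
    assert score.met_total == 0.0
    assert score.category == "low"


def test_implausible_minutes_truncated_and_flagged():
    resp = IpaqResponse(days={("work", "walking"): 5}, minutes={("work", "walking"): 1200})
    score = score_ipaq(resp)
    assert score.met_total == pytest.approx(3.3 * 5 * 960)
    assert any("implausible" in f for f in score.flags)


def test_short_bouts_score_zero():
    resp = IpaqResponse(days={("work", "moderate"): 5}, minutes={("work", "moderate"): 5})
    assert score_ipaq(resp).met_total == 0.0


def test_category_rules():
    # high: vigorous >= 3 days and >= 1500 MET-min/week
    high = IpaqResponse(days={("leisure", "vigorous"): 4}, minutes={("leisure", "vigorous"): 60})
    assert score_ipaq(high).category == "high"  # 4*60*8 = 1920
    # moderate: walking >= 30 min on >= 5 days
    mod = IpaqResponse(days={("transport", "walking"): 5}, minutes={("transport", "walking"): 30})
    assert score_ipaq(mod).category == "moderate"
    # low: 2 days x 20 min moderate only
    low = IpaqResponse(days={("leisure", "moderate"): 2}, minutes={("leisure", "moderate"): 20})
    assert score_ipaq(low).category == "low"


def test_scoring_additive_and_domain_order_invariant():
    days = {(d, "moderate"): 2 for d in DOMAINS}
    minutes = {(d, "moderate"): 30 for d in DOMAINS}
    total = score_ipaq(IpaqResponse(days=days, minutes=minutes)).met_total
    parts = sum(
        score_ipaq(IpaqResponse(days={(d, "moderate"): 2}, minutes={(d, "moderate"): 30})).met_total
        for d in DOMAINS
    )
    assert total == pytest.approx(parts)


def test_invalid_responses_rejected():
    with pytest.raises(ValueError):
        IpaqResponse(days={("work", "vigorous"): 9})
    with pytest.raises(ValueError):
        IpaqResponse(minutes={("work", "vigorous"): -5})


def test_strength_aggregation_example():
    rec = aggregate_strength("extensors", (100.0, 110.0), (105.0, 95.0))
    assert rec.max_L == 110.0
    assert rec.max_R == 105.0
    assert rec.ms_average == pytest.approx(107.5)
    assert rec.ms_diff == pytest.approx(5.0)


def test_equal_sides_zero_difference():
    rec = aggregate_strength("flexors", (90.0, 80.0), (85.0, 90.0))
    assert rec.ms_diff == 0.0


def test_missing_side_flagged():
    rec = aggregate_strength("abductors", (100.0, 120.0), None)
    assert rec.max_L == 120.0
    assert rec.max_R is None
    assert rec.ms_average is None and rec.ms_diff is None
    assert "missing_side" in rec.flags


def test_negative_force_rejected():
    with pytest.raises(ValueError):
        aggregate_strength("adductors", (-1.0, 50.0), (60.0, 55.0))


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    st.tuples(st.floats(0, 500), st.floats(0, 500)),
    st.tuples(st.floats(0, 500), st.floats(0, 500)),
    st.floats(0.1, 10.0),
)
def test_strength_invariants(tl, tr, scale):
    """ms_diff is invariant to a left/right swap; both summaries scale
    linearly with force."""
    a = aggregate_strength("extensors", tl, tr)
    b = aggregate_strength("extensors", tr, tl)
    assert a.ms_diff == pytest.approx(b.ms_diff, abs=1e-9)
    assert a.ms_average == pytest.approx(b.ms_average, abs=1e-9)
    s = aggregate_strength(
        "extensors", (tl[0] * scale, tl[1] * scale), (tr[0] * scale, tr[1] * scale)
    )
    assert s.ms_average == pytest.approx(a.ms_average * scale, rel=1e-9, abs=1e-9)
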