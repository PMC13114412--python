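"""ICER computation, dominance classification, subgroup table and one-way DSA."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtcea.cohort import ArmSummary, ComparatorSpec
from rtcea.incremental import (
    Classification,
    WTPVerdict,
    incremental_icer,
    one_way_dsa,
    subgroup_table,
)
from rtcea.reference import cancer_comparators, cancer_summaries


def _arm(label, cost, qaly, n=10):
    return ArmSummary(label, n, cost, None, qaly, None)


def _comp(cost, qaly, label="No RT"):
    return ComparatorSpec(label, cost, None, qaly, None, provenance="literature")


@pytest.mark.parametrize(
    "cost,qaly,c_cost,c_qaly,icer,classification",
    [
        # published technique / subgroup rows
        (2787.00, 0.1394, 5560.00, 0.352, 13043.27, Classification.COST_SAVING_LESS_EFFECTIVE),
        (6686.25, 0.310, 7800.00, 0.360, 22275.00, Classification.COST_SAVING_LESS_EFFECTIVE),
        (5724.25, 0.370, 2300.00, 0.110, 13170.19, Classification.MORE_EFFECTIVE_MORE_COSTLY),
        (9351.20, 0.590, 7730.00, 0.520, 23160.00, Classification.MORE_EFFECTIVE_MORE_COSTLY),
        (3770.91, -0.030, 5000.00, 0.350, 3234.45, Classification.COST_SAVING_LESS_EFFECTIVE),
    ],
)
def test_published_icers_reproduce(cost, qaly, c_cost, c_qaly, icer, classification):
    r = incremental_icer(_arm("x", cost, qaly), _comp(c_cost, c_qaly))
    assert r.icer == pytest.approx(icer, abs=0.01)
    assert r.classification is classification


def test_equal_qalys_cost_saving():
    r = incremental_icer(_arm("breast", 5716.70, 0.550), _comp(6500.00, 0.550))
    assert r.icer is None
    assert r.classification is Classification.COST_SAVING_EQUAL


def test_identical_arms_undefined_icer():
    r = incremental_icer(_arm("a", 100.0, 0.3), _comp(100.0, 0.3))
    assert r.delta_cost == 0 and r.delta_qaly == 0 and r.icer is None


def test_equal_effect_more_costly_is_weakly_dominated():
    r = incremental_icer(_arm("a", 200.0, 0.3), _comp(100.0, 0.3))
    assert r.classification is Classification.DOMINATED


def test_wtp_verdicts():
    dominant = incremental_icer(_arm("a", 50.0, 0.5), _comp(100.0, 0.3))
    assert dominant.wtp_verdict is WTPVerdict.COST_EFFECTIVE
    ne_ok = incremental_icer(_arm("a", 200.0, 0.5), _comp(100.0, 0.49), wtp=30_000)
    assert ne_ok.wtp_verdict is WTPVerdict.COST_EFFECTIVE
    ne_bad = incremental_icer(_arm("a", 5000.0, 0.5), _comp(100.0, 0.49), wtp=30_000)
    assert ne_bad.wtp_verdict is WTPVerdict.NOT_COST_EFFECTIVE
    sw = incremental_icer(_arm("a", 50.0, 0.2), _comp(100.0, 0.3))
    assert sw.wtp_verdict is WTPVerdict.NOT_APPLICABLE


finite = st.floats(0, 20_000)
effect = st.floats(-1, 1)


@settings(max_examples=100, derandomize=True)
@given(finite, effect, finite, effect)
def test_classification_matches_delta_signs(c1, e1, c2, e2):
    r = incremental_icer(_arm("a", c1, e1), _comp(c2, e2))
    dc, de = r.delta_cost, r.delta_qaly
    cls = r.classification
    if de > 0:
        assert cls in (Classification.DOMINANT, Classification.MORE_EFFECTIVE_MORE_COSTLY)
        assert (cls is Classification.MORE_EFFECTIVE_MORE_COSTLY) == (dc > 0)
    elif de < 0:
        assert cls in (Classification.DOMINATED, Classification.COST_SAVING_LESS_EFFECTIVE)
        assert (cls is Classification.DOMINATED) == (dc > 0)
    else:
        assert r.icer is None


@settings(max_examples=100, derandomize=True)
@given(finite, effect, finite, effect)
def test_icer_antisymmetric_under_swap(c1, e1, c2, e2):
    fwd = incremental_icer(_arm("a", c1, e1, n=3), _comp(c2, e2))
    rev = incremental_icer(_arm("No RT", c2, e2, n=3), _comp(c1, e1, label="a"))
    assert rev.delta_cost == pytest.approx(-fwd.delta_cost)
    assert rev.delta_qaly == pytest.approx(-fwd.delta_qaly)
    if fwd.icer is not None:
        assert rev.icer == pytest.approx(fwd.icer, rel=1e-12, abs=1e-12)


@settings(max_examples=60, derandomize=True)
@given(st.floats(1, 10_000), st.floats(0.01, 1), st.floats(0, 60_000), st.floats(0, 60_000))
def test_ne_verdict_monotone_in_wtp(dc, de, w1, w2):
    lo, hi = sorted((w1, w2))
    arm, comp = _arm("a", 1000.0 + dc, 0.2 + de), _comp(1000.0, 0.2)
    if incremental_icer(arm, comp, wtp=lo).wtp_verdict is WTPVerdict.COST_EFFECTIVE:
        assert incremental_icer(arm, comp, wtp=hi).wtp_verdict is WTPVerdict.COST_EFFECTIVE


# ---------------------------------------------------------------------------
# subgroup table


def test_subgroup_table_classifications_and_total():
    results = {
        r.intervention: r
        for r in subgroup_table(cancer_summaries(), cancer_comparators())
    }
    assert results["skin"].classification is Classification.DOMINANT
    assert results["sarcoma"].classification is Classification.DOMINANT
    assert results["breast"].classification is Classification.COST_SAVING_EQUAL
    assert results["lung"].icer == pytest.approx(13_170.19, abs=0.01)
    # pooled row: RT cheaper and (slightly) more effective than pooled no-RT
    assert results["Total"].classification is Classification.DOMINANT


def test_subgroup_missing_comparator_errors():
    comps = cancer_comparators()
    comps.pop("lung")
    with pytest.raises(KeyError, match="lung"):
        subgroup_table(cancer_summaries(), comps)


def test_single_stratum_identical_to_comparator():
    res = subgroup_table(
        {"skin": _arm("skin", 100.0, 0.3, n=4)},
        {"skin": _comp(100.0, 0.3)},
    )
    assert res[0].icer is None


# ---------------------------------------------------------------------------
# one-way DSA


def test_dsa_bound_values_match_published_table():
    r = one_way_dsa(
        _arm("Total", 6367.93, 0.4368), _comp(6652.07, 0.4287),
        "comparator_cost", percent=20,
    )
    assert r.lower_value == pytest.approx(5321.66, abs=0.01)
    assert r.upper_value == pytest.approx(7982.49, abs=0.01)


def test_dsa_zero_percent_is_base_case():
    arm, comp = _arm("a", 1100.0, 0.31), _comp(1000.0, 0.30)
    r = one_way_dsa(arm, comp, "comparator_qaly", percent=0)
    assert r.lower_value == r.upper_value == r.base_value
    assert r.icer_lower == r.icer_upper == r.icer_base


def test_dsa_matches_brute_force_recomputation():
    arm, comp = _arm("a", 1100.0, 0.31), _comp(1000.0, 0.30)
    r = one_way_dsa(arm, comp, "comparator_cost", percent=10)
    for bound, icer in ((900.0, r.icer_lower), (1100.0, r.icer_upper)):
        expected = (1100.0 - bound) / (0.31 - 0.30)  # direct recomputation
        assert icer == pytest.approx(expected)


def test_dsa_flags_undefined_bound():
    # +25% on comparator QALY 0.4 hits the intervention's 0.5 exactly
    r = one_way_dsa(_arm("a", 1100.0, 0.5), _comp(1000.0, 0.4),
                    "comparator_qaly", percent=25)
    assert r.icer_upper is None and r.icer_undefined_at_bound


def test_dsa_unknown_parameter():
    with pytest.raises(ValueError, match="parameter"):
        one_way_dsa(_arm("a", 1.0, 0.1), _comp(1.0, 0.2), "intervention_cost")
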