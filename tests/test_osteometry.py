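"""Traction index, osteometric sexing and withers-height estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleodraught.core import Assemblage, Element, Fusion
from paleodraught.osteometry import (
    SexClass,
    SexRuleConfig,
    TractionVerdict,
    WithersFactors,
    classify_traction,
    gracility_index,
    sex_by_bd,
    sex_by_gracility,
    specimen_summary,
    traction_index,
    withers_height,
)

from conftest import make_metapodial


def test_gracility_index_arithmetic_and_scale_invariance():
    assert gracility_index(200, 32) == pytest.approx(16.0)
    assert gracility_index(200, 36) == pytest.approx(18.0)  # bull band 17-20
    assert gracility_index(400, 64) == gracility_index(200, 32)


def test_gracility_index_rejects_bad_inputs():
    with pytest.raises(ValueError):
        gracility_index(0, 30)
    with pytest.raises(ValueError):
        gracility_index(200, 250)


@pytest.mark.parametrize(
    "bd, expected",
    [
        (60, SexClass.FEMALE),
        (64, SexClass.AMBIGUOUS),
        (66, SexClass.MALE),
        (63, SexClass.AMBIGUOUS),  # boundaries inclusive into the overlap band
        (65, SexClass.AMBIGUOUS),
        ("62.999", SexClass.FEMALE),
        ("65.001", SexClass.MALE),
    ],
)
def test_sex_by_bd_thresholds(bd, expected):
    assert sex_by_bd(bd).klass == expected


@settings(derandomize=True, max_examples=300)
@given(st.floats(min_value=0.1, max_value=200, allow_nan=False))
def test_sex_by_bd_partitions_positive_reals(bd):
    """Every breadth gets exactly one of the three classes, consistent with
    the interval structure."""
    klass = sex_by_bd(bd).klass
    if bd < 63:
        assert klass == SexClass.FEMALE
    elif bd > 65:
        assert klass == SexClass.MALE
    else:
        assert klass == SexClass.AMBIGUOUS


@pytest.mark.parametrize(
    "gl, sd, expected",
    [
        (220, 35, SexClass.CASTRATE_CANDIDATE),  # long + intermediate gracility
        (195, 30, SexClass.FEMALE),
        (200, 36, SexClass.MALE),
        (200, 41, SexClass.AMBIGUOUS),  # gracility 20.5, outside all bands
        (220, 35.2, SexClass.CASTRATE_CANDIDATE),  # gracility 16 < 17: ox rule wins over cow band
        (200, 32, SexClass.FEMALE),  # gracility 16 but GL below the ox length rule
    ],
)
def test_sex_by_gracility_rules_and_precedence(gl, sd, expected):
    assert sex_by_gracility(gl, sd).klass == expected


def test_sex_assignment_records_rule_fired():
    a = sex_by_gracility(220, 35, specimen_id="m1")
    assert a.specimen_id == "m1" and "GL" in a.rule_fired


def test_traction_index_values():
    assert traction_index(30, 30) == pytest.approx(1.0)
    assert traction_index(0.86 * 31.0, 31.0) == pytest.approx(0.86)
    assert traction_index(15, 30) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        traction_index(-1, 30)


@pytest.mark.parametrize(
    "index, expected",
    [
        (0.86, TractionVerdict.TRACTION_CONSISTENT),
        (0.75, TractionVerdict.TRACTION_CONSISTENT),  # inclusive threshold
        ("0.75", TractionVerdict.TRACTION_CONSISTENT),
        (0.74, TractionVerdict.NOT_INDICATED),
        (0.7499999, TractionVerdict.NOT_INDICATED),
    ],
)
def test_classify_traction_inclusive_boundary(index, expected):
    assert classify_traction(index) == expected


@settings(derandomize=True, max_examples=200)
@given(
    st.floats(min_value=0.01, max_value=2.0, allow_nan=False),
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
)
def test_classify_traction_is_monotone(index, bump):
    """Raising the index never flips consistent back to not-indicated."""
    lo = classify_traction(index)
    hi = classify_traction(index + bump)
    assert not (
        lo == TractionVerdict.TRACTION_CONSISTENT and hi == TractionVerdict.NOT_INDICATED
    )


def test_withers_height_anchor_and_linearity():
    h = withers_height(188.6, Element.METACARPAL, SexClass.FEMALE)
    assert h == pytest.approx(113.7, abs=0.05)  # 188.6 mm x 6.03 / 10
    assert withers_height(400, Element.METACARPAL, SexClass.MALE) == pytest.approx(
        2 * withers_height(200, Element.METACARPAL, SexClass.MALE)
    )


def test_withers_height_missing_factor_names_pair():
    factors = WithersFactors(factors={(Element.METACARPAL, SexClass.FEMALE): 6.03})
    with pytest.raises(KeyError, match="metatarsal"):
        withers_height(200, Element.METATARSAL, SexClass.FEMALE, factors)


def test_withers_factor_range_enforced():
    with pytest.raises(ValueError):
        WithersFactors(factors={(Element.METACARPAL, SexClass.FEMALE): 10.0})


# -- synthesis table ---------------------------------------------------------


def test_specimen_summary_empty():
    assert len(specimen_summary(Assemblage([]))) == 0


def test_specimen_summary_composes_sexing_and_traction():
    bull = make_metapodial("m1", GL=200, SD=37, Bd=68, e=0.8 * 33, D1=33)
    a = Assemblage([bull])
    row = specimen_summary(a).iloc[0]
    assert row["sex_bd"] == "male"
    assert row["sex_gracility"] == "male"
    assert row["traction_index"] == pytest.approx(0.8)
    assert row["traction_verdict"] == "traction_consistent"
    assert row["withers_cm_low"] == row["withers_cm_high"] == pytest.approx(200 * 6.33 / 10)


def test_specimen_summary_flags_missing_not_imputes():
    only_bd = make_metapodial("m2", Bd=60)
    row = specimen_summary(Assemblage([only_bd])).iloc[0]
    assert row["sex_bd"] == "female"
    assert row["sex_gracility"] is None
    assert np.isnan(row["withers_cm_low"]) and row["traction_index"] is None


def test_specimen_summary_ambiguous_sex_gets_height_interval():
    amb = make_metapodial("m3", GL=205, SD=42)  # gracility 20.5: ambiguous
    row = specimen_summary(Assemblage([amb])).iloc[0]
    assert row["sex_gracility"] == "ambiguous"
    assert row["withers_cm_low"] == pytest.approx(205 * 6.03 / 10)
    assert row["withers_cm_high"] == pytest.approx(205 * 6.33 / 10)
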