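"""Pathological index, stage distributions, limb bias and reference ranking."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleodraught.core import Assemblage, Limb, OAState, PathologyScores
from paleodraught.pathology import (
    IndexFormula,
    IndexSummary,
    IndexVariant,
    ReferencePopulation,
    compare_reference,
    index_summary,
    limb_bias,
    modified_pathological_index,
    pathological_index,
    stage_distribution,
)

from conftest import make_phalanx

ALL_COMBOS = list(
    itertools.product(
        (1, 2, 3, 4), (1, 2, 3, 4), (1, 2, 3, 4), (OAState.ABSENT, OAState.PRESENT),
        (OAState.ABSENT, OAState.PRESENT),
    )
)


def brute_force_pi(pex, dex, plip, oa_prox, oa_dist, include_dex=True):
    """Independent enumeration of the normalised-sum index."""
    scores = [pex, plip, 1 + (oa_prox == OAState.PRESENT), 1 + (oa_dist == OAState.PRESENT)]
    maxima = [4, 4, 2, 2]
    if include_dex:
        scores.append(dex)
        maxima.append(4)
    return sum(s - 1 for s in scores) / sum(m - 1 for m in maxima)


def test_exhaustive_oracle_all_256_combinations():
    for combo in ALL_COMBOS:
        s = PathologyScores(*combo)
        assert pathological_index(s) == pytest.approx(brute_force_pi(*combo))
        assert modified_pathological_index(s) == pytest.approx(
            brute_force_pi(*combo, include_dex=False)
        )


def test_mpi_invariant_to_dex_all_combinations():
    for pex, _, plip, oa_p, oa_d in ALL_COMBOS:
        values = {
            modified_pathological_index(PathologyScores(pex, dex, plip, oa_p, oa_d))
            for dex in (1, 2, 3, 4)
        }
        assert len(values) == 1


@pytest.mark.parametrize(
    "scores, expected",
    [
        (PathologyScores(1, 1, 1, OAState.ABSENT, OAState.ABSENT), 0.0),
        (PathologyScores(4, 4, 4, OAState.PRESENT, OAState.PRESENT), 1.0),
        # three stage-2 ordinal scores, no osteoarthritis: 3/11
        (PathologyScores(2, 2, 2, OAState.ABSENT, OAState.ABSENT), 3 / 11),
    ],
)
def test_hand_computed_pi_values(scores, expected):
    assert pathological_index(scores) == pytest.approx(expected)


def test_hand_computed_mpi_value():
    # pex=2, plip=2, no osteoarthritis, dex irrelevant: 2/8
    s = PathologyScores(2, 4, 2, OAState.ABSENT, OAState.ABSENT)
    assert modified_pathological_index(s) == pytest.approx(0.25)


def test_feature_mean_variant():
    s = PathologyScores(2, 2, 2, OAState.ABSENT, OAState.ABSENT)
    f = IndexFormula.pathological(IndexVariant.FEATURE_MEAN)
    assert pathological_index(s, f) == pytest.approx((3 * (1 / 3) + 0 + 0) / 5)


def test_missing_score_names_feature():
    s = PathologyScores(pex=2, dex=None, plip=2)
    with pytest.raises(ValueError, match="dex"):
        pathological_index(s)


def test_oa_coding_flip():
    f = IndexFormula(oa_present_is_high=False)
    present = PathologyScores(1, 1, 1, OAState.PRESENT, OAState.PRESENT)
    absent = PathologyScores(1, 1, 1, OAState.ABSENT, OAState.ABSENT)
    assert pathological_index(present, f) == 0.0
    assert pathological_index(absent, f) == pytest.approx(2 / 11)


@settings(derandomize=True, max_examples=200)
@given(
    base=st.tuples(
        st.integers(1, 4), st.integers(1, 4), st.integers(1, 4),
        st.booleans(), st.booleans(),
    ),
    feature=st.integers(0, 4),
)
def test_index_monotone_in_every_score(base, feature):
    """Raising any single feature's score never lowers PI or MPI."""

    def build(values):
        pex, dex, plip, p1, p2 = values
        return PathologyScores(
            pex, dex, plip,
            OAState.PRESENT if p1 else OAState.ABSENT,
            OAState.PRESENT if p2 else OAState.ABSENT,
        )

    raised = list(base)
    limit = 4 if feature < 3 else True
    if raised[feature] == limit:
        return
    raised[feature] = raised[feature] + 1 if feature < 3 else True
    lo, hi = build(base), build(raised)
    assert pathological_index(hi) >= pathological_index(lo)
    assert modified_pathological_index(hi) >= modified_pathological_index(lo)
    assert 0.0 <= pathological_index(hi) <= 1.0


# -- stage distributions -----------------------------------------------------


def test_stage_distribution_all_stage_two():
    a = Assemblage([make_phalanx(f"p{i}", plip=2) for i in range(3)])
    d = stage_distribution(a, "plip")
    assert [d.frequencies[k] for k in (1, 2, 3, 4)] == [0.0, 1.0, 0.0, 0.0]


def test_stage_distribution_single_stage_three_among_forty():
    specs = [make_phalanx(f"p{i}", plip=1) for i in range(39)]
    specs.append(make_phalanx("p39", plip=3))
    d = stage_distribution(Assemblage(specs), "plip")
    assert d.frequencies[3] == pytest.approx(1 / 40)
    assert sum(d.frequencies.values()) == pytest.approx(1.0)


def test_stage_distribution_empty_is_flagged():
    d = stage_distribution(Assemblage([]), "pex")
    assert d.empty and d.total == 0


def test_stage_distribution_respects_limb_filter():
    a = Assemblage(
        [make_phalanx("a", limb=Limb.ANTERIOR, pex=2), make_phalanx("b", limb=Limb.POSTERIOR, pex=4)]
    )
    assert stage_distribution(a, "pex", Limb.ANTERIOR).counts[2] == 1
    assert stage_distribution(a, "pex", Limb.ANTERIOR).counts[4] == 0
    assert stage_distribution(a, "pex").total == 2


# -- summaries and limb bias -------------------------------------------------


def test_index_summary_single_minimal_specimen():
    s = index_summary(Assemblage([make_phalanx("p1")]))
    assert s.n_anterior == 1 and s.n_posterior == 0
    assert s.mean_pi_anterior == 0.0
    assert np.isnan(s.mean_pi_posterior)


def test_index_summary_mean_is_arithmetic_and_order_invariant():
    specs = [
        make_phalanx("a", pex=2),          # PI 1/11
        make_phalanx("b", pex=3, plip=2),  # PI 3/11
    ]
    expected = np.mean([1 / 11, 3 / 11])
    for order in (specs, specs[::-1]):
        s = index_summary(Assemblage(list(order)))
        assert s.mean_pi_anterior == pytest.approx(expected)


def test_limb_bias_zero_for_identical_score_sets():
    specs = []
    for limb, tag in ((Limb.ANTERIOR, "a"), (Limb.POSTERIOR, "p")):
        specs += [
            make_phalanx(f"{tag}1", limb=limb, pex=2, plip=3),
            make_phalanx(f"{tag}2", limb=limb, dex=2),
        ]
    b = limb_bias(Assemblage(specs), n_boot=200, seed=0)
    assert b.difference == pytest.approx(0.0)


def test_limb_bias_is_bit_reproducible(herd_small):
    _, assemblage, _ = herd_small
    from paleodraught.io import Analysis, select_analysable

    phal = select_analysable(assemblage, Analysis.PHALANX_INDEX)
    b1 = limb_bias(phal, n_boot=500, seed=42)
    b2 = limb_bias(phal, n_boot=500, seed=42)
    assert (b1.difference, b1.ci_low, b1.ci_high) == (b2.difference, b2.ci_low, b2.ci_high)


def test_limb_bias_requires_both_limbs():
    with pytest.raises(ValueError, match="both limbs"):
        limb_bias(Assemblage([make_phalanx("a")]), n_boot=10, seed=0)


# -- reference comparison ----------------------------------------------------


REFS = [
    ReferencePopulation("oxen", mean_mpi_anterior=0.32, mean_mpi_posterior=0.41, draught=True),
    ReferencePopulation("bulls", mean_mpi_anterior=0.05, mean_mpi_posterior=0.04),
]


def summary_with(ant, post):
    return IndexSummary(10, 10, ant, post, ant, post)


def test_query_with_zero_index_ranks_lowest():
    table = compare_reference(summary_with(0.0, 0.0), REFS, query_name="site")
    for limb in ("anterior", "posterior"):
        sub = table[table.limb == limb].reset_index(drop=True)
        assert sub.loc[0, "population"] == "site"
        assert not sub["query_exceeds"].dropna().any()


def test_intermediate_query_flagged_as_draught_like():
    table = compare_reference(summary_with(0.16, 0.20), REFS, query_name="site")
    q = table[(table.is_query) & (table.limb == "anterior")].iloc[0]
    assert q["note"] == "intermediate, draught-like ordering"
    bulls = table[(table.population == "bulls") & (table.limb == "anterior")].iloc[0]
    assert bulls["query_exceeds"]


def test_duplicate_reference_adds_its_rows():
    t1 = compare_reference(summary_with(0.2, 0.2), REFS)
    t2 = compare_reference(summary_with(0.2, 0.2), REFS + [REFS[1]])
    assert len(t2) == len(t1) + 2  # one row per reported limb mean
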