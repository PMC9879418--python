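"""Properties of the synthetic herd and assemblage generator."""

import numpy as np
import pytest
from scipy import stats

from paleodraught.core import Element, Fusion, Limb
from paleodraught.io import write_assemblage
from paleodraught.mortality import MandibleAgeRecord, assign_age_class
from paleodraught.simulate import (
    HerdConfig,
    PathologyModelParams,
    TaphonomyConfig,
    generate_assemblage,
    simulate_herd,
    simulate_measurements,
    simulate_pathology,
)


def test_same_seed_reproduces_bit_identical_output(tmp_path):
    cfg = HerdConfig(n_individuals=30, seed=77)
    a1, t1 = generate_assemblage(cfg)
    a2, t2 = generate_assemblage(cfg)
    assert t1.equals(t2)
    p1, p2 = tmp_path / "a1.csv", tmp_path / "a2.csv"
    write_assemblage(a1, p1)
    write_assemblage(a2, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_zero_traction_fraction_means_no_worked_animals():
    truth = simulate_herd(HerdConfig(n_individuals=300, traction_fraction=0.0, seed=2))
    assert not truth["worked"].any()


def test_invalid_sex_simplex_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        HerdConfig(sex_proportions=(0.5, 0.5, 0.5))


def test_worked_share_matches_traction_fraction():
    cfg = HerdConfig(n_individuals=10_000, traction_fraction=0.3, seed=4)
    truth = simulate_herd(cfg)
    eligible = truth[
        truth["sex"].isin(("bull", "castrate")) & (truth["age_months"] >= cfg.adult_min_months)
    ]
    share = eligible["worked"].mean()
    se = (0.3 * 0.7 / len(eligible)) ** 0.5
    assert abs(share - 0.3) < 4 * se


def test_degenerate_thresholds_give_all_score_one():
    p = PathologyModelParams(
        thresholds={"pex": (60, 60, 60), "dex": (60, 60, 60), "plip": (60, 60, 60)},
        oa_thresholds={"oa_prox": 60, "oa_dist": 60},
    )
    rng = np.random.default_rng(0)
    for _ in range(50):
        s = simulate_pathology(48, Limb.POSTERIOR, True, p, rng)
        assert (s.pex, s.dex, s.plip) == (1, 1, 1)


def test_worked_scores_stochastically_dominate_unworked():
    p = PathologyModelParams()
    rng = np.random.default_rng(11)
    worked = [simulate_pathology(40, Limb.POSTERIOR, True, p, rng).plip for _ in range(2000)]
    unworked = [simulate_pathology(40, Limb.POSTERIOR, False, p, rng).plip for _ in range(2000)]
    for k in (2, 3, 4):
        assert np.mean(np.array(worked) >= k) > np.mean(np.array(unworked) >= k)


def test_hindlimb_bias_in_worked_scores():
    p = PathologyModelParams()
    rng = np.random.default_rng(12)
    post = [simulate_pathology(40, Limb.POSTERIOR, True, p, rng).plip for _ in range(2000)]
    ant = [simulate_pathology(40, Limb.ANTERIOR, True, p, rng).plip for _ in range(2000)]
    assert np.mean(post) > np.mean(ant)


def test_score_marginals_match_cumulative_logit_closed_form():
    """Chi-square goodness of fit of simulated stages against the model's
    closed-form stage probabilities."""
    p = PathologyModelParams()
    rng = np.random.default_rng(13)
    n = 5000
    draws = [simulate_pathology(60, Limb.POSTERIOR, True, p, rng).plip for _ in range(n)]
    observed = np.bincount(draws, minlength=5)[1:5]
    expected = p.stage_probabilities("plip", 60, Limb.POSTERIOR, True) * n
    _, pval = stats.chisquare(observed, expected)
    assert pval > 1e-3


def test_measurement_degenerate_sd_returns_means():
    cfg = HerdConfig()
    model = {k: dict(v) for k, v in cfg.measurement_model.items()}
    key = (Element.METACARPAL, "cow")
    model[key] = {code: (mean, 1e-9) for code, (mean, _) in model[key].items()}
    cfg2 = HerdConfig(measurement_model=model)
    m = simulate_measurements(Element.METACARPAL, "cow", False, cfg2, np.random.default_rng(0))
    for code, (mean, _) in model[key].items():
        assert m[code] == pytest.approx(mean, rel=1e-6)


def test_sexual_dimorphism_in_simulated_breadths():
    cfg = HerdConfig()
    rng = np.random.default_rng(14)
    cows = [simulate_measurements(Element.METACARPAL, "cow", False, cfg, rng)["Bd"] for _ in range(1000)]
    bulls = [simulate_measurements(Element.METACARPAL, "bull", False, cfg, rng)["Bd"] for _ in range(1000)]
    assert np.mean(bulls) > np.mean(cows)


def test_traction_signal_separates_at_075():
    cfg = HerdConfig()
    rng = np.random.default_rng(15)
    worked = [simulate_measurements(Element.METATARSAL, "bull", True, cfg, rng) for _ in range(1000)]
    unworked = [simulate_measurements(Element.METATARSAL, "bull", False, cfg, rng) for _ in range(1000)]
    frac_worked = np.mean([m["e"] / m["D1"] >= 0.75 for m in worked])
    frac_unworked = np.mean([m["e"] / m["D1"] < 0.75 for m in unworked])
    assert frac_worked > 0.9
    assert frac_unworked > 0.9


def test_missing_measurement_model_entry_is_hard_failure():
    cfg = HerdConfig()
    with pytest.raises(KeyError, match="phalanx1"):
        simulate_measurements(Element.PHALANX1, "cow", False, cfg, np.random.default_rng(0))


# -- assemblage generation ---------------------------------------------------


def test_full_recovery_gives_exact_element_multiples():
    cfg = HerdConfig(n_individuals=12, seed=6)
    t = TaphonomyConfig(recovery_rate=1.0, surface_erosion_rate=0.0, unfused_removal_rate=0.0)
    a, truth = generate_assemblage(cfg, t)
    # per skeleton: 2 metacarpals + 2 metatarsals + 8 + 8 phalanges + 1 mandible
    assert len(a) == 21 * 12
    assert len(a.by_element(Element.PHALANX1)) == 8 * 12
    assert len(a.by_element(Element.MANDIBLE)) == 12


def test_taphonomy_only_removes_or_blanks_never_alters():
    cfg = HerdConfig(n_individuals=30, seed=8)
    full, _ = generate_assemblage(
        cfg, TaphonomyConfig(recovery_rate=1.0, surface_erosion_rate=0.0, unfused_removal_rate=0.0)
    )
    thinned, _ = generate_assemblage(
        cfg, TaphonomyConfig(recovery_rate=0.6, surface_erosion_rate=0.7, unfused_removal_rate=0.9)
    )
    by_id = {s.specimen_id: s for s in full}
    assert len(thinned) < len(full)
    for s in thinned:
        original = by_id[s.specimen_id]
        for code, value in s.measurements.items():
            assert value == original.measurements[code]
        if s.pathology is not None:
            assert s.pathology == original.pathology


def test_generated_mws_recovers_true_age_class():
    cfg = HerdConfig(n_individuals=80, seed=10)
    a, truth = generate_assemblage(cfg, TaphonomyConfig(recovery_rate=1.0))
    classes = truth.set_index("individual_id")["age_class"]
    for s in a.by_element(Element.MANDIBLE):
        record = MandibleAgeRecord(s.specimen_id, s.side, s.mandible_wear.mws)
        assert assign_age_class(record, cfg.scheme) == classes[s.individual_id]


def test_fusion_state_follows_age():
    cfg = HerdConfig(n_individuals=60, seed=16)
    a, truth = generate_assemblage(cfg, TaphonomyConfig(recovery_rate=1.0))
    ages = truth.set_index("individual_id")["age_months"]
    for s in a.by_element(Element.METACARPAL, Element.METATARSAL):
        expected = Fusion.FUSED if ages[s.individual_id] >= cfg.fusion_age_months else Fusion.UNFUSED
        assert s.distal_fusion == expected
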