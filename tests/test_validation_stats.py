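"""Set similarities, permutation null, ratio stratifications, profile correlation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genedrug import validation_stats as vs
from genedrug.data_model import ValidationError
from genedrug.druggability import score_all
from genedrug.synthetic_data import SimulationConfig, generate
from genedrug.validation_stats import (
    OntologyConcept,
    Stratifier,
    czekanowski_dice,
    clinically_active_ratio,
    disease_profile_correlation,
    lin_similarity,
    permutation_test,
    stratified_ratio_curve,
    tanimoto,
)


class TestTanimoto:
    @pytest.mark.parametrize(
        "na, nb, nab, expected", [(5, 5, 5, 1.0), (3, 4, 0, 0.0), (3, 4, 2, 0.4)]
    )
    def test_values(self, na, nb, nab, expected):
        assert tanimoto(na, nb, nab) == pytest.approx(expected)

    def test_invalid_intersection_rejected(self):
        with pytest.raises(ValidationError):
            tanimoto(2, 3, 4)
        with pytest.raises(ValidationError):
            tanimoto(0, 0, 0)

    @given(st.sets(st.integers(0, 30)), st.sets(st.integers(0, 30)))
    @settings(deadline=None, max_examples=60)
    def test_symmetric_and_identity_iff_equal_sets(self, a, b):
        if not a | b:
            return
        t_ab = tanimoto(len(a), len(b), len(a & b))
        assert t_ab == tanimoto(len(b), len(a), len(a & b))
        assert (t_ab == 1.0) == (a == b)


def _toy_ontology():
    # root -> {mid1, mid2}; mid1 -> leaf1; {mid1, mid2} -> leaf2
    concepts = [
        OntologyConcept("root", frozenset(), 1.0),
        OntologyConcept("mid1", frozenset({"root"}), 0.4),
        OntologyConcept("mid2", frozenset({"root"}), 0.5),
        OntologyConcept("leaf1", frozenset({"mid1"}), 0.1),
        OntologyConcept("leaf2", frozenset({"mid1", "mid2"}), 0.05),
    ]
    return {c.concept_id: c for c in concepts}


class TestLin:
    def test_self_similarity_is_half_as_printed(self):
        ont = _toy_ontology()
        c = ont["leaf1"]
        assert lin_similarity(c, c, ont) == pytest.approx(0.5)
        assert lin_similarity(c, c, ont, canonical=True) == pytest.approx(1.0)

    def test_root_subsumer_gives_zero(self):
        ont = _toy_ontology()
        ont["lone"] = OntologyConcept("lone", frozenset({"root"}), 0.3)
        # leaf1 and lone share only the root, whose IC is 0
        assert lin_similarity(ont["leaf1"], ont["lone"], ont) == 0.0

    def test_lcs_matches_exhaustive_ancestor_search(self):
        ont = _toy_ontology()
        c1, c2 = ont["leaf1"], ont["leaf2"]
        # brute force: enumerate common ancestors, take max IC
        def ancestors(cid):
            out = {cid}
            frontier = set(ont[cid].parents)
            while frontier:
                out |= frontier
                frontier = {p for f in frontier for p in ont[f].parents} - out
            return out

        common = ancestors("leaf1") & ancestors("leaf2")
        best_ic = max(-math.log(ont[c].probability) for c in common)
        expected = best_ic / (c1.ic + c2.ic)
        assert lin_similarity(c1, c2, ont) == pytest.approx(expected)
        assert common == {"root", "mid1"}  # mid1 is the max-IC subsumer

    def test_disconnected_concepts_are_undefined(self):
        ont = _toy_ontology()
        ont["island"] = OntologyConcept("island", frozenset(), 0.2)
        assert math.isnan(lin_similarity(ont["leaf1"], ont["island"], ont))


class TestCzekanowskiDice:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"x", "y"}, {"x", "y"}, 0.0),
            ({"x"}, {"y"}, 1.0),
            ({"a", "b", "c"}, {"b", "c", "d"}, 1 / 3),
        ],
    )
    def test_values(self, a, b, expected):
        assert czekanowski_dice(a, b) == pytest.approx(expected)

    def test_both_empty_is_undefined(self):
        assert math.isnan(czekanowski_dice(set(), set()))

    @given(st.sets(st.integers(0, 20)), st.sets(st.integers(0, 20)))
    @settings(deadline=None, max_examples=60)
    def test_bounded_symmetric_distance(self, a, b):
        if not a and not b:
            return
        d = czekanowski_dice(a, b)
        assert 0.0 <= d <= 1.0
        assert d == czekanowski_dice(b, a)


class TestClinicallyActiveRatio:
    def test_counts_on_small_subset(self, minimal_ds):
        subset = [("agent01", "d1"), ("agent06", "d1"), ("agent05", "d1"), ("agent02", "d1")]
        # agent01/d1 approved, agent06/d1 clinical-only, other two unindicated
        clin, appr = clinically_active_ratio(minimal_ds, subset)
        assert (clin, appr) == (0.5, 0.25)

    def test_no_indications_gives_zero(self, minimal_ds):
        clin, appr = clinically_active_ratio(minimal_ds, [("agent02", "d1")])
        assert (clin, appr) == (0.0, 0.0)

    def test_empty_subset_undefined(self, minimal_ds):
        clin, appr = clinically_active_ratio(minimal_ds, [])
        assert math.isnan(clin) and math.isnan(appr)

    def test_matches_hand_count_on_synthetic_corpus(self, small_synthetic):
        ds, _ = small_synthetic
        from genedrug.data_model import IndicationStatus, eligible_pairs

        pairs = sorted(eligible_pairs(ds))[:100]
        status = ds.indication_map()
        clin, appr = clinically_active_ratio(ds, pairs)
        assert clin == sum(1 for p in pairs if p in status) / 100
        assert appr == sum(
            1 for p in pairs if status.get(p) is IndicationStatus.APPROVED
        ) / 100
        assert appr <= clin


class TestPermutationTest:
    def test_same_seed_reproduces_null(self, small_synthetic):
        ds, _ = small_synthetic
        _, null_a, p_a = permutation_test(ds, n_perm=50, seed=3)
        _, null_b, p_b = permutation_test(ds, n_perm=50, seed=3)
        assert (null_a == null_b).all() and p_a == p_b

    def test_p_floor_when_observed_beats_all_nulls(self, small_synthetic):
        ds, _ = small_synthetic
        obs, null, p = permutation_test(ds, n_perm=200, seed=0)
        if (null >= obs).sum() == 0:
            assert p == pytest.approx(1 / 201)
        assert p >= 1 / 201

    def test_shuffle_preserves_degree_sequences(self, small_synthetic):
        # the scheme permutes the gene column: drug slot counts and the
        # global target multiset are preserved by construction
        ds, _ = small_synthetic
        rng = np.random.default_rng(1)
        flat = [g for d in sorted(ds.drugs, key=lambda d: d.drug_id) for g in sorted(d.targets)]
        for _ in range(5):
            perm = rng.permutation(len(flat))
            shuffled = [flat[i] for i in perm]
            assert sorted(shuffled) == sorted(flat)  # multiset preserved
            assert len(shuffled) == len(flat)


class TestStratifiedRatioCurve:
    def test_planted_effect_gives_positive_trend(self):
        ds, _ = generate(SimulationConfig(seed=21))
        _, trend = stratified_ratio_curve(ds, Stratifier.DRUGGABILITY_SCORE_BIN, 5)
        assert trend > 0

    def test_target_count_stratifier_also_rises(self):
        ds, _ = generate(SimulationConfig(seed=22))
        _, trend = stratified_ratio_curve(ds, Stratifier.TARGET_COUNT, 4)
        assert trend > 0

    def test_single_bin_equals_global_ratio(self, small_synthetic):
        ds, _ = small_synthetic
        from genedrug.data_model import eligible_pairs

        points, trend = stratified_ratio_curve(ds, Stratifier.TARGET_COUNT, 1)
        assert len(points) == 1
        clin, appr = clinically_active_ratio(ds, eligible_pairs(ds))
        assert points[0].clinically_active_ratio == pytest.approx(clin)
        assert points[0].approved_ratio == pytest.approx(appr)
        assert math.isnan(trend)

    def test_empty_bins_emit_nan_points(self, small_synthetic):
        ds, _ = small_synthetic
        points, _ = stratified_ratio_curve(
            ds, Stratifier.OHNOLOG_COVERAGE, [0, 1, 2, 50, 100]
        )
        empty = [p for p in points if p.n_pairs == 0]
        assert all(math.isnan(p.clinically_active_ratio) for p in empty)

    def test_bins_must_cover_range(self, small_synthetic):
        ds, _ = small_synthetic
        with pytest.raises(ValidationError):
            stratified_ratio_curve(ds, Stratifier.TARGET_COUNT, [0.5, 0.6])


class TestDiseaseProfileCorrelation:
    def test_identical_profiles_correlate_perfectly(self):
        scores = {("g1", "dA"): 8, ("g2", "dA"): 4, ("g3", "dA"): 2,
                  ("g1", "dB"): 8, ("g2", "dB"): 4, ("g3", "dB"): 2}
        assert disease_profile_correlation(scores, "dA", "dB") == pytest.approx(1.0)

    def test_reversed_ranking_gives_minus_one(self):
        scores = {("g1", "dA"): 9, ("g2", "dA"): 5, ("g3", "dA"): 1,
                  ("g1", "dB"): 1, ("g2", "dB"): 5, ("g3", "dB"): 9}
        assert disease_profile_correlation(scores, "dA", "dB") == pytest.approx(-1.0)

    def test_matches_hand_rank_arithmetic(self):
        # six genes; dB seen only on four of them (others score 0)
        scores = {("g1", "dA"): 10, ("g2", "dA"): 8, ("g3", "dA"): 6,
                  ("g4", "dA"): 4, ("g5", "dA"): 2, ("g6", "dA"): 1,
                  ("g1", "dB"): 3, ("g2", "dB"): 9, ("g4", "dB"): 5, ("g6", "dB"): 7}
        from scipy import stats

        a = [10, 8, 6, 4, 2, 1]
        b = [3, 9, 0, 5, 0, 7]
        expected = stats.spearmanr(a, b).statistic
        assert disease_profile_correlation(scores, "dA", "dB") == pytest.approx(expected)

    def test_too_few_genes_undefined(self):
        scores = {("g1", "dA"): 3, ("g1", "dB"): 2}
        assert math.isnan(disease_profile_correlation(scores, "dA", "dB"))


def test_profile_correlation_on_scored_corpus(small_synthetic):
    ds, _ = small_synthetic
    scores = score_all(ds)
    r = disease_profile_correlation(scores, ds.diseases[0], ds.diseases[0])
    assert r == pytest.approx(1.0)
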