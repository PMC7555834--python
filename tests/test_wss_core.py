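import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wsstrack.datatypes import SampleQc, SpeciesRef, WssScore
from wsstrack.qc_filters import build_window_mask, sample_qc
from wsstrack.wss_core import call_relatedness, compute_wss, score_all_pairs, window_similarity

from conftest import full_mask, make_profile, make_track, naive_wss, passing_qc, uniform_track


class TestWindowSimilarity:
    def test_identical_alleles_give_one(self):
        calls = {i * 10 + 1: 1 for i in range(8)}
        a, b = make_profile("a", calls), make_profile("b", calls)
        assert window_similarity(a, b, (0, 100)) == 1.0

    def test_three_of_four_matches(self):
        a = make_profile("a", {1: 1, 2: 1, 3: 1, 4: 1})
        b = make_profile("b", {1: 1, 2: 1, 3: 1, 4: 2})
        assert window_similarity(a, b, (0, 10)) == 0.75

    def test_reference_genotype_counts_as_mismatch_against_alt(self):
        # b was genotyped reference (0) at a's variant positions
        a = make_profile("a", {5: 1, 6: 2})
        b = make_profile("b", {5: 0, 6: 2})
        assert window_similarity(a, b, (0, 10)) == 0.5

    def test_missing_positions_are_excluded_not_mismatched(self):
        a = make_profile("a", {5: 1, 6: 1})
        b = make_profile("b", {6: 1})  # no call at 5
        assert window_similarity(a, b, (0, 10)) == 1.0

    def test_empty_shared_set_is_undefined(self):
        a, b = make_profile("a", {5: 1}), make_profile("b", {500: 1})
        assert window_similarity(a, b, (0, 10)) is None


class TestComputeWss:
    def test_identical_profiles_full_coverage_score_100(self, species):
        calls = {i * 37 + 1: 1 for i in range(100)}
        a, b = make_profile("a", calls), make_profile("b", calls)
        mask = full_mask(species, ["a", "b"])
        s = compute_wss(a, b, mask, passing_qc("a"), passing_qc("b"))
        assert s.valid and s.wss == 100.0

    def test_disjoint_alt_sets_score_near_zero_matching_oracle(self, species):
        rng = np.random.default_rng(42)
        pos = rng.choice(4000, size=100, replace=False) + 1
        # joint VCF: both samples genotyped at every record, alt in only one
        calls_a = {int(p): (1 if i < 50 else 0) for i, p in enumerate(pos)}
        calls_b = {int(p): (0 if i < 50 else 1) for i, p in enumerate(pos)}
        a, b = make_profile("a", calls_a), make_profile("b", calls_b)
        mask = full_mask(species, ["a", "b"])
        s = compute_wss(a, b, mask, passing_qc("a"), passing_qc("b"))
        depths = np.full(4000, 20)
        expected = naive_wss(calls_a, calls_b, depths, depths, 4000, 1000)
        assert s.wss == pytest.approx(expected, abs=1e-12)
        assert s.wss == 0.0

    def test_qc_failure_invalidates_score(self, species):
        calls = {1: 1, 2: 1}
        a, b = make_profile("a", calls), make_profile("b", calls)
        mask = full_mask(species, ["a", "b"])
        failed = SampleQc("a", "sp1", breadth=0.1, mean_depth=1.0, passed=False)
        s = compute_wss(a, b, mask, failed, passing_qc("b"))
        assert not s.valid and math.isnan(s.wss)

    def test_species_mismatch_rejected(self, species):
        a = make_profile("a", {1: 1})
        b = make_profile("b", {1: 1}, species_id="other")
        mask = full_mask(species, ["a", "b"])
        with pytest.raises(ValueError, match="species mismatch"):
            compute_wss(a, b, mask, passing_qc("a"), passing_qc("b"))

    def test_min_windows_invalidates_sparse_pairs(self, species):
        a, b = make_profile("a", {1: 1}), make_profile("b", {1: 1})
        mask = full_mask(species, ["a", "b"])
        s = compute_wss(a, b, mask, passing_qc("a"), passing_qc("b"), min_windows=2)
        assert s.n_windows_used == 1 and not s.valid

    def test_weighted_variant_weights_by_position_count(self, species):
        # window 1: 1 shared position, mismatch; window 2: 3 shared, all match
        a = make_profile("a", {10: 1, 1010: 1, 1020: 1, 1030: 1})
        b = make_profile("b", {10: 2, 1010: 1, 1020: 1, 1030: 1})
        mask = full_mask(species, ["a", "b"])
        unweighted = compute_wss(a, b, mask, passing_qc("a"), passing_qc("b"))
        weighted = compute_wss(a, b, mask, passing_qc("a"), passing_qc("b"),
                               weight_by_positions=True)
        assert unweighted.wss == pytest.approx(50.0)
        assert weighted.wss == pytest.approx(75.0)

    def test_oracle_equivalence_on_random_small_instances(self):
        """compute_wss equals a naive position-by-position recomputation on
        many random small references (<= 5 kb), including window dropout."""
        rng = np.random.default_rng(2024)
        for trial in range(60):
            ref_len = int(rng.integers(500, 5001))
            window = int(rng.integers(100, 2000))
            sp = SpeciesRef(species_id="sp1", reference_length=ref_len)
            n_sites = int(rng.integers(1, max(2, ref_len // 20)))
            pos = rng.choice(ref_len, size=n_sites, replace=False) + 1
            calls_a = {int(p): int(rng.integers(0, 3)) for p in pos}
            calls_b = {int(p): int(rng.integers(0, 3)) for p in pos if rng.random() > 0.1}
            depths_a = rng.choice([0, 2, 20], size=ref_len, p=[0.1, 0.2, 0.7])
            depths_b = rng.choice([0, 2, 20], size=ref_len, p=[0.1, 0.2, 0.7])
            a, b = make_profile("a", calls_a), make_profile("b", calls_b)
            tr_a, tr_b = make_track("a", depths_a), make_track("b", depths_b)
            mask = build_window_mask([tr_a, tr_b], sp, window_size=window)
            s = compute_wss(a, b, mask, passing_qc("a"), passing_qc("b"))
            expected = naive_wss(calls_a, calls_b, depths_a, depths_b, ref_len, window)
            if expected is None:
                assert not s.valid
            else:
                assert s.valid, f"trial {trial}"
                assert abs(s.wss - expected) < 1e-12, f"trial {trial}"

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.dictionaries(st.integers(min_value=1, max_value=4000),
                           st.integers(min_value=0, max_value=2), max_size=60),
           st.dictionaries(st.integers(min_value=1, max_value=4000),
                           st.integers(min_value=0, max_value=2), max_size=60))
    def test_symmetry_and_bounds(self, calls_a, calls_b):
        sp = SpeciesRef(species_id="sp1", reference_length=4000)
        a, b = make_profile("a", calls_a), make_profile("b", calls_b)
        mask = full_mask(sp, ["a", "b"])
        ab = compute_wss(a, b, mask, passing_qc("a"), passing_qc("b"))
        ba = compute_wss(b, a, mask, passing_qc("b"), passing_qc("a"))
        assert (ab.wss == ba.wss) or (math.isnan(ab.wss) and math.isnan(ba.wss))
        assert ab.valid == ba.valid
        if ab.valid:
            assert 0.0 <= ab.wss <= 100.0

    def test_self_comparison_scores_100_at_full_coverage(self, species):
        calls = {i * 13 + 1: i % 3 for i in range(200)}
        a = make_profile("a", calls)
        b = make_profile("b", calls)
        mask = full_mask(species, ["a", "b"])
        assert compute_wss(a, b, mask, passing_qc("a"), passing_qc("b")).wss == 100.0

    def test_fixing_a_mismatch_never_decreases_wss(self, species):
        rng = np.random.default_rng(5)
        pos = [int(p) + 1 for p in rng.choice(4000, size=80, replace=False)]
        calls_a = {p: int(rng.integers(0, 3)) for p in pos}
        calls_b = {p: int(rng.integers(0, 3)) for p in pos}
        mask = full_mask(species, ["a", "b"])
        qa, qb = passing_qc("a"), passing_qc("b")
        base = compute_wss(make_profile("a", calls_a), make_profile("b", calls_b), mask, qa, qb)
        for p in pos:
            if calls_a[p] != calls_b[p]:
                fixed = dict(calls_b)
                fixed[p] = calls_a[p]
                s = compute_wss(make_profile("a", calls_a), make_profile("b", fixed), mask, qa, qb)
                assert s.wss >= base.wss - 1e-12


class TestCallRelatedness:
    @staticmethod
    def score(wss, valid=True):
        return WssScore(species_id="sp1", sample_a="a", sample_b="b", wss=wss,
                        n_windows_used=1, n_windows_total=1, valid=valid)

    def test_above_cutoff_is_related(self):
        call = call_relatedness(self.score(100.0), {"sp1": 87.5})
        assert call.related

    def test_exactly_at_cutoff_is_unrelated(self):
        call = call_relatedness(self.score(87.5), {"sp1": 87.5})
        assert not call.related

    def test_low_score_is_unrelated(self):
        call = call_relatedness(self.score(8.0), {"sp1": 87.5})
        assert not call.related

    def test_invalid_score_rejected(self):
        with pytest.raises(ValueError, match="invalid score"):
            call_relatedness(self.score(float("nan"), valid=False), {"sp1": 87.5})

    def test_missing_cutoff_excludes_species(self):
        assert call_relatedness(self.score(99.0), {}) is None


def test_score_all_pairs_deterministic_order(species):
    calls = {1: 1}
    profiles = [make_profile(s, calls) for s in ("c", "a", "b")]
    mask = full_mask(species, ["a", "b", "c"])
    qcs = {s: passing_qc(s) for s in ("a", "b", "c")}
    scores = score_all_pairs(profiles, mask, qcs)
    assert [(s.sample_a, s.sample_b) for s in scores] == [("a", "b"), ("a", "c"), ("b", "c")]
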