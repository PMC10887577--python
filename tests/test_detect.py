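"""ROH scanner: window semantics, hit fractions against brute-force
enumeration, run criteria, and equivalence with the literal oracle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rohscan.detect import (
    RohParams,
    call_roh_cohort,
    call_roh_individual,
    snp_hit_fraction,
    window_is_hit,
)
from rohscan.genotypes import HET, HOM_ALT, HOM_REF, MISSING
from rohscan.reference import oracle_call_roh

from conftest import make_matrix, random_scan_instance

DEFAULT = RohParams()


class TestWindowIsHit:
    def test_one_het_allowed(self):
        codes = np.full(50, HOM_REF)
        codes[10] = HET
        assert window_is_hit(codes, DEFAULT)

    def test_two_het_not_allowed(self):
        codes = np.full(50, HOM_REF)
        codes[[10, 20]] = HET
        assert not window_is_hit(codes, DEFAULT)

    def test_five_missing_allowed_six_not(self):
        codes = np.full(50, HOM_ALT)
        codes[:5] = MISSING
        assert window_is_hit(codes, DEFAULT)
        codes[5] = MISSING
        assert not window_is_hit(codes, DEFAULT)

    def test_all_homozygous_is_hit(self):
        assert window_is_hit(np.full(50, HOM_REF), DEFAULT)

    def test_wrong_window_length_rejected(self):
        with pytest.raises(ValueError):
            window_is_hit(np.full(49, HOM_REF), DEFAULT)


class TestSnpHitFraction:
    def test_all_homozygous_chromosome_is_one_everywhere(self):
        frac = snp_hit_fraction(np.full(200, HOM_REF), DEFAULT)
        assert (frac == 1.0).all()

    def test_all_het_chromosome_is_zero_everywhere(self):
        frac = snp_hit_fraction(np.full(200, HET), DEFAULT)
        assert (frac == 0.0).all()

    def test_short_chromosome_has_no_windows(self):
        frac = snp_hit_fraction(np.full(49, HOM_REF), DEFAULT)
        assert (frac == 0.0).all()

    def test_matches_explicit_enumeration(self):
        """300 random SNPs: fraction equals enumerating every window per SNP."""
        rng = np.random.default_rng(3)
        codes = rng.choice([0, 1, 2, 3], size=300, p=[0.45, 0.08, 0.42, 0.05])
        params = RohParams(window_snp=20, window_het_max=1, window_missing_max=2)
        frac = snp_hit_fraction(codes, params)
        w = params.window_snp
        for i in range(300):
            containing = [
                s
                for s in range(300 - w + 1)
                if s <= i <= s + w - 1
            ]
            hits = sum(
                1
                for s in containing
                if (codes[s : s + w] == HET).sum() <= 1
                and (codes[s : s + w] == MISSING).sum() <= 2
            )
            assert frac[i] == pytest.approx(hits / len(containing))


class TestCallRoh:
    def test_ideal_run_emits_one_full_segment(self):
        matrix = make_matrix(np.full((1000, 1), HOM_REF), spacing=2000)
        (seg,) = call_roh_cohort(matrix)
        assert (seg.start_bp, seg.end_bp, seg.n_snps) == (2000, 2_000_000, 1000)

    def test_run_under_100kb_rejected(self):
        # 60 homozygous SNPs spanning 90 kb fail the minimum-length criterion
        positions = np.linspace(10_000, 100_000, 60).astype(np.int64)
        matrix = make_matrix(np.full((60, 1), HOM_REF), positions=positions)
        assert call_roh_cohort(matrix) == []

    def test_run_under_50_snps_rejected(self):
        # 45 homozygous SNPs spanning 200 kb fail the minimum-SNP criterion
        positions = np.linspace(10_000, 210_000, 45).astype(np.int64)
        matrix = make_matrix(np.full((45, 1), HOM_REF), positions=positions)
        assert call_roh_cohort(matrix) == []

    def test_gap_splitting_breaks_a_run(self):
        positions = np.concatenate(
            [np.arange(1, 101) * 2000, 1_500_000 + np.arange(1, 101) * 2000]
        ).astype(np.int64)
        matrix = make_matrix(np.full((200, 1), HOM_REF), positions=positions)
        segs = call_roh_cohort(matrix)
        assert len(segs) == 2  # 1.3 Mb gap exceeds the 1000-kb default
        merged = call_roh_cohort(matrix, RohParams(max_gap_kb=2000))
        assert len(merged) == 1

    def test_density_criterion_rejects_sparse_run(self):
        # 60 SNPs over 120 kb: 2 kb/SNP fails a 1.5 kb/SNP cap
        matrix = make_matrix(np.full((60, 1), HOM_REF), spacing=2000)
        strict = RohParams(max_density=1.5)
        assert call_roh_cohort(matrix, strict) == []
        literal = RohParams(max_density=1500, density_units="bp_per_snp")
        assert call_roh_cohort(matrix, literal) == []
        loose = RohParams(max_density=2500, density_units="bp_per_snp")
        assert len(call_roh_cohort(matrix, loose)) == 1

    def test_unsorted_positions_hard_error(self):
        with pytest.raises(ValueError, match="increasing"):
            call_roh_individual(
                "1", np.array([10, 5]), np.array([HOM_REF, HOM_REF]), DEFAULT, "s1"
            )

    def test_all_het_cohort_is_empty(self):
        matrix = make_matrix(np.full((300, 4), HET))
        assert call_roh_cohort(matrix) == []

    def test_fully_homozygous_individual_on_dense_chromosome(self):
        codes = np.full((2500, 3), HET, dtype=np.int8)
        codes[:, 1] = HOM_ALT  # second individual homozygous across 5 Mb
        matrix = make_matrix(codes, spacing=2000)
        segs = call_roh_cohort(matrix)
        assert len(segs) == 1 and segs[0].sample == "s2"


class TestScannerProperties:
    def test_monotone_in_min_length_and_min_snp(self):
        rng = np.random.default_rng(21)
        matrix, params = random_scan_instance(rng, 1500)
        n_base = len(call_roh_cohort(matrix, params))
        relaxed = RohParams(
            **{
                **params.__dict__,
                "min_length_kb": params.min_length_kb / 2,
                "min_snp": max(1, params.min_snp // 2),
            }
        )
        assert len(call_roh_cohort(matrix, relaxed)) >= n_base

    def test_hom_to_het_flip_is_local(self):
        """Flipping one call changes hit status only for windows containing it."""
        rng = np.random.default_rng(5)
        codes = rng.choice([0, 2], size=400)
        params = RohParams(window_snp=30)
        from rohscan.detect import _window_hits

        before = _window_hits(codes, params)
        flip = 200
        mutated = codes.copy()
        mutated[flip] = HET
        after = _window_hits(mutated, params)
        changed = np.nonzero(before != after)[0]
        assert all(s <= flip <= s + params.window_snp - 1 for s in changed)

    def test_segments_satisfy_invariants_and_are_disjoint(self):
        rng = np.random.default_rng(8)
        matrix, params = random_scan_instance(rng, 2000)
        segs = call_roh_cohort(matrix, params)
        by_key: dict = {}
        for s in segs:
            assert s.n_snps >= params.min_snp
            assert s.length_kb >= params.min_length_kb
            assert params.density_ok(s.length_bp, s.n_snps)
            by_key.setdefault((s.sample, s.chrom), []).append(s)
        for group in by_key.values():
            for a, b in zip(group, group[1:]):
                assert a.end_bp < b.start_bp  # sorted and disjoint

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n_snps=st.integers(60, 400))
    def test_scanner_equals_oracle_on_random_instances(self, seed, n_snps):
        rng = np.random.default_rng(seed)
        matrix, params = random_scan_instance(rng, n_snps, n_samples=2)
        assert call_roh_cohort(matrix, params) == oracle_call_roh(matrix, params)

    def test_oracle_on_single_window_chromosome(self):
        codes = np.full((50, 1), HOM_REF)
        matrix = make_matrix(codes, spacing=3000)
        params = RohParams(min_length_kb=100)
        assert oracle_call_roh(matrix, params) == call_roh_cohort(matrix, params)
        assert len(oracle_call_roh(matrix, params)) == 1

    def test_oracle_empty_matrix(self):
        matrix = make_matrix(np.zeros((0, 2), dtype=np.int8))
        assert oracle_call_roh(matrix) == []
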