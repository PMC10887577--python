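"""F_ROH arithmetic, Wright path counting vs the tabular kinship oracle,
and the Pearson correlation contract."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from rohscan.detect import RohSegment
from rohscan.genotypes import ChromMap
from rohscan.inbreeding import (
    f_ped_path,
    f_ped_recursive,
    f_roh,
    pearson_correlation,
)
from rohscan.pedigree import Pedigree
from rohscan.sim import simulate_pedigree

FULL_SIB = Pedigree(
    {"S": (None, None), "D": (None, None), "B": ("S", "D"), "C": ("S", "D"), "X": ("B", "C")}
)
HALF_SIB = Pedigree(
    {
        "S": (None, None), "D1": (None, None), "D2": (None, None),
        "B": ("S", "D1"), "C": ("S", "D2"), "X": ("B", "C"),
    }
)


class TestFroh:
    def test_ratio_arithmetic(self):
        cm = ChromMap.from_lengths({"1": 2_500_000_000})
        segs = [RohSegment("s", "1", 1, 25_000_000, 5000)]
        assert f_roh(segs, cm) == pytest.approx(0.01)

    def test_no_segments_is_zero(self, simple_chrom_map):
        assert f_roh([], simple_chrom_map) == 0.0

    def test_whole_genome_segment_is_one(self):
        cm = ChromMap.from_lengths({"1": 5_000_000})
        assert f_roh([RohSegment("s", "1", 1, 5_000_000, 1000)], cm) == 1.0

    def test_additive_over_disjoint_segments_and_order_invariant(self, simple_chrom_map):
        segs = [
            RohSegment("s", "3", 1_000_001, 2_000_000, 300),
            RohSegment("s", "3", 5_000_001, 5_500_000, 200),
            RohSegment("s", "7", 1, 3_000_000, 900),
        ]
        total = sum(f_roh([s], simple_chrom_map) for s in segs)
        assert f_roh(segs, simple_chrom_map) == pytest.approx(total)
        assert f_roh(list(reversed(segs)), simple_chrom_map) == pytest.approx(total)

    def test_non_autosomal_segments_ignored_and_zero_lauto_errors(self):
        cm = ChromMap({"1": 1_000_000, "X": 1_000_000}, {"1"})
        assert f_roh([RohSegment("s", "X", 1, 500_000, 100)], cm) == 0.0
        with pytest.raises(ValueError):
            f_roh([], ChromMap({"X": 1_000_000}, set()))


class TestFpedClosedForms:
    def test_unrelated_parents_give_zero(self):
        ped = Pedigree({"A": (None, None), "B": (None, None), "X": ("A", "B")})
        assert f_ped_path(ped, "X") == 0.0

    def test_full_sib_offspring_quarter(self):
        # two common ancestors, each path pair contributing (1/2)^3
        assert f_ped_path(FULL_SIB, "X") == pytest.approx(0.25)
        assert f_ped_recursive(FULL_SIB, "X") == pytest.approx(0.25)

    def test_half_sib_offspring_eighth(self):
        assert f_ped_path(HALF_SIB, "X") == pytest.approx(0.125)
        assert f_ped_recursive(HALF_SIB, "X") == pytest.approx(0.125)

    def test_founder_is_zero_and_missing_id_errors(self):
        assert f_ped_recursive(FULL_SIB, "S") == 0.0
        assert f_ped_path(FULL_SIB, "S") == 0.0
        with pytest.raises(KeyError):
            f_ped_path(FULL_SIB, "nobody")

    def test_inbred_common_ancestor_raises_contribution(self):
        # X's parents are full sibs whose own parents were full sibs:
        # F(X) = sum over A in {B, C} of (1/2)^1... via parents' kinship
        ped = Pedigree(
            {
                "G1": (None, None), "G2": (None, None),
                "P": ("G1", "G2"), "Q": ("G1", "G2"),
                "B": ("P", "Q"), "C": ("P", "Q"),
                "X": ("B", "C"),
            }
        )
        path = f_ped_path(ped, "X", max_generations=10)
        rec = f_ped_recursive(ped, "X")
        assert path == pytest.approx(rec, abs=1e-12)
        assert path > 0.25  # inbred ancestors inflate F above the full-sib baseline

    def test_founder_f_override(self):
        ped = Pedigree(FULL_SIB.parents.copy(), founder_f={"S": 0.5, "D": 0.5})
        # each common ancestor now contributes (1/2)^3 * 1.5
        assert f_ped_path(ped, "X") == pytest.approx(2 * 0.125 * 1.5)


class TestFpedDualMethod:
    def test_matches_recursive_on_random_pedigrees(self):
        """30 random 5-generation looped pedigrees: |path - tabular| < 1e-12."""
        for seed in range(30):
            loops = [("full_sib", 3), ("half_sib", 4), ("cousin", 5)]
            ped = simulate_pedigree(6, 5, loops[: (seed % 4)], seed=seed)
            depth = ped.max_depth()
            for ind in ped.individuals:
                assert f_ped_path(ped, ind, max_generations=depth + 1) == pytest.approx(
                    f_ped_recursive(ped, ind), abs=1e-12
                )

    def test_truncation_monotone_in_generations(self):
        ped = simulate_pedigree(6, 5, [("full_sib", 3), ("cousin", 5)], seed=99)
        for ind in ped.individuals:
            values = [f_ped_path(ped, ind, g) for g in range(1, 7)]
            assert all(a <= b + 1e-15 for a, b in zip(values, values[1:]))

    def test_truncation_drops_distant_paths(self):
        # grandparental full-sib loop invisible at max_generations=1
        assert f_ped_path(FULL_SIB, "X", max_generations=1) == 0.0
        assert f_ped_path(FULL_SIB, "X", max_generations=2) == pytest.approx(0.25)


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10, dtype=float)
        up = pearson_correlation(x, 2 * x + 1)
        down = pearson_correlation(x, -x)
        assert up.r == pytest.approx(1.0)
        assert down.r == pytest.approx(-1.0)
        assert up.p < 1e-30

    def test_matches_covariance_formula_and_scipy(self):
        rng = np.random.default_rng(31)
        x = rng.normal(size=10)
        y = 0.5 * x + rng.normal(size=10)
        res = pearson_correlation(x, y)
        r_direct = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert res.r == pytest.approx(r_direct, abs=1e-12)
        scipy_res = stats.pearsonr(x, y)
        assert res.r == pytest.approx(scipy_res.statistic, abs=1e-12)
        assert res.p == pytest.approx(scipy_res.pvalue, rel=1e-9)
        assert res.t == pytest.approx(res.r * np.sqrt(8 / (1 - res.r**2)))

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="variance"):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
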