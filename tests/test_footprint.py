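"""Binning, the Cochran-Armitage trend test, genetic-map conversion, and
backcross-number estimation."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from congenicscan import (
    GeneticMap,
    Genotype,
    GenotypeCallSet,
    KoLinkedSet,
    SiteKey,
    TrendTable,
    VariantCall,
    bin_variants,
    build_footprint_interval,
    cochran_armitage,
    estimate_backcross_generations,
    estimate_footprint_interval,
    flag_chromosomes,
)
from conftest import random_callset
from perm_oracle import permutation_T


def _chr1_set(positions, genotype=Genotype.HOM_ALT, label="KO"):
    cs = GenotypeCallSet(label)
    for pos in positions:
        key = SiteKey("chr1", pos, "A", "G")
        cs.add(VariantCall(key, genotype, 50.0, 20, label))
    return cs


class TestBinVariants:
    def test_half_open_bin_convention(self):
        cs = _chr1_set([1, 9_999_999, 10_000_000])
        [b] = bin_variants(cs)
        assert b.counts == [2, 1]  # pos 10,000,000 falls in bin 1

    def test_empty_set(self):
        assert bin_variants(GenotypeCallSet("X")) == []

    def test_bin_size_one_degenerate(self):
        cs = _chr1_set([3, 5])
        [b] = bin_variants(cs, bin_size=1)
        assert sum(b.counts) == 2 and b.counts[3] == 1 and b.counts[5] == 1

    def test_counts_conserved_per_chromosome(self):
        rng = np.random.default_rng(5)
        cs = random_callset(rng, n=100)
        total_variants = len(cs.variant_calls())
        binned = bin_variants(cs)
        assert sum(b.total for b in binned) == total_variants

    def test_hom_ref_and_missing_not_counted(self):
        cs = _chr1_set([10], genotype=Genotype.HOM_REF)
        assert bin_variants(cs) == []


class TestCochranArmitage:
    def test_symmetric_table_has_no_trend(self):
        res = cochran_armitage(TrendTable([5, 5, 5], [5, 5, 5], [0, 1, 2]))
        assert res.z == 0.0 and res.p_value == 1.0 and not res.degenerate

    def test_hand_computed_example(self):
        # T = sum t_i (n1i - c_i R1/N) = 10, Var = 5, z = 10/sqrt(5)
        res = cochran_armitage(TrendTable([0, 5, 10], [10, 5, 0], [0, 1, 2]))
        assert res.z == pytest.approx(10 / math.sqrt(5), abs=1e-12)
        assert res.z == pytest.approx(4.4721, abs=1e-4)

    @pytest.mark.parametrize(
        "ko,wt,chisq,p",
        [
            # frozen from R stats::prop.trend.test (independent implementation)
            ((0, 5, 10), (10, 5, 0), 20.0, 7.744216431e-06),
            ((3, 7, 2, 8), (6, 2, 5, 1), 2.8991874528, 0.08862421593),
            ((12, 0, 3), (5, 9, 9), 7.2907351338, 0.006931110872),
        ],
    )
    def test_matches_independent_reference_values(self, ko, wt, chisq, p):
        res = cochran_armitage(
            TrendTable(np.array(ko, float), np.array(wt, float), np.arange(len(ko), dtype=float))
        )
        assert res.z**2 == pytest.approx(chisq, rel=1e-9)
        assert res.p_value == pytest.approx(p, rel=1e-8)

    @given(
        ko=st.lists(st.integers(0, 20), min_size=2, max_size=5),
        wt=st.lists(st.integers(0, 20), min_size=2, max_size=5),
        a=st.floats(0.1, 50),
        b=st.floats(-100, 100),
    )
    @settings(max_examples=60, derandomize=True)
    def test_affine_invariance_and_row_swap(self, ko, wt, a, b):
        k = min(len(ko), len(wt))
        ko, wt = np.array(ko[:k], float), np.array(wt[:k], float)
        scores = np.arange(k, dtype=float)
        base = cochran_armitage(TrendTable(ko, wt, scores))
        scaled = cochran_armitage(TrendTable(ko, wt, a * scores + b))
        assert scaled.z == pytest.approx(base.z, abs=1e-9)
        swapped = cochran_armitage(TrendTable(wt, ko, scores))
        assert swapped.z == pytest.approx(-base.z, abs=1e-9)
        assert swapped.p_value == pytest.approx(base.p_value, abs=1e-12)

    def test_degenerate_tables_flagged(self):
        assert cochran_armitage(TrendTable([0, 0], [3, 4], [0, 1])).degenerate
        assert cochran_armitage(TrendTable([5, 0], [7, 0], [0, 1])).degenerate

    def test_permutation_moments_match_closed_form(self):
        """The analytic Var(T) is the exact fixed-margin permutation
        variance; check both moments against the oracle's sample."""
        for ko, wt in [((2, 7, 11), (9, 6, 1)), ((5, 5), (1, 9)), ((4, 0, 2, 8), (3, 5, 6, 2))]:
            ko_a, wt_a = np.array(ko, float), np.array(wt, float)
            scores = np.arange(len(ko), dtype=float)
            c = ko_a + wt_a
            r1, r2 = ko_a.sum(), wt_a.sum()
            n = r1 + r2
            tbar = (scores * c).sum() / n
            var_exact = (r1 * r2 / n**2) * ((scores**2 * c).sum() - n * tbar**2)
            # finite-population correction: permutation draws without
            # replacement from N items, variance of a sum of R1 draws
            var_exact *= n / (n - 1)
            _, t_perm = permutation_T(ko_a, wt_a, scores, n_perm=200_000, seed=17)
            assert abs(t_perm.mean()) < 4 * t_perm.std() / math.sqrt(len(t_perm))
            assert t_perm.var() == pytest.approx(var_exact, rel=0.02)


class TestFlagChromosomes:
    def test_identical_counts_nothing_significant(self):
        rng = np.random.default_rng(2)
        cs = random_callset(rng, n=200, chroms=("chr1", "chr2", "chr3"))
        binned = bin_variants(cs)
        results = flag_chromosomes(binned, binned)
        assert results and not any(r.significant for r in results)
        assert all(r.p_value == 1.0 or r.z == pytest.approx(0) for r in results)

    def test_one_sided_chromosome_skipped_with_warning(self, caplog):
        wt = bin_variants(_chr1_set([100], label="WT"))
        ko_set = GenotypeCallSet("KO")
        key = SiteKey("chr2", 100, "A", "G")
        ko_set.add(VariantCall(key, Genotype.HOM_ALT, 50.0, 20, "KO"))
        with caplog.at_level(logging.WARNING):
            results = flag_chromosomes(wt, bin_variants(ko_set))
        assert results == []
        assert any("skipped" in r.message for r in caplog.records)

    def test_bonferroni_reported_alongside_raw(self):
        rng = np.random.default_rng(9)
        wt = bin_variants(random_callset(rng, "WT", n=150, chroms=("chr1", "chr2")))
        ko = bin_variants(random_callset(rng, "KO", n=150, chroms=("chr1", "chr2")))
        for r in flag_chromosomes(wt, ko):
            assert r.p_adjusted >= r.p_value
            assert r.significant == (r.p_value < 0.05)


class TestFootprintInterval:
    def _ko_linked(self, entries):
        cs = KoLinkedSet("KO")
        for pos, geno in entries:
            key = SiteKey("chr14", pos, "A", "G")
            cs.calls[key] = VariantCall(key, geno, 50.0, 20, "KO")
        return cs

    def test_min_max_envelope_of_homozygous(self):
        kol = self._ko_linked(
            [(20_000_000, Genotype.HOM_ALT), (55_000_000, Genotype.HOM_ALT),
             (80_000_000, Genotype.HOM_ALT), (90_000_000, Genotype.HET)]
        )
        assert estimate_footprint_interval(kol, "chr14") == (20_000_000, 80_000_000)
        assert estimate_footprint_interval(kol, "chr14", "all") == (20_000_000, 90_000_000)

    def test_single_variant_zero_width(self):
        kol = self._ko_linked([(5_000_000, Genotype.HOM_ALT)])
        assert estimate_footprint_interval(kol, "chr14") == (5_000_000, 5_000_000)

    def test_het_only_with_hom_filter_errors(self):
        kol = self._ko_linked([(5_000_000, Genotype.HET)])
        with pytest.raises(ValueError, match="chr14"):
            estimate_footprint_interval(kol, "chr14")

    def test_gap_tolerant_trims_isolated_outlier(self):
        core = [(50_000_000 + i * 1_000_000, Genotype.HOM_ALT) for i in range(10)]
        outlier = [(1_000_000, Genotype.HOM_ALT)]  # > 1 empty bin away
        kol = self._ko_linked(core + outlier)
        start, end = estimate_footprint_interval(kol, "chr14", segmentation="gap_tolerant")
        assert start == 50_000_000 and end == 59_000_000

    def test_build_interval_converts_to_cm_and_n(self):
        kol = self._ko_linked(
            [(20_000_000, Genotype.HOM_ALT), (60_000_000, Genotype.HOM_ALT)]
        )
        gmap = GeneticMap(fallback_rate_cm_per_mb=0.5)
        fp = build_footprint_interval(kol, "chr14", gmap)
        assert fp.extent_cM == pytest.approx(20.0)
        assert fp.estimated_N == 10


class TestGeneticMap:
    def test_linear_interpolation_between_anchors(self):
        gm = GeneticMap()
        gm.add_chromosome("chr1", np.array([0.0, 10e6]), np.array([0.0, 5.0]))
        assert gm.interpolate("chr1", 5e6) == pytest.approx(2.5)
        assert gm.interpolate("chr1", 10e6) == pytest.approx(5.0)  # exact anchor

    def test_constant_rate_fallback(self):
        gm = GeneticMap(fallback_rate_cm_per_mb=0.5)
        assert gm.interval_cm("chrX", 0, 20e6) == pytest.approx(10.0)

    def test_missing_chromosome_without_fallback_errors(self):
        with pytest.raises(KeyError):
            GeneticMap().interpolate("chr9", 1000)

    def test_extrapolation_uses_terminal_slope(self):
        gm = GeneticMap()
        gm.add_chromosome("chr1", np.array([10e6, 20e6]), np.array([5.0, 10.0]))
        assert gm.interpolate("chr1", 30e6) == pytest.approx(15.0)
        assert gm.interpolate("chr1", 0.0) == pytest.approx(0.0)

    @given(bps=st.lists(st.integers(0, 200_000_000), min_size=2, max_size=20))
    @settings(max_examples=40, derandomize=True)
    def test_monotone_in_bp(self, bps):
        gm = GeneticMap(fallback_rate_cm_per_mb=0.5)
        gm.add_chromosome(
            "chr1", np.array([0.0, 50e6, 120e6]), np.array([0.0, 20.0, 65.0])
        )
        values = [gm.interpolate("chr1", bp) for bp in sorted(bps)]
        assert all(a <= b + 1e-9 for a, b in zip(values, values[1:]))

    def test_tsv_roundtrip(self, tmp_path):
        gm = GeneticMap.constant_rate({"chr1": 100_000_000}, 0.6)
        path = tmp_path / "map.tsv"
        gm.to_tsv(path)
        back = GeneticMap.from_tsv(path)
        assert back.interpolate("chr1", 50e6) == pytest.approx(gm.interpolate("chr1", 50e6))

    def test_non_monotone_anchors_rejected(self):
        with pytest.raises(ValueError):
            GeneticMap().add_chromosome("chr1", np.array([0.0, 10.0]), np.array([5.0, 5.0]))


class TestBackcrossEstimation:
    @pytest.mark.parametrize("cm,n", [(42.14, 5), (11.94, 17), (200.0, 1), (400.0, 1)])
    def test_generation_number_formula(self, cm, n):
        assert estimate_backcross_generations(cm) == n

    def test_monotone_non_increasing(self):
        grid = np.linspace(0.5, 300, 500)
        values = [estimate_backcross_generations(c) for c in grid]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_non_positive_extent_rejected(self):
        with pytest.raises(ValueError):
            estimate_backcross_generations(0.0)
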