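"""Expression-on-genotype regression screen."""

import math

import numpy as np
import pandas as pd
import pytest

from congenicscan import (
    CountTable,
    default_eqtl_slopes,
    encode_genotypes,
    screen_eqtl,
    select_candidates,
    simulate_count_table,
)
from congenicscan.eqtl import EqtlScreenResult


def _table(values_by_gene, genotypes, conditions=None):
    samples = list(genotypes)
    df = pd.DataFrame.from_dict(values_by_gene, orient="index", columns=samples)
    return CountTable(df, genotypes, conditions or {})


SIX = {"a": "WT", "b": "WT", "c": "HET", "d": "HET", "e": "KO", "f": "KO"}


class TestEncodeGenotypes:
    def test_dosage_codes(self):
        assert encode_genotypes(["WT", "HET", "KO"]) == [1.0, 0.5, 0.0]
        assert encode_genotypes(["KO", "KO"]) == [0.0, 0.0]

    def test_empty_and_unknown_rejected(self):
        with pytest.raises(ValueError):
            encode_genotypes([])
        with pytest.raises(ValueError, match="het"):
            encode_genotypes(["WT", "het"])


class TestScreenEqtl:
    def test_constant_expression_not_selected(self):
        [res] = screen_eqtl(_table({"g": [7.0] * 6}, SIX))
        assert res.slope == 0.0 and not res.selected

    def test_hand_computed_ols_example(self):
        # x=(1,1,.5,.5,0,0), y=(10,9,6,5,2,1): Sxx=1, Sxy=8 -> slope 8;
        # SSE=1.5, s^2=0.375, SE=sqrt(.375)=0.6124, t=13.06, df=4
        [res] = screen_eqtl(_table({"g": [10.0, 9.0, 6.0, 5.0, 2.0, 1.0]}, SIX))
        assert res.slope == pytest.approx(8.0, abs=1e-12)
        assert res.stderr == pytest.approx(math.sqrt(0.375), abs=1e-12)
        t = res.slope / res.stderr
        assert t == pytest.approx(13.0639, abs=1e-4)
        assert res.p_value == pytest.approx(2.0e-4, abs=5e-5)
        assert res.selected

    def test_matches_statsmodels_ols(self):
        """Dual route: our per-gene fit vs an independent OLS implementation."""
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        y = rng.normal(10, 2, size=6)
        [res] = screen_eqtl(_table({"g": y}, SIX))
        x = sm.add_constant(np.array(encode_genotypes(list(SIX.values()))))
        fit = sm.OLS(y, x).fit()
        assert res.slope == pytest.approx(fit.params[1], rel=1e-9)
        assert res.p_value == pytest.approx(fit.pvalues[1], rel=1e-6)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(15)
        y = rng.normal(5, 1, size=6)
        base = screen_eqtl(_table({"g": y}, SIX))[0]
        perm = [5, 0, 3, 1, 4, 2]
        samples = list(SIX)
        shuffled = _table(
            {"g": [y[i] for i in perm]},
            {samples[i]: SIX[samples[i]] for i in perm},
        )
        res = screen_eqtl(shuffled)[0]
        assert res.slope == pytest.approx(base.slope, rel=1e-9)
        assert res.p_value == pytest.approx(base.p_value, rel=1e-9)

    def test_perfect_fit_flagged_with_smallest_p(self):
        y = [11.0, 11.0, 10.5, 10.5, 10.0, 10.0]  # exactly linear in code
        [res] = screen_eqtl(_table({"g": y}, SIX))
        assert res.perfect_fit and res.selected
        assert 0 < res.p_value < 1e-300

    def test_single_genotype_rejected(self):
        with pytest.raises(ValueError):
            screen_eqtl(_table({"g": [1.0, 2.0, 3.0]}, {"a": "KO", "b": "KO", "c": "KO"}))

    def test_two_group_design_allowed(self):
        geno = {"a": "WT", "b": "WT", "c": "KO", "d": "KO"}
        [res] = screen_eqtl(_table({"g": [5.0, 6.0, 1.0, 2.0]}, geno))
        assert res.slope == pytest.approx(4.0)

    def test_fdr_selection_is_more_conservative(self):
        rng = np.random.default_rng(44)
        table, _ = simulate_count_table(
            {f"g{i}": 0.0 for i in range(200)}, ["WT"] * 3 + ["HET"] * 3 + ["KO"] * 3,
            seed=7,
        )
        raw = sum(r.selected for r in screen_eqtl(table))
        adj = sum(r.selected for r in screen_eqtl(table, fdr=True))
        assert adj <= raw


class TestSelectCandidates:
    def _res(self, gene, p, selected):
        return EqtlScreenResult(gene, 1.0, 0.0, p, 0.5, selected)

    def test_requires_both_conditions(self):
        control = [self._res("a", 0.01, True), self._res("b", 0.02, True), self._res("c", 0.5, False)]
        perturbed = [self._res("a", 0.03, True), self._res("b", 0.2, False), self._res("c", 0.01, True)]
        assert select_candidates(control, perturbed) == ["a"]

    def test_ordered_by_control_p(self):
        control = [self._res("a", 0.04, True), self._res("b", 0.001, True)]
        perturbed = [self._res("a", 0.01, True), self._res("b", 0.01, True)]
        assert select_candidates(control, perturbed) == ["b", "a"]

    def test_empty_intersection(self):
        assert select_candidates([self._res("a", 0.01, True)], [self._res("a", 0.5, False)]) == []


class TestSimulateCountTable:
    def test_seed_determinism(self):
        slopes = default_eqtl_slopes(20, seed=3)
        labels = ["WT", "WT", "HET", "HET", "KO", "KO"]
        t1, _ = simulate_count_table(slopes, labels, seed=9)
        t2, _ = simulate_count_table(slopes, labels, seed=9)
        pd.testing.assert_frame_equal(t1.values, t2.values)

    def test_noiseless_limit_recovers_slope(self):
        labels = ["WT"] * 3 + ["HET"] * 3 + ["KO"] * 3
        table, _ = simulate_count_table({"g": 10.0}, labels, seed=1, noise_sigma=1e-9)
        [res] = screen_eqtl(table)
        assert res.slope == pytest.approx(10.0, abs=1e-6)

    def test_tsv_roundtrip(self, tmp_path):
        slopes = default_eqtl_slopes(5, seed=2)
        table, _ = simulate_count_table(slopes, ["WT", "HET", "KO"] * 2, seed=4)
        table.to_tsv(tmp_path / "counts.tsv", tmp_path / "samples.tsv")
        back = CountTable.from_tsv(tmp_path / "counts.tsv", tmp_path / "samples.tsv")
        assert back.genes == table.genes
        assert back.genotypes == table.genotypes
        np.testing.assert_allclose(back.values.to_numpy(), table.values.to_numpy(), rtol=1e-12)
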