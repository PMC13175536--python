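import numpy as np
import pytest

from clonekit.core import MISSING
from clonekit.popgen import (
    exclusion_probability,
    expected_genotype_null,
    gst_double_prime,
    imputed_copy,
    mll_representatives,
    nei_gis,
    plain_freqs,
    psex_F,
    round_robin_freqs,
    rst,
    AlleleFreqs,
)

from conftest import make_table


class TestRoundRobin:
    def test_all_identical_stems_single_lineage(self):
        t = make_table([[(10, 12), (20, 20)]] * 5)
        f = round_robin_freqs(t)
        assert f.freqs["L1"] == {10: 0.5, 12: 0.5}
        assert f.freqs["L2"] == {20: 1.0}

    def test_all_unique_equals_plain(self):
        rng = np.random.default_rng(2)
        alleles = np.stack(
            [rng.permutation(np.arange(10, 50))[:20].reshape(10, 2) for _ in range(3)],
            axis=1,
        )
        t = make_table(alleles.tolist())
        rr = round_robin_freqs(t)
        pl = plain_freqs(t)
        for locus in t.locus_names:
            assert rr.freqs[locus] == pytest.approx(pl.freqs[locus])

    def test_clone_pooled_by_hand(self):
        # 3-ramet clone + 2 singletons, 2 loci; lineages collapse the clone,
        # pooled alleles give 0.5/0.5 at both loci (plain would give 0.7/0.3)
        rows = [[(10, 10), (20, 22)]] * 3 + [
            [(10, 12), (20, 20)],
            [(12, 12), (22, 22)],
        ]
        t = make_table(rows)
        rr = round_robin_freqs(t)
        assert rr.freqs["L1"] == pytest.approx({10: 0.5, 12: 0.5})
        assert rr.freqs["L2"] == pytest.approx({20: 0.5, 22: 0.5})
        pl = plain_freqs(t)
        assert pl.freqs["L1"] == pytest.approx({10: 0.7, 12: 0.3})

    def test_single_locus_rejected(self):
        with pytest.raises(ValueError):
            round_robin_freqs(make_table([[(10, 10)]] * 3))


class TestImputation:
    def test_no_missing_identity(self):
        t = make_table([[(10, 12)], [(10, 10)]])
        out = imputed_copy(t, plain_freqs(t), seed=0)
        assert out.equals(t)

    def test_monomorphic_locus_imputes_homozygote(self):
        t = make_table([[(10, 10)], [(-1, -1)]])
        out = imputed_copy(t, plain_freqs(t), seed=3)
        assert out.alleles[1, 0].tolist() == [10, 10]

    def test_imputation_frequencies_converge(self):
        t = make_table([[(10, 12)]] * 5 + [[(-1, -1)]])
        freqs = plain_freqs(t)
        rng = np.random.default_rng(0)
        draws = []
        for _ in range(3000):
            out = imputed_copy(t, freqs, seed=rng)
            draws.extend(out.alleles[5, 0].tolist())
        frac10 = np.mean(np.array(draws) == 10)
        assert frac10 == pytest.approx(0.5, abs=0.02)


class TestPsexExclusion:
    def test_hwe_heterozygote(self):
        f = AlleleFreqs(freqs={"L1": {10: 0.5, 12: 0.5}})
        assert psex_F(np.array([(10, 12)]), f, F=0.0, locus_names=["L1"]) == pytest.approx(0.5)

    def test_full_inbreeding_kills_heterozygotes(self):
        f = AlleleFreqs(freqs={"L1": {10: 0.5, 12: 0.5}})
        assert psex_F(np.array([(10, 12)]), f, F=1.0, locus_names=["L1"]) == 0.0

    def test_two_locus_hand_product(self):
        # het 2*0.7*0.3*(1-0.2) = 0.336; hom 0.55^2 + 0.2*0.55*0.45 = 0.352
        f = AlleleFreqs(freqs={"L1": {10: 0.7, 12: 0.3}, "L2": {20: 0.55, 22: 0.45}})
        p = psex_F(np.array([(10, 12), (20, 20)]), f, F=0.2, locus_names=["L1", "L2"])
        assert p == pytest.approx(0.336 * 0.352)

    def test_unknown_allele_rejected(self):
        f = AlleleFreqs(freqs={"L1": {10: 1.0}})
        with pytest.raises(KeyError):
            psex_F(np.array([(10, 99)]), f, F=0.0, locus_names=["L1"])

    def test_exclusion_limits(self):
        assert exclusion_probability(0.0, 935).p_any_identity == 0.0
        r = exclusion_probability(1.0, 1)
        assert r.p_any_identity == 1.0 and r.p_no_identity == 0.0

    def test_complement_consistency(self):
        r = exclusion_probability(2e-9, 935)
        assert r.p_no_identity + r.p_any_identity == pytest.approx(1.0)


class TestNeiGis:
    def test_heterozygote_excess_gives_negative_gis(self):
        # an all-heterozygote sample at a 2-allele locus has H_O = 1 > H_S
        t = make_table([[(10, 12)]] * 10)
        g = nei_gis(t)
        assert g.g_is < 0

    def test_all_homozygotes_polymorphic_locus_is_one(self):
        t = make_table([[(10, 10)]] * 5 + [[(12, 12)]] * 5)
        g = nei_gis(t)
        assert g.per_locus_gis["L1"] == pytest.approx(1.0)
        assert g.g_is == pytest.approx(1.0)

    def test_ten_individual_worked_toy(self):
        # locus A: (10,10) x3, (10,12) x4, (12,12) x3 -> H_O 0.4, p 0.5/0.5
        # locus B: (20,22) x5, (20,20) x3, (22,22) x2 -> H_O 0.5, p 0.55/0.45
        # unbiased H_S per the (n/(n-1))(1 - sum p^2 - H_O/2n) formula;
        # G_IS = 1 - (0.4 + 0.5) / (H_S_A + H_S_B) = 14/95 (independent arithmetic)
        rows = (
            [[(10, 10), (20, 22)]] * 3
            + [[(10, 12), (20, 22)]] * 2
            + [[(10, 12), (20, 20)]] * 2
            + [[(12, 12), (20, 20)]]
            + [[(12, 12), (22, 22)]] * 2
        )
        t = make_table(rows)
        g = nei_gis(t)
        assert g.h_o["L1"] == pytest.approx(0.4)
        assert g.h_o["L2"] == pytest.approx(0.5)
        assert g.g_is == pytest.approx(14 / 95)

    def test_monomorphic_everywhere_is_nan_with_warning(self):
        t = make_table([[(10, 10)]] * 4)
        with pytest.warns(UserWarning):
            g = nei_gis(t)
        assert np.isnan(g.g_is)

    def test_jackknife_brackets_estimate(self):
        rng = np.random.default_rng(1)
        t = make_table(rng.integers(8, 16, size=(40, 5, 2)).tolist())
        g = nei_gis(t)
        assert g.jackknife_lo <= g.jackknife_hi


def _two_patches(rows_a, rows_b):
    return {
        "A": make_table(rows_a),
        "B": make_table(rows_b),
    }


class TestGstDoublePrime:
    def test_identical_patches_exactly_zero(self):
        rows = [[(10, 12)], [(10, 10)], [(12, 12)]]
        d = gst_double_prime(_two_patches(rows, rows), n_boot=10, seed=0)
        assert d.value == pytest.approx(0.0, abs=1e-12)

    def test_fixed_alternative_alleles_exactly_one(self):
        d = gst_double_prime(
            _two_patches([[(10, 10)]] * 4, [[(12, 12)]] * 4), n_boot=10, seed=0
        )
        assert d.value == pytest.approx(1.0, abs=1e-12)

    def test_three_patch_worked_toy(self):
        # one locus; patch allele-10 freqs 1/2, 5/6, 1/6 ->
        # H_S = 38/108, H_T = 1/2, k = 3 -> G'' = 648/1085 (indep. arithmetic)
        tables = {
            "P1": make_table([[(10, 10)], [(10, 12)], [(12, 12)]]),
            "P2": make_table([[(10, 10)], [(10, 10)], [(10, 12)]]),
            "P3": make_table([[(12, 12)], [(12, 12)], [(10, 12)]]),
        }
        d = gst_double_prime(tables, n_boot=10, seed=0)
        assert d.value == pytest.approx(648 / 1085)

    def test_pairwise_matrix_shape_and_symmetry(self):
        tables = {
            "P1": make_table([[(10, 10)], [(10, 12)]]),
            "P2": make_table([[(12, 12)], [(10, 12)]]),
            "P3": make_table([[(14, 14)], [(10, 14)]]),
        }
        d = gst_double_prime(tables, n_boot=20, seed=0)
        assert d.pairwise.shape == (3, 3)
        assert np.allclose(d.pairwise, d.pairwise.T, equal_nan=True)

    def test_bootstrap_deterministic_under_seed(self):
        tables = {
            "P1": make_table([[(10, 10)], [(10, 12)]]),
            "P2": make_table([[(12, 12)], [(10, 12)]]),
        }
        a = gst_double_prime(tables, n_boot=100, seed=9)
        b = gst_double_prime(tables, n_boot=100, seed=9)
        assert (a.ci_lo, a.ci_hi) == (b.ci_lo, b.ci_hi)


class TestRst:
    def test_identical_patches_exactly_zero(self):
        rows = [[(10, 14)], [(10, 10)], [(14, 14)]]
        d = rst(_two_patches(rows, rows), n_boot=10, seed=0)
        assert d.value == pytest.approx(0.0, abs=1e-12)

    def test_fixed_alternative_sizes_exactly_one(self):
        d = rst(_two_patches([[(10, 10)]] * 3, [[(20, 20)]] * 3), n_boot=10, seed=0)
        assert d.value == pytest.approx(1.0, abs=1e-12)

    def test_two_patch_variance_component_oracle(self):
        # patch A copies {10,10,11,12}, patch B {14,14,15,13}:
        # pooled var 3.234375, weighted within var 0.59375 -> R_ST 0.8164251...
        d = rst(
            _two_patches([[(10, 10)], [(11, 12)]], [[(14, 14)], [(15, 13)]]),
            n_boot=10,
            seed=0,
        )
        assert d.value == pytest.approx(0.8164251207729468)

    def test_monomorphic_everywhere_nan_with_warning(self):
        with pytest.warns(UserWarning):
            d = rst(_two_patches([[(10, 10)]] * 2, [[(10, 10)]] * 2), n_boot=5, seed=0)
        assert np.isnan(d.value)

    def test_pairwise_jackknife_spread_present(self):
        rng = np.random.default_rng(4)
        tables = {
            p: make_table(rng.integers(8, 20, size=(6, 4, 2)).tolist())
            for p in ("P1", "P2", "P3")
        }
        d = rst(tables, n_boot=20, seed=1)
        assert d.pairwise_spread is not None
        assert np.isfinite(d.pairwise_spread[0, 1])


class TestRepresentatives:
    def test_fewest_missing_then_lowest_id(self):
        from clonekit.distances import pairwise_matrix
        from clonekit.mll import assign_mlls_table

        rows = [
            [(10, 10), (-1, -1)],  # s1: 1 missing
            [(10, 10), (20, 20)],  # s2: complete -> representative
            [(10, 10), (20, 20)],  # s3: complete but higher id
        ]
        t = make_table(rows)
        part = assign_mlls_table(t, pairwise_matrix(t, "stepwise"), 0)
        # s2, s3 identical; s1 joins them at threshold 0 (missing locus skipped)
        reps = mll_representatives(t, part)
        assert "s2" in list(reps.sample_id)


class TestGenotypeNull:
    def test_single_allele_always_one_genotype(self):
        f = AlleleFreqs(freqs={"L1": {10: 1.0}})
        r = expected_genotype_null(f, N=5, n_iter=50, seed=0)
        assert r.expected_distinct == 1.0

    def test_two_equifrequent_alleles_closed_form(self):
        # genotype probs {1/4, 1/2, 1/4}; E[distinct | N=2] =
        # sum_g (1 - (1-p_g)^2) = 7/16 + 3/4 + 7/16 = 1.625
        f = AlleleFreqs(freqs={"L1": {10: 0.5, 12: 0.5}})
        r = expected_genotype_null(f, N=2, n_iter=5000, seed=1)
        se = r.sd_distinct / np.sqrt(r.n_iter)
        assert abs(r.expected_distinct - 1.625) < 3 * se

    def test_high_diversity_no_collisions(self):
        rng = np.random.default_rng(0)
        freqs = {
            f"L{j}": {int(a): 1 / 20 for a in range(10 + 20 * j, 30 + 20 * j)}
            for j in range(10)
        }
        f = AlleleFreqs(freqs=freqs)
        r = expected_genotype_null(f, N=100, n_iter=50, seed=2)
        assert r.expected_distinct == pytest.approx(100.0, abs=0.5)

    def test_p_value_detects_clonal_deficit(self):
        f = AlleleFreqs(freqs={"L1": {10: 0.5, 12: 0.5}, "L2": {20: 0.5, 22: 0.5}})
        r = expected_genotype_null(f, N=40, n_iter=500, seed=3, observed=2)
        assert r.p_value <= 1 / 500

    def test_deterministic_under_seed(self):
        f = AlleleFreqs(freqs={"L1": {10: 0.6, 12: 0.4}})
        a = expected_genotype_null(f, N=10, n_iter=200, seed=5)
        b = expected_genotype_null(f, N=10, n_iter=200, seed=5)
        assert a.expected_distinct == b.expected_distinct
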