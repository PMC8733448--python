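"""Estimator formulas, variant reductions, ratio statistics, jackknife."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fstatkin as fk
from fstatkin import estimators as est


def ctx(pop, phat, phi2=None, sum_m=None):
    return est.LocusContext(pop, np.atleast_1d(np.asarray(phat, float)), phi2, sum_m)


def random_contexts(seed, n_pops=2, j=30, n_ind=8):
    """Unrelated noninbred diploid contexts where Phi2 = 1/sum_m exactly."""
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_pops):
        phat = rng.integers(0, 2 * n_ind + 1, size=j) / (2 * n_ind)
        out.append(ctx("ABCD"[k], phat, phi2=1.0 / (2 * n_ind), sum_m=2.0 * n_ind))
    return out


class TestEstimateFrequency:
    def test_sample_proportion(self):
        gm = fk.GenotypeMatrix("P", np.array([[2, 1, 1]]), np.full((1, 3), 2),
                               np.zeros((1, 3), bool), None, ["a", "b", "c"])
        assert np.isclose(fk.estimate_frequency(gm)[0], 4 / 6)

    def test_single_haploid(self):
        gm = fk.GenotypeMatrix("P", np.array([[1]]), np.array([[1]]),
                               np.zeros((1, 1), bool), None, ["a"])
        assert fk.estimate_frequency(gm)[0] == 1.0

    def test_explicit_weights(self):
        gm = fk.GenotypeMatrix("P", np.array([[2, 0]]), np.full((1, 2), 2),
                               np.zeros((1, 2), bool), None, ["a", "b"])
        w = fk.WeightVector(np.array([0.25, 0.75]), "custom")
        assert np.isclose(fk.estimate_frequency(gm, w)[0], 0.25)

    def test_all_missing_locus_errors(self):
        gm = fk.GenotypeMatrix("P", np.array([[0]]), np.array([[2]]),
                               np.ones((1, 1), bool), None, ["a"])
        with pytest.raises(ValueError, match="missing"):
            fk.estimate_frequency(gm)

    def test_missing_individual_dropped_per_locus(self):
        dos = np.array([[2, 2], [2, 0]])
        miss = np.array([[False, True], [False, False]])
        gm = fk.GenotypeMatrix("P", dos, np.full((2, 2), 2), miss, None, ["a", "b"])
        lc = est.locus_context(gm)
        np.testing.assert_allclose(lc.phat, [1.0, 0.5])
        np.testing.assert_allclose(lc.sum_m, [2.0, 4.0])
        np.testing.assert_allclose(lc.phi2, [0.5, 0.25])


class TestGStat:
    def test_tilde_divides_by_one_minus_phi2(self):
        r = fk.g_stat(ctx("A", 0.5, phi2=0.5), "tilde")
        assert np.isclose(r.estimate, 0.5)

    def test_breve_scales_by_allele_count(self):
        r = fk.g_stat(ctx("A", 0.5, sum_m=4.0), "breve")
        assert np.isclose(r.estimate, 1 / 3)

    def test_tilde_with_phi2_one_errors(self):
        with pytest.raises(ValueError, match="haploid"):
            fk.g_stat(ctx("A", 0.5, phi2=1.0), "tilde")


class TestHStat:
    def test_symmetric_half_frequencies(self):
        cs = [ctx(p, 0.5) for p in "ABCD"]
        assert np.isclose(fk.h_stat(*cs).estimate, 0.25)

    def test_fixed_sister_pair_zero(self):
        cs = [ctx("A", 0.0), ctx("B", 0.0), ctx("C", 0.5), ctx("D", 0.5)]
        assert fk.h_stat(*cs).estimate == 0.0

    def test_matches_direct_formula(self, rng):
        p = {k: rng.uniform(0, 1, 25) for k in "ABCD"}
        r = fk.h_stat(*[ctx(k, p[k]) for k in "ABCD"])
        direct = np.mean((p["A"] + p["B"] - 2 * p["A"] * p["B"])
                         * (p["C"] + p["D"] - 2 * p["C"] * p["D"]))
        assert np.isclose(r.estimate, direct, atol=1e-15)


class TestF2F3:
    def test_f2_tilde_fixed_frequencies_keeps_squared_difference(self):
        r = fk.f2(ctx("A", 1.0, phi2=0.4, sum_m=4.0),
                  ctx("B", 0.0, phi2=0.4, sum_m=4.0), "tilde")
        assert np.isclose(r.estimate, 1.0)

    def test_f2_tilde_can_be_negative_at_equal_frequencies(self):
        r = fk.f2(ctx("A", 0.5, phi2=0.375, sum_m=4.0),
                  ctx("B", 0.5, phi2=0.375, sum_m=4.0), "tilde")
        assert r.estimate < 0

    def test_f3_only_target_corrected(self):
        a = ctx("A", 0.5, phi2=0.375, sum_m=4.0)
        b = ctx("B", 0.5)  # no kinship info needed for reference pops
        c = ctx("C", 0.5)
        r = fk.f3(a, b, c, "tilde")
        expected = -0.375 * 0.25 / (1 - 0.375)
        assert np.isclose(r.estimate, expected)

    def test_f3_fixed_target_correction_vanishes(self):
        a = ctx("A", 1.0, phi2=0.375, sum_m=4.0)
        b, c = ctx("B", 0.3), ctx("C", 0.6)
        assert np.isclose(fk.f3(a, b, c, "tilde").estimate,
                          fk.f3(a, b, c, "hat").estimate)


class TestReductionIdentity:
    """With unrelated noninbred samples and sample-proportion weights the
    tilde and breve corrections coincide exactly (Phi2 = 1/sum_m)."""

    @given(st.integers(0, 100))
    def test_tilde_equals_breve_everywhere(self, seed):
        a, b, c, d = random_contexts(seed, n_pops=4)
        for fn, args in [
            (fk.g_stat, (a,)),
            (fk.f2, (a, b)),
            (fk.f3, (a, b, c)),
        ]:
            rt = fn(*args, "tilde")
            rb = fn(*args, "breve")
            np.testing.assert_allclose(rt.per_locus, rb.per_locus, atol=1e-14)
        if fk.g_stat(a, "hat").estimate > 0:
            assert np.isclose(fk.f3_normalized(a, b, c, "tilde").estimate,
                              fk.f3_normalized(a, b, c, "breve").estimate, atol=1e-12)
            assert np.isclose(
                fk.f4_normalized(a, b, c, d, normalizing="A", variant="tilde").estimate,
                fk.f4_normalized(a, b, c, d, normalizing="A", variant="breve").estimate,
                atol=1e-12)


class TestF4AndD:
    def test_f4_zero_when_sisters_equal(self, rng):
        p = rng.uniform(0, 1, 10)
        cs = [ctx("A", p), ctx("B", p), ctx("C", rng.uniform(0, 1, 10)),
              ctx("D", rng.uniform(0, 1, 10))]
        assert np.isclose(fk.f4(*cs).estimate, 0.0, atol=1e-15)

    def test_f4_antisymmetry(self, rng):
        p = {k: rng.uniform(0, 1, 15) for k in "ABCD"}
        cs = {k: ctx(k, p[k]) for k in "ABCD"}
        fwd = fk.f4(cs["A"], cs["B"], cs["C"], cs["D"]).estimate
        swapped = fk.f4(cs["B"], cs["A"], cs["C"], cs["D"]).estimate
        both = fk.f4(cs["B"], cs["A"], cs["D"], cs["C"]).estimate
        assert np.isclose(fwd, -swapped, atol=1e-15)
        assert np.isclose(fwd, both, atol=1e-15)

    def test_f4_norm_no_factor_two(self):
        cs = [ctx(k, v) for k, v in zip("ABCD", (0.8, 0.2, 0.7, 0.1))]
        r = fk.f4_normalized(*cs, normalizing="A", variant="hat")
        f4_val = (0.8 - 0.2) * (0.7 - 0.1)
        assert np.isclose(r.estimate, f4_val / (0.8 * 0.2))

    def test_f4_norm_tilde_shrinks_magnitude(self):
        cs = [ctx(k, v, phi2=0.3, sum_m=10.0)
              for k, v in zip("ABCD", (0.8, 0.2, 0.7, 0.1))]
        hat = fk.f4_normalized(*cs, normalizing="A", variant="hat").estimate
        tilde = fk.f4_normalized(*cs, normalizing="A", variant="tilde").estimate
        assert abs(tilde) <= abs(hat)

    @given(st.integers(0, 200))
    def test_d_bounded(self, seed):
        rng = np.random.default_rng(seed)
        cs = [ctx(k, rng.uniform(0.05, 0.95, 12)) for k in "ABCD"]
        d = fk.d_stat(*cs).estimate
        assert -1.0 <= d <= 1.0

    def test_d_zero_when_sisters_equal(self, rng):
        p = rng.uniform(0.1, 0.9, 10)
        cs = [ctx("A", p), ctx("B", p), ctx("C", rng.uniform(0.1, 0.9, 10)),
              ctx("D", rng.uniform(0.1, 0.9, 10))]
        assert fk.d_stat(*cs).estimate == 0.0

    def test_d_attains_bound(self):
        # (a-b)(c-d) = -H per locus: a=1,b=0,c=0,d=1 gives F4=-1, H=1
        cs = [ctx("A", 1.0), ctx("B", 0.0), ctx("C", 0.0), ctx("D", 1.0)]
        assert np.isclose(fk.d_stat(*cs).estimate, 1.0)


class TestDfoil:
    def test_zero_numerators_cd_equal(self, rng):
        p = rng.uniform(0.1, 0.9, 10)
        cs = [ctx("A", rng.uniform(0.1, 0.9, 10)), ctx("B", rng.uniform(0.1, 0.9, 10)),
              ctx("C", p), ctx("D", p)]
        r = fk.dfoil(*cs)
        assert r["DFO"].estimate == 0.0 and r["DIL"].estimate == 0.0

    def test_zero_numerators_ab_equal(self, rng):
        p = rng.uniform(0.1, 0.9, 10)
        cs = [ctx("A", p), ctx("B", p), ctx("C", rng.uniform(0.1, 0.9, 10)),
              ctx("D", rng.uniform(0.1, 0.9, 10))]
        r = fk.dfoil(*cs)
        assert r["DFI"].estimate == 0.0 and r["DOL"].estimate == 0.0

    def test_half_frequency_in_a_kills_dfo(self, rng):
        cs = [ctx("A", np.full(10, 0.5)), ctx("B", rng.uniform(0.1, 0.9, 10)),
              ctx("C", rng.uniform(0.1, 0.9, 10)), ctx("D", rng.uniform(0.1, 0.9, 10))]
        assert fk.dfoil(*cs)["DFO"].estimate == 0.0


class TestJackknife:
    def test_identical_values_zero_se(self):
        assert fk.jackknife_se(np.full(10, 0.3)) == pytest.approx(0.0, abs=1e-12)

    def test_two_block_closed_form(self):
        vals = np.array([1.0, 1.0, 3.0, 3.0])
        # deleting each 2-locus block leaves means 3 and 1
        assert np.isclose(fk.jackknife_se(vals, block_size=2), abs(3.0 - 1.0) / 2)

    def test_delete_one_equals_classic_formula(self, rng):
        vals = rng.normal(size=50)
        se = fk.jackknife_se(vals)
        assert np.isclose(se, vals.std(ddof=1) / np.sqrt(len(vals)), rtol=1e-10)

    def test_se_scales_with_block_count(self, rng):
        vals = rng.normal(size=4000)
        se_few = fk.jackknife_se(vals[:1000])
        se_many = fk.jackknife_se(vals)
        assert np.isclose(se_many / se_few, 0.5, atol=0.15)

    def test_ratio_recomputed_per_block(self, rng):
        num = rng.normal(1.0, 0.1, 40)
        den = rng.normal(2.0, 0.1, 40)
        se = fk.jackknife_se(num, den, block_size=4)
        assert se > 0

    def test_too_few_blocks(self):
        with pytest.raises(ValueError, match="2 blocks"):
            fk.jackknife_se(np.array([1.0, 2.0]), block_size=2)
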