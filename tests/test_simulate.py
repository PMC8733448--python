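"""Generators: IBD-copy pairs, exact enumeration, Wright-Fisher admixture."""

import numpy as np
import pytest

import fstatkin as fk
from fstatkin import simulate as sim


class TestRelativePairCatalog:
    @pytest.mark.parametrize("label", sorted(fk.RELATIVE_PAIRS))
    def test_delta_consistency(self, label):
        """The kinship implied by the Delta-copy process equals the
        cataloged value for every relative type that has a Delta form."""
        spec = fk.RELATIVE_PAIRS[label]
        implied = spec.delta_implied_phi()
        if implied is not None:
            assert np.isclose(implied, spec.implied_phi)

    def test_diploid_noninbred_identity(self):
        """Phi = Delta2/2 + Delta1/4 for diploid noninbred pairs."""
        for label in ("parent_offspring", "full_sibling", "avuncular", "ff_sibling_x"):
            spec = fk.RELATIVE_PAIRS[label]
            d0, d1, d2 = spec.delta
            assert np.isclose(spec.implied_phi, d2 / 2 + d1 / 4)

    def test_inbred_siblings_match_pedigree(self):
        spec = fk.RELATIVE_PAIRS["inbred_full_sibling"]
        assert spec.implied_phi == 0.375 and spec.inbreeding == (0.25, 0.25)


class TestDrawUnrelatedSample:
    def test_fixed_frequency_gives_full_dosage(self, rng):
        gm = sim.draw_unrelated_sample(np.ones(5), 4, rng=rng)
        assert (gm.dosages == 2).all()

    def test_mean_dosage_near_expectation(self):
        gm = sim.draw_unrelated_sample(np.full(2000, 0.5), 10, rng=3)
        se = np.sqrt(0.5 * 0.5 * 2 / (2000 * 10))
        assert abs(gm.dosages.mean() - 1.0) < 3 * 2 * se

    def test_seed_determinism(self):
        g1 = sim.draw_unrelated_sample(np.full(50, 0.3), 6, rng=11)
        g2 = sim.draw_unrelated_sample(np.full(50, 0.3), 6, rng=11)
        assert (g1.dosages == g2.dosages).all()


class TestImposeRelativePair:
    def test_full_copy_spec_duplicates_genotype(self, rng):
        gm = sim.draw_unrelated_sample(rng.uniform(0.2, 0.8, 100), 4, rng=rng)
        twin = fk.RelativePairSpec("twin", (0.0, 0.0, 1.0), 0.5)
        out = sim.impose_relative_pair(gm, 0, 1, twin, rng=rng)
        assert (out.dosages[:, 0] == out.dosages[:, 1]).all()

    def test_parent_offspring_realized_kinship(self):
        """Across many loci the realized correlation of the Delta-copy pair
        matches Phi = 1/4: Cov(X_x, X_y) = 2 Phi p(1-p) for individual
        frequencies of a diploid pair."""
        p = 0.4
        nloci = 200_000
        gm = sim.draw_unrelated_sample(np.full(nloci, p), 2, rng=5)
        out = sim.impose_relative_pair(gm, 0, 1, fk.RELATIVE_PAIRS["parent_offspring"],
                                       rng=6)
        x = out.dosages[:, 0] / 2.0
        y = out.dosages[:, 1] / 2.0
        cov = np.cov(x, y)[0, 1]
        expected = 2 * 0.25 * p * (1 - p) / 2.0  # Phi * p(1-p) per pair of alleles
        se = 3 * p * (1 - p) / np.sqrt(nloci)
        assert abs(cov - expected) < se

    def test_ploidy_mismatch_rejected(self, rng):
        gm = sim.draw_unrelated_sample(np.full(10, 0.5), 3, ploidy=1, rng=rng)
        with pytest.raises(ValueError, match="ploidy"):
            sim.impose_relative_pair(gm, 0, 1, fk.RELATIVE_PAIRS["full_sibling"], rng=rng)

    def test_same_individual_rejected(self, rng):
        gm = sim.draw_unrelated_sample(np.full(10, 0.5), 3, rng=rng)
        with pytest.raises(ValueError):
            sim.impose_relative_pair(gm, 1, 1, fk.RELATIVE_PAIRS["full_sibling"], rng=rng)


class TestEnumerationOracle:
    @pytest.mark.parametrize("label", ["parent_offspring", "full_sibling",
                                       "avuncular", "inbred_full_sibling"])
    def test_mean_is_true_frequency(self, label):
        des = fk.SampleDesign(n_unrelated=1, pairs=[fk.RELATIVE_PAIRS[label]])
        e = sim.enumeration_oracle({"P": 0.37}, {"P": des}, lambda ph: ph["P"])
        assert abs(e - 0.37) < 1e-13

    @pytest.mark.parametrize("label", ["parent_offspring", "full_sibling",
                                       "avuncular", "inbred_full_sibling"])
    def test_variance_matches_phi2(self, label):
        """Var(p-hat) = Phi2 p(1-p) exactly, for every pair construction."""
        des = fk.SampleDesign(n_unrelated=2, pairs=[fk.RELATIVE_PAIRS[label]])
        p = 0.61
        e2 = sim.enumeration_oracle({"P": p}, {"P": des}, lambda ph: ph["P"] ** 2)
        assert abs(e2 - p ** 2 - des.phi2() * p * (1 - p)) < 1e-13

    def test_f4_unbiased_with_relatives_everywhere(self):
        des = fk.SampleDesign(pairs=[fk.RELATIVE_PAIRS["full_sibling"]])
        freqs = {"A": 0.7, "B": 0.3, "C": 0.55, "D": 0.2}
        e = sim.enumeration_oracle(freqs, {k: des for k in freqs},
                                   lambda ph: (ph["A"] - ph["B"]) * (ph["C"] - ph["D"]))
        true = (0.7 - 0.3) * (0.55 - 0.2)
        assert abs(e - true) < 1e-13

    def test_outcome_space_guard(self):
        des = fk.SampleDesign(n_unrelated=40)
        with pytest.raises(ValueError, match="Monte Carlo"):
            sim.enumeration_oracle({k: 0.5 for k in "ABCD"}, {k: des for k in "ABCD"},
                                   lambda ph: ph["A"], max_outcomes=1000)

    def test_monte_carlo_agrees_with_enumeration(self):
        """simulate_phat and the exact distribution describe the same model."""
        des = fk.SampleDesign(n_unrelated=1, pairs=[fk.RELATIVE_PAIRS["full_sibling"]])
        p = 0.45
        values, pmf = sim.population_phat_distribution(p, des)
        mean_exact = (values * pmf).sum()
        draws = sim.simulate_phat(np.array([p]), des, 200_000, rng=9)[:, 0]
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - mean_exact) < 3 * se


class TestWrightFisher:
    def test_no_time_no_drift(self):
        model = fk.DemographicModel(ne=1000, t_split=0, t_admix=0, n_loci=200,
                                    init_law="uniform")
        res = sim.wf_simulate(model, rng=2)
        np.testing.assert_allclose(res.panel.freq["A"], res.panel.freq["B"])
        np.testing.assert_allclose(res.panel.freq["B"], res.panel.freq["C"])

    def test_pure_drift_divergence_matches_closed_form(self):
        """E[(b-c)^2] = 2 E[p0(1-p0)] (1 - (1-1/(2Ne))^t) for independent
        lineages drifting t generations from a shared start."""
        ne, t = 500, 100
        model = fk.DemographicModel(ne=ne, t_split=t, t_admix=0, n_loci=20_000,
                                    init_law="uniform")
        res = sim.wf_simulate(model, rng=8)
        b, c = res.panel.freq["B"], res.panel.freq["C"]
        d2 = (b - c) ** 2
        h0 = np.mean([p * (1 - p) for p in np.linspace(0.05, 0.95, 10001)])
        expected = 2 * h0 * (1 - (1 - 1 / (2 * ne)) ** t)
        se = d2.std(ddof=1) / np.sqrt(len(d2))
        assert abs(d2.mean() - expected) < 3 * se

    def test_admixture_model_parametric_f3_negative(self):
        model = fk.DemographicModel(ne=10_000, t_split=2000, t_admix=400,
                                    alpha=0.4, n_loci=15_000)
        res = sim.wf_simulate(model, rng=3)
        poly = res.polymorphic
        panel = fk.FrequencyPanel(freq={k: res.panel.freq[k][poly] for k in "ABC"})
        assert sim.true_fstat(panel, "f3", ["A", "B", "C"]) < 0

    def test_seed_determinism(self):
        model = fk.DemographicModel(ne=200, t_split=50, t_admix=10, n_loci=100,
                                    init_law="uniform")
        r1 = sim.wf_simulate(model, rng=4)
        r2 = sim.wf_simulate(model, rng=4)
        np.testing.assert_array_equal(r1.panel.freq["A"], r2.panel.freq["A"])


class TestTrueFstat:
    def test_fixed_difference_f2_is_one(self):
        panel = fk.FrequencyPanel(freq={"A": np.ones(5), "B": np.zeros(5)})
        assert sim.true_fstat(panel, "f2", ["A", "B"]) == 1.0

    def test_equal_sisters_zero(self, rng):
        p = rng.uniform(0, 1, 10)
        panel = fk.FrequencyPanel(freq={"A": p, "B": p,
                                        "C": rng.uniform(0, 1, 10),
                                        "D": rng.uniform(0, 1, 10)})
        assert np.isclose(sim.true_fstat(panel, "f3", ["A", "B", "C"]),
                          np.mean((p - p) * (p - panel.freq["C"])), atol=1e-15)
        assert np.isclose(sim.true_fstat(panel, "f4", list("ABCD")), 0.0, atol=1e-15)

    def test_f4_as_f2_combination(self, rng):
        """F4(A,B;C,D) = [F2(A,D) + F2(B,C) - F2(A,C) - F2(B,D)] / 2."""
        panel = fk.FrequencyPanel(freq={k: rng.uniform(0, 1, 40) for k in "ABCD"})
        f2 = lambda x, y: sim.true_fstat(panel, "f2", [x, y])
        f4 = sim.true_fstat(panel, "f4", list("ABCD"))
        combo = (f2("A", "D") + f2("B", "C") - f2("A", "C") - f2("B", "D")) / 2
        assert np.isclose(f4, combo, atol=1e-12)


class TestSyntheticPanel:
    def test_packaged_panel_shape_and_range(self, panel):
        assert panel.n_loci == 20 and panel.populations == list("ABCD")
        for pop in panel.populations:
            assert ((panel.freq[pop] > 0) & (panel.freq[pop] < 1)).all()

    def test_generator_reproduces_packaged_panel(self, panel):
        regen = sim.synthetic_divergence_panel(20, list("ABCD"), drift_generations=4000,
                                               ne=10_000, rng=20210715, init_law="uniform")
        for pop in "ABCD":
            np.testing.assert_allclose(panel.freq[pop], regen.freq[pop], atol=5e-7)
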