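import math

import numpy as np
import pytest

from ssrforge import (
    GenotypeMatrix,
    PopulationSpec,
    SimulationSpec,
    allele_frequencies,
    combined_pi,
    expected_heterozygosity,
    holm_correction,
    hwe_exact_test,
    inbreeding_coefficient,
    load_reference_panel,
    null_allele_frequency,
    observed_heterozygosity,
    pic,
    probability_of_identity,
    simulate_genotypes,
    summarize_loci,
    summarize_panel,
    summarize_panel_from_table,
)
from ssrforge.popgen import genotype_counts


def _matrix(calls_per_ind, locus="L1"):
    inds = [f"s{i}" for i in range(len(calls_per_ind))]
    calls = {(ind, locus): c for ind, c in zip(inds, calls_per_ind)}
    return GenotypeMatrix(inds, [locus], calls)


class TestFrequenciesAndHeterozygosity:
    def test_frequencies_count_gene_copies(self):
        m = _matrix([(100, 100), (100, 102)])
        assert allele_frequencies(m, "L1") == {100: 0.75, 102: 0.25}

    def test_monomorphic_and_missing_excluded(self):
        m = _matrix([(100, 100), None, (100, 100)])
        assert allele_frequencies(m, "L1") == {100: 1.0}
        with pytest.raises(ValueError):
            allele_frequencies(_matrix([None]), "L1")

    def test_observed_heterozygosity(self):
        calls = [(100, 102)] + [(100, 100)] * 11  # 1 het of 12 typed
        assert observed_heterozygosity(_matrix(calls), "L1") == pytest.approx(1 / 12)
        assert observed_heterozygosity(_matrix([(1, 2), (3, 4)]), "L1") == 1.0
        assert observed_heterozygosity(_matrix([(1, 1), (2, 2)]), "L1") == 0.0

    def test_expected_heterozygosity_forms(self):
        assert expected_heterozygosity({1: 0.5, 2: 0.5}, 10) == pytest.approx(
            (20 / 19) * 0.5
        )
        assert expected_heterozygosity({1: 0.5, 2: 0.5}, None, unbiased=False) == 0.5
        assert expected_heterozygosity({1: 1.0}, 10) == 0.0
        with pytest.raises(ValueError):
            expected_heterozygosity({1: 0.5, 2: 0.5}, 1)

    @pytest.mark.parametrize(
        "Ho,He,expected",
        [(0.167, 0.235, 0.289), (0.542, 0.633, 0.144), (0.5, 0.5, 0.0)],
    )
    def test_inbreeding_coefficient_matches_reference_rows(self, Ho, He, expected):
        assert inbreeding_coefficient(Ho, He) == pytest.approx(expected, abs=5e-4)

    def test_inbreeding_undefined_when_he_zero(self):
        assert inbreeding_coefficient(0.0, 0.0) is None


class TestHweExactTest:
    def test_two_het_individuals(self):
        # allele counts (2,2): tables {Aa:2} prob 2/3 and {AA,aa} prob 1/3
        assert hwe_exact_test({(1, 2): 2}) == pytest.approx(1.0)

    def test_two_opposite_homozygotes(self):
        assert hwe_exact_test({(1, 1): 1, (2, 2): 1}) == pytest.approx(1 / 3)

    def test_monomorphic_returns_none(self):
        assert hwe_exact_test({(1, 1): 5}) is None

    def test_monte_carlo_agrees_with_enumeration(self):
        observed = {(1, 1): 3, (1, 2): 2, (2, 2): 5, (1, 3): 1, (3, 3): 1}
        p_enum = hwe_exact_test(observed, method="enum", max_tables=100_000)
        reps = 20_000
        p_mc = hwe_exact_test(observed, method="mc", mc_reps=reps, seed=5)
        se = math.sqrt(p_enum * (1 - p_enum) / reps)
        assert abs(p_mc - p_enum) <= 2 * se + 1e-12

    def test_p_values_roughly_uniform_under_the_null(self):
        rng = np.random.default_rng(9)
        pvals = []
        for rep in range(60):
            spec = SimulationSpec(
                seed=int(rng.integers(2**31)),
                populations=[PopulationSpec("P", 50, {"L": {100: 0.5, 102: 0.5}})],
            )
            m, _ = simulate_genotypes(spec)
            pvals.append(hwe_exact_test(genotype_counts(m, "L")))
        pvals = np.array(pvals)
        # exact-test p's are discrete and conservative; demand loose uniformity
        assert (pvals <= 0.05).mean() <= 0.10
        assert 0.35 <= pvals.mean() <= 0.75


class TestNullAllelesPicPi:
    def test_estimators_match_closed_forms(self):
        # He/Ho from a published marker row: (He-Ho)/(He+Ho), (He-Ho)/(1+He)
        assert null_allele_frequency(0.333, 0.505, "chakraborty") == pytest.approx(
            0.2052, abs=1e-3
        )
        assert null_allele_frequency(0.333, 0.505, "brookfield1") == pytest.approx(
            0.1143, abs=1e-3
        )

    def test_floor_at_zero_and_unknown_name(self):
        assert null_allele_frequency(0.6, 0.5, "chakraborty") == 0.0
        assert null_allele_frequency(0.5, 0.5, "brookfield1") == 0.0
        with pytest.raises(ValueError):
            null_allele_frequency(0.5, 0.5, "oosterhout")

    def test_pic_closed_forms(self):
        assert pic({1: 0.5, 2: 0.5}) == pytest.approx(0.375)
        assert pic({1: 1.0}) == 0.0
        assert pic({i: 0.25 for i in range(4)}) == pytest.approx(0.703125)

    def test_pi_closed_forms(self):
        assert probability_of_identity({1: 0.5, 2: 0.5}) == pytest.approx(0.375)
        assert probability_of_identity({1: 1.0}) == pytest.approx(1.0)

    def test_pic_pi_bounds_over_random_frequency_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            k = int(rng.integers(1, 9))
            p = rng.dirichlet(np.ones(k))
            v_pic, v_pi = pic(p), probability_of_identity(p)
            assert 0.0 <= v_pic < 1.0
            assert 0.0 < v_pi <= 1.0 + 1e-12
            assert v_pic <= 1.0 - np.sum(p**2) + 1e-12

    def test_combined_pi_is_exact_product(self):
        vals = [0.1, 0.25, 0.5]
        assert combined_pi(vals) == pytest.approx(0.0125)
        with pytest.raises(ValueError):
            combined_pi([])


class TestHolmCorrection:
    def test_sequential_stop_at_first_failure(self):
        assert holm_correction([0.01, 0.2, 0.03]) == [True, False, False]

    def test_all_ones_none_rejected(self):
        assert holm_correction([1.0, 1.0, 1.0]) == [False, False, False]

    def test_single_test_reduces_to_alpha(self):
        assert holm_correction([0.04]) == [True]
        assert holm_correction([0.06]) == [False]


class TestSummaries:
    def test_panel_aggregates_from_reference_table(self):
        panel = summarize_panel_from_table(load_reference_panel())
        assert panel.total_alleles == 94
        assert panel.mean_Na == pytest.approx(5.53, abs=0.005)
        assert panel.mean_He == pytest.approx(0.545, abs=5e-4)
        assert panel.mean_PIC == pytest.approx(0.492, abs=5e-4)
        assert panel.combined_PI == pytest.approx(1.94e-11, rel=0.01)
        assert (panel.n_high_PIC, panel.n_moderate_PIC, panel.n_low_PIC) == (2, 8, 4)

    def test_single_locus_panel_is_identity(self):
        m = _matrix([(1, 2), (1, 1), (2, 2), (1, 2)])
        summaries = summarize_loci(m, mc_reps=500)
        panel = summarize_panel(summaries)
        assert panel.n_loci == 1
        assert panel.total_alleles == summaries[0].Na
        assert panel.combined_PI == summaries[0].PI

    def test_summarize_loci_flags_and_nulls(self):
        spec = SimulationSpec(
            seed=21,
            populations=[
                PopulationSpec("P", 40, {"L1": {100: 0.5, 102: 0.5},
                                         "L2": {100: 0.7, 102: 0.3}})
            ],
        )
        m, _ = simulate_genotypes(spec)
        summaries = summarize_loci(m, mc_reps=2000, seed=4)
        assert [s.locus for s in summaries] == ["L1", "L2"]
        for s in summaries:
            assert 0 <= s.Ho <= 1 and 0 <= s.He <= 1
            assert s.hwe_p is None or 0 <= s.hwe_p <= 1
            assert set(s.F_null) == {"chakraborty", "brookfield1"}


class TestParameterRecovery:
    def test_he_and_fis_recovered_under_hwe(self):
        freqs = {f"L{l}": {100 + 2 * a: 0.25 for a in range(4)} for l in range(6)}
        spec = SimulationSpec(seed=33, populations=[PopulationSpec("P", 200, freqs)])
        m, _ = simulate_genotypes(spec)
        he_true = 0.75
        fis_values = []
        for locus in m.loci:
            f = allele_frequencies(m, locus)
            n = len(m.typed_individuals(locus))
            he = expected_heterozygosity(f, n)
            ho = observed_heterozygosity(m, locus)
            assert abs(he - he_true) < 0.05
            fis_values.append(inbreeding_coefficient(ho, he))
        assert abs(np.mean(fis_values)) < 0.05

    def test_null_allele_rate_recovered(self):
        r = 0.2
        freqs = {f"L{l}": {100 + 2 * a: 0.2 for a in range(5)} for l in range(4)}
        brookfield = []
        for rep in range(50):
            spec = SimulationSpec(
                seed=1000 + rep,
                populations=[PopulationSpec("P", 100, freqs)],
                null_allele_rate=r,
            )
            m, _ = simulate_genotypes(spec)
            for locus in m.loci:
                f = allele_frequencies(m, locus)
                n = len(m.typed_individuals(locus))
                he = expected_heterozygosity(f, n)
                ho = observed_heterozygosity(m, locus)
                brookfield.append(null_allele_frequency(ho, he, "brookfield1"))
        mean_est = float(np.mean(brookfield))
        assert mean_est > 0
        assert abs(mean_est - r) < 0.07
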