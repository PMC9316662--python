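"""Negative-binomial background fitting, diagnostics and candidate calling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pansubtypes.gene_selection import (
    DegenerateDataError,
    NBFit,
    cramer_von_mises,
    cullen_frey,
    cvm_statistic,
    empirical_mutation_rate,
    fit_negative_binomial,
    gene_sample_counts,
    moment_start,
    poisson_geometric_loglik,
    select_candidates,
    tail_pvalue,
)
from pansubtypes.io_profiles import CohortMatrix
import pandas as pd


def make_matrix(counts, ctypes):
    df = pd.DataFrame(counts)
    df.index = [f"S{i}" for i in range(df.shape[0])]
    df.columns = [f"G{j}" for j in range(df.shape[1])]
    return CohortMatrix(df, pd.Series(ctypes, index=df.index))


class TestGeneSampleCounts:
    def test_presence_not_multiplicity(self):
        m = make_matrix([[7, 0], [0, 2]], ["CT1", "CT1"])
        k = gene_sample_counts(m, "CT1")
        assert list(k) == [1, 1]

    def test_zero_and_full_saturation(self):
        m = make_matrix([[1, 0]] * 4, ["CT1"] * 4)
        k = gene_sample_counts(m, "CT1")
        assert list(k) == [4, 0]

    def test_unknown_cancer_type(self):
        m = make_matrix([[1]], ["CT1"])
        with pytest.raises(KeyError):
            gene_sample_counts(m, "CT9")


class TestCullenFrey:
    def test_balanced_binary_moments(self):
        x = np.array([0, 1] * 50)
        skew, kurt, cloud = cullen_frey(x, n_boot=200, seed=0)
        assert skew == pytest.approx(0.0, abs=1e-12)
        assert kurt == pytest.approx(1.0, abs=1e-12)  # Bernoulli(1/2) kurtosis
        assert cloud.shape == (200, 2)

    def test_nb_skewness_matches_theory(self):
        rng = np.random.default_rng(0)
        x = rng.negative_binomial(2, 0.5, size=50_000)
        skew, _, _ = cullen_frey(x, n_boot=10, seed=0)
        theory = float(stats.nbinom.stats(2, 0.5, moments="s"))
        assert abs(skew - theory) / theory < 0.05

    def test_constant_vector_is_zero_variance_error(self):
        with pytest.raises(DegenerateDataError, match="zero variance"):
            cullen_frey(np.ones(10))

    def test_determinism_under_seed(self):
        x = np.random.default_rng(1).poisson(4, 100) + np.arange(100) % 3
        _, _, c1 = cullen_frey(x, n_boot=50, seed=9)
        _, _, c2 = cullen_frey(x, n_boot=50, seed=9)
        assert np.array_equal(c1, c2)


class TestNBFit:
    def test_moment_start_algebra(self):
        x = np.array([0, 1, 1, 2, 4, 10, 3, 3])
        m, v = x.mean(), x.var()
        r, p = moment_start(x)
        assert r == pytest.approx(m * m / (v - m))
        assert p == pytest.approx(r / (r + m))

    def test_mle_recovers_simulated_parameters(self):
        rng = np.random.default_rng(7)
        x = rng.negative_binomial(2, 0.5, size=5000)
        fit = fit_negative_binomial(x)
        assert 1.8 <= fit.size <= 2.2
        assert 0.47 <= fit.prob <= 0.53

    def test_mle_never_below_moment_start(self):
        rng = np.random.default_rng(3)
        x = rng.negative_binomial(5.5, 0.3, size=800)
        fit = fit_negative_binomial(x)
        r0, p0 = moment_start(x)
        ll0 = stats.nbinom.logpmf(x, r0, p0).sum()
        assert fit.log_likelihood >= ll0 - 1e-9

    def test_constant_vector_is_error(self):
        with pytest.raises(DegenerateDataError):
            fit_negative_binomial(np.full(20, 3))

    def test_underdispersed_advises_poisson(self):
        rng = np.random.default_rng(0)
        x = rng.binomial(10, 0.5, size=500)  # variance < mean
        with pytest.raises(DegenerateDataError, match="Poisson"):
            fit_negative_binomial(x)

    def test_diagnostic_competitors_reported(self):
        rng = np.random.default_rng(2)
        x = rng.negative_binomial(2, 0.4, size=2000)
        ll = poisson_geometric_loglik(x)
        fit = fit_negative_binomial(x)
        assert fit.log_likelihood > ll["poisson"]
        assert fit.log_likelihood > ll["geometric"]


class TestTailPvalue:
    def test_k_zero_is_one(self):
        fit = NBFit("", size=2.0, prob=0.3, log_likelihood=0.0)
        assert tail_pvalue(0, fit) == 1.0

    def test_geometric_closed_form(self):
        fit = NBFit("", size=1.0, prob=0.5, log_likelihood=0.0)
        assert tail_pvalue(3, fit) == pytest.approx(0.125, abs=1e-14)

    def test_matches_brute_force_pmf_summation(self):
        fit = NBFit("", size=2.0, prob=0.3, log_likelihood=0.0)
        brute = 1.0 - sum(stats.nbinom.pmf(x, 2.0, 0.3) for x in range(5))
        assert tail_pvalue(5, fit) == pytest.approx(brute, abs=1e-12)

    def test_gt_variant_shifts_by_one(self):
        fit = NBFit("", size=2.0, prob=0.3, log_likelihood=0.0)
        assert tail_pvalue(5, fit, tail="gt") == pytest.approx(
            tail_pvalue(6, fit, tail="ge"), abs=1e-14)

    def test_negative_k_is_error(self):
        fit = NBFit("", size=1.0, prob=0.5, log_likelihood=0.0)
        with pytest.raises(ValueError):
            tail_pvalue(-1, fit)

    @settings(derandomize=True, max_examples=40)
    @given(st.floats(0.3, 20), st.floats(0.05, 0.95), st.integers(0, 30))
    def test_nonincreasing_in_k(self, r, p, k):
        fit = NBFit("", size=r, prob=p, log_likelihood=0.0)
        assert tail_pvalue(k + 1, fit) <= tail_pvalue(k, fit) + 1e-15


class TestCramerVonMises:
    def test_statistic_nonnegative(self):
        rng = np.random.default_rng(0)
        x = rng.negative_binomial(3, 0.4, 150)
        fit = fit_negative_binomial(x)
        assert cvm_statistic(x, fit) >= 0

    def test_calibrated_under_the_null(self):
        rng = np.random.default_rng(5)
        hits = 0
        reps = 20
        for i in range(reps):
            x = rng.negative_binomial(3, 0.4, size=200)
            fit = fit_negative_binomial(x)
            _, p = cramer_von_mises(x, fit, n_null=199, seed=i)
            hits += p > 0.05
        assert hits >= 0.9 * reps

    def test_power_against_uniform(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 101, size=300)
        fit = NBFit("", size=2.0, prob=0.5, log_likelihood=0.0)
        _, p = cramer_von_mises(x, fit, n_null=199, seed=0)
        assert p < 0.01

    def test_small_null_warns(self):
        rng = np.random.default_rng(1)
        x = rng.negative_binomial(3, 0.4, 100)
        fit = fit_negative_binomial(x)
        with pytest.warns(UserWarning, match="unstable"):
            cramer_von_mises(x, fit, n_null=50, seed=0)


class TestSelectCandidates:
    def _matrix_with_hot_gene(self):
        # per-gene mutation probabilities vary, so mutated-sample counts
        # are overdispersed (beta-binomial) as the background model expects
        rng = np.random.default_rng(0)
        pi = rng.beta(2, 12, size=200)
        counts = (rng.random((60, 200)) < pi).astype(int)
        counts[:, 0] = 1  # gene G0 mutated in every sample
        return make_matrix(counts, ["CT1"] * 60)

    def test_extreme_gene_enters_union(self):
        table, union, fits = select_candidates(self._matrix_with_hot_gene())
        assert "G0" in union
        assert set(table.columns) >= {"gene_id", "cancer_type", "k", "p_value",
                                      "significant"}

    def test_threshold_is_strict(self):
        m = self._matrix_with_hot_gene()
        table, _, _ = select_candidates(m)
        p0 = table.loc[table.gene_id == "G0", "p_value"].iloc[0]
        table2, union2, _ = select_candidates(m, alpha=p0)
        assert "G0" not in union2  # ties at the boundary are excluded

    def test_union_across_disjoint_cancer_types(self):
        rng = np.random.default_rng(1)
        pi = rng.beta(2, 12, size=100)
        base = (rng.random((80, 100)) < pi).astype(int)
        base[:40, 0] = 1  # hot in CT1 only
        base[40:, 1] = 1  # hot in CT2 only
        m = make_matrix(base, ["CT1"] * 40 + ["CT2"] * 40)
        _, union, _ = select_candidates(m)
        assert {"G0", "G1"} <= set(union)

    def test_small_cancer_type_warns_but_processes(self):
        rng = np.random.default_rng(2)
        pi = rng.beta(2, 5, size=300)
        counts = (rng.random((8, 300)) < pi).astype(int)
        m = make_matrix(counts, ["CT1"] * 8)
        with pytest.warns(UserWarning, match="< 10 samples"):
            table, _, _ = select_candidates(m)
        assert len(table) == 300


def test_worked_mutation_probability_example():
    assert empirical_mutation_rate(10, 100) == (0.1, 0.9)
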