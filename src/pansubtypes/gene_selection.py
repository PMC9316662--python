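"""Negative-binomial background modelling and candidate-gene calling.

For each cancer type, the vector of per-gene mutated-sample counts (how many
samples of that type carry >= 1 mutation in each gene) is treated as draws
from an overdispersed background. A negative binomial NB(r, p) is fitted by
maximum likelihood; a gene is a *candidate* when its count falls in the
extreme right tail of the fitted background (tail probability below alpha,
0.001 by default). Diagnostics follow the usual distribution-diagnosis
workflow: a skewness/kurtosis (Cullen-Frey) summary with bootstrap
replicates, and a discrete-adapted Cramer-von Mises goodness-of-fit test with
a parametric-bootstrap null.

The NB uses the "number of failures" parameterization of scipy.stats.nbinom:
pmf(k) = C(k+r-1, k) p^r q^k with q = 1 - p, mean r q / p. r may be
non-integer. The tail probability is the survival function P(X >= k),
computed through the regularized incomplete beta function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_profiles import CohortMatrix


class DegenerateDataError(ValueError):
    """Raised for constant, all-zero, or underdispersed count vectors."""


def empirical_mutation_rate(k: int, n: int) -> tuple[float, float]:
    """Relative frequency of mutated samples for one gene: (p, q).

    A gene mutated in k of n samples has mutation probability p = k/n and
    complementary probability q = 1 - p (a gene mutated in 10 of 100 samples
    gives p = 0.1, q = 0.9).
    """
    if n <= 0 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n with n > 0")
    p = k / n
    return p, 1.0 - p


def gene_sample_counts(matrix: CohortMatrix, cancer_type: str) -> pd.Series:
    """Per-gene number of samples of one cancer type with >= 1 mutation."""
    samples = matrix.samples_of_type(cancer_type)
    return (matrix.counts.loc[samples] > 0).sum(axis=0)


def cullen_frey(
    counts: np.ndarray, n_boot: int = 500, seed: int = 0
) -> tuple[float, float, np.ndarray]:
    """Sample skewness and (non-excess) kurtosis with a bootstrap cloud.

    Returns (skewness, kurtosis, cloud) where cloud is an (n_boot, 2) array
    of resampled (skewness, kurtosis) pairs, the uncertainty display of a
    Cullen-Frey diagnosis plot. Kurtosis is the raw fourth standardized
    moment (Gaussian = 3, Bernoulli(1/2) = 1).
    """
    x = np.asarray(counts, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0:
        raise DegenerateDataError("zero variance: constant vector")
    skew = stats.skew(x, bias=True)
    kurt = stats.kurtosis(x, fisher=False, bias=True)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    boot = x[idx]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cloud = np.column_stack([
            stats.skew(boot, axis=1, bias=True),
            stats.kurtosis(boot, axis=1, fisher=False, bias=True),
        ])
    return float(skew), float(kurt), cloud


@dataclass
class NBFit:
    """Fitted negative-binomial background for one cancer type."""

    cancer_type: str
    size: float  # r > 0
    prob: float  # p in (0, 1)
    log_likelihood: float
    skewness: float = np.nan
    kurtosis: float = np.nan
    bootstrap_cloud: np.ndarray | None = None
    cvm_statistic: float = np.nan
    cvm_pvalue: float = np.nan
    n_obs: int = 0
    diagnostics: dict = field(default_factory=dict)

    @property
    def q(self) -> float:
        return 1.0 - self.prob

    @property
    def mean(self) -> float:
        return self.size * self.q / self.prob

    def distribution(self):
        return stats.nbinom(self.size, self.prob)


def moment_start(counts: np.ndarray) -> tuple[float, float]:
    """Method-of-moments NB start: r = m^2/(v - m), p = r/(r + m)."""
    x = np.asarray(counts, dtype=float)
    m = x.mean()
    v = x.var()
    if v <= m:
        raise DegenerateDataError(
            "variance <= mean: data not overdispersed, consider a Poisson model")
    r = m * m / (v - m)
    return r, r / (r + m)


def _nb_loglik(log_r: float, x: np.ndarray) -> float:
    r = np.exp(log_r)
    p = r / (r + x.mean())
    return float(stats.nbinom.logpmf(x, r, p).sum())


def fit_negative_binomial(counts: np.ndarray, cancer_type: str = "") -> NBFit:
    """Maximum-likelihood NB fit to a nonnegative integer vector.

    p is profiled out (for fixed r the MLE is p = r/(r + mean)), leaving a
    1-D optimization in log r started from the method-of-moments estimate.
    The log-likelihood at the optimum never falls below the start.
    """
    x = np.asarray(counts, dtype=float)
    if x.size == 0 or (x < 0).any():
        raise ValueError("counts must be a nonempty nonnegative vector")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant vector")
    r0, _ = moment_start(x)  # raises on underdispersion
    ll0 = _nb_loglik(np.log(r0), x)
    res = optimize.minimize_scalar(
        lambda lr: -_nb_loglik(lr, x),
        bounds=(np.log(r0) - 5.0, np.log(r0) + 5.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    log_r = res.x if -res.fun >= ll0 else np.log(r0)
    r = float(np.exp(log_r))
    p = float(r / (r + x.mean()))
    ll = _nb_loglik(log_r, x)
    assert ll >= ll0 - 1e-9
    return NBFit(cancer_type=cancer_type, size=r, prob=p,
                 log_likelihood=ll, n_obs=int(x.size))


def poisson_geometric_loglik(counts: np.ndarray) -> dict[str, float]:
    """Log-likelihoods of Poisson and geometric fits, for diagnosis only.

    The pipeline always proceeds with the NB background; these competitors
    are reported so the distribution choice is inspectable.
    """
    x = np.asarray(counts, dtype=float)
    m = x.mean()
    out = {"poisson": float(stats.poisson.logpmf(x, m).sum())}
    p_geo = 1.0 / (1.0 + m)
    out["geometric"] = float(stats.nbinom.logpmf(x, 1.0, p_geo).sum())
    return out


def cvm_statistic(counts: np.ndarray, fit: NBFit) -> float:
    """Cramer-von Mises statistic of counts against the fitted NB CDF.

    Uses the standard computing formula on the sorted sample,
    W^2 = 1/(12n) + sum_i (F(x_(i)) - (2i-1)/(2n))^2, with F the fitted NB
    CDF evaluated at the (discrete) data points.
    """
    x = np.sort(np.asarray(counts, dtype=float))
    n = x.size
    f = stats.nbinom.cdf(x, fit.size, fit.prob)
    i = np.arange(1, n + 1)
    return float(1.0 / (12 * n) + np.sum((f - (2 * i - 1) / (2 * n)) ** 2))


def cramer_von_mises(
    counts: np.ndarray, fit: NBFit, n_null: int = 199, seed: int = 0
) -> tuple[float, float]:
    """Goodness-of-fit p-value by parametric bootstrap.

    Each null replicate redraws a sample of the same size from the fitted
    NB, refits, and recomputes the statistic, so the null accounts for
    parameter estimation. p = (1 + #{W_b >= W}) / (n_null + 1).
    """
    if n_null < 100:
        warnings.warn("n_null < 100 gives an unstable p-value", stacklevel=2)
    x = np.asarray(counts, dtype=float)
    stat = cvm_statistic(x, fit)
    rng = np.random.default_rng(seed)
    null = np.empty(n_null)
    for b in range(n_null):
        for _ in range(20):  # rare degenerate resamples: redraw
            xb = rng.negative_binomial(fit.size, fit.prob, size=x.size)
            try:
                fb = fit_negative_binomial(xb, fit.cancer_type)
            except DegenerateDataError:
                continue
            null[b] = cvm_statistic(xb, fb)
            break
        else:
            null[b] = np.inf
    p = (1.0 + np.sum(null >= stat)) / (n_null + 1.0)
    return stat, float(p)


def tail_pvalue(k: int, fit: NBFit, tail: str = "ge") -> float:
    """Right-tail probability of a mutated-sample count under the background.

    ``tail='ge'`` (default, slightly conservative) returns P(X >= k);
    ``tail='gt'`` returns P(X > k). Both via the NB survival function,
    which for integer arguments equals 1 - sum_{x<k} pmf(x).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if tail not in ("ge", "gt"):
        raise ValueError("tail must be 'ge' or 'gt'")
    kk = k - 1 if tail == "ge" else k
    return float(stats.nbinom.sf(kk, fit.size, fit.prob))


def diagnose_background(
    counts: np.ndarray,
    cancer_type: str = "",
    n_boot: int = 500,
    n_null: int = 199,
    seed: int = 0,
) -> NBFit:
    """Full background fit with Cullen-Frey and Cramer-von Mises evidence."""
    fit = fit_negative_binomial(counts, cancer_type)
    fit.skewness, fit.kurtosis, fit.bootstrap_cloud = cullen_frey(
        counts, n_boot=n_boot, seed=seed)
    fit.cvm_statistic, fit.cvm_pvalue = cramer_von_mises(
        counts, fit, n_null=n_null, seed=seed + 1)
    fit.diagnostics = poisson_geometric_loglik(counts)
    return fit


def select_candidates(
    matrix: CohortMatrix,
    alpha: float = 0.001,
    tail: str = "ge",
    include_zero_genes: bool = True,
) -> tuple[pd.DataFrame, list[str], dict[str, NBFit]]:
    """Call candidate genes per cancer type and take their union.

    Returns (table, union, fits). The table has one row per (gene, cancer
    type) with the mutated-sample count k, its tail p-value, and a
    significance flag (strict p < alpha); the union lists genes significant
    in at least one cancer type, sorted. Genes with zero mutated samples in
    a cancer type are included in the fitted vector by default.
    """
    rows = []
    fits: dict[str, NBFit] = {}
    for ct in matrix.cancer_types:
        k = gene_sample_counts(matrix, ct)
        if len(matrix.samples_of_type(ct)) < 10:
            warnings.warn(f"cancer type {ct!r} has < 10 samples; "
                          "background fit may be unstable", stacklevel=2)
        vec = k.to_numpy() if include_zero_genes else k.to_numpy()[k.to_numpy() > 0]
        fit = fit_negative_binomial(vec, ct)
        fits[ct] = fit
        kk = k.to_numpy()
        shift = 1 if tail == "ge" else 0
        pvals = stats.nbinom.sf(kk - shift, fit.size, fit.prob)
        rows.append(pd.DataFrame({
            "gene_id": k.index,
            "cancer_type": ct,
            "k": kk,
            "p_value": pvals,
            "significant": pvals < alpha,
        }))
    table = pd.concat(rows, ignore_index=True)
    union = sorted(table.loc[table["significant"], "gene_id"].unique())
    return table, union, fits
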