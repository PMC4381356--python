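"""Negative-binomial exact test for two-group count data.

The statistical core shared by the gene-level and bin-level pipelines: a
common-dispersion estimate by maximizing the conditional log-likelihood, an
exact conditional test of the split of the group totals (the edgeR-style
exact test), and Benjamini-Hochberg FDR adjustment.

Parameterization: a count Y ~ NB(mu, phi) has Var Y = mu + phi * mu^2; the
"size" (number of failures) is r = 1/phi.  For n i.i.d. replicates the group
sum is NB with size n*r, and the conditional distribution of one group's sum
given the grand total is beta-binomial(T, n_A*r, n_B*r), degenerating to
Binomial(T, n_A/(n_A+n_B)) as phi -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

_PHI_FLOOR = 1e-8  # below this the NB is numerically Poisson


@dataclass(frozen=True)
class DispersionEstimate:
    phi: float
    n_features: int
    method: str = "conditional-ml"


@dataclass(frozen=True)
class TestResult:
    feature_id: str
    log2_fc: float
    p: float
    fdr: float = np.nan


def equalize_libraries(counts: np.ndarray, library_sizes: np.ndarray) -> np.ndarray:
    """Scale each sample's counts to the geometric-mean library size.

    Returns float pseudo-counts; downstream group sums are rounded to
    integers for the conditional test.  Identity when library sizes are
    equal.
    """
    library_sizes = np.asarray(library_sizes, dtype=float)
    if np.any(library_sizes <= 0):
        raise ValueError("library sizes must be positive")
    ref = np.exp(np.mean(np.log(library_sizes)))
    return np.asarray(counts, dtype=float) * (ref / library_sizes)


def _group_conditional_loglik(pseudo: np.ndarray, r: float) -> float:
    """Summed conditional log-likelihood of one group's replicate counts
    given their total, for NB size r per sample (equal effective libraries).

    pseudo: features x samples (integer-rounded pseudo-counts).
    """
    y = np.asarray(pseudo, dtype=float)
    n = y.shape[1]
    z = y.sum(axis=1)
    ll = (
        gammaln(y + r).sum(axis=1)
        - n * gammaln(r)
        + gammaln(n * r)
        - gammaln(z + n * r)
    )
    # the multinomial-coefficient term gammaln(z+1) - sum gammaln(y+1) is
    # constant in r and omitted
    return float(ll.sum())


def estimate_common_dispersion(
    counts: np.ndarray,
    groups: np.ndarray,
    library_sizes: np.ndarray | None = None,
) -> DispersionEstimate:
    """Common NB dispersion by conditional maximum likelihood.

    ``groups`` labels the columns of ``counts``; the conditional likelihood
    (conditioning on each feature's per-group total of library-equalized
    counts) is summed over groups and features and maximized over phi on a
    log grid followed by bounded refinement.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.size == 0:
        raise ValueError("counts must be a non-empty 2D array")
    if counts.sum() == 0:
        raise ValueError("all-zero count matrix")
    groups = np.asarray(groups)
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    pseudo = np.rint(equalize_libraries(counts, library_sizes))

    blocks = []
    for g in np.unique(groups):
        block = pseudo[:, groups == g]
        if block.shape[1] >= 2:
            blocks.append(block)
    if not blocks:
        raise ValueError("need at least one group with >=2 samples")
    # features with zero total carry no information and break nothing, but
    # dropping them speeds the grid search up
    blocks = [b[b.sum(axis=1) > 0] for b in blocks]
    n_features = max(b.shape[0] for b in blocks)

    def neg_ll_logphi(logphi: float) -> float:
        r = 1.0 / np.exp(logphi)
        return -sum(_group_conditional_loglik(b, r) for b in blocks)

    grid = np.log(np.logspace(-6, 1, 30))
    vals = [neg_ll_logphi(x) for x in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(neg_ll_logphi, bounds=(lo, hi), method="bounded")
    phi = float(np.exp(res.x))
    if phi < 1e-5:  # boundary: no overdispersion signal
        phi = 0.0
    return DispersionEstimate(phi=phi, n_features=n_features)


def _conditional_log_pmf(T: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """log P(S_A = t | S_A + S_B = T) for t = 0..T under common-mean NB."""
    t = np.arange(T + 1, dtype=float)
    if phi <= _PHI_FLOOR:
        p = n_a / (n_a + n_b)
        return (
            gammaln(T + 1) - gammaln(t + 1) - gammaln(T - t + 1)
            + t * np.log(p) + (T - t) * np.log1p(-p)
        )
    ra, rb = n_a / phi, n_b / phi
    return (
        gammaln(T + 1) - gammaln(t + 1) - gammaln(T - t + 1)
        + gammaln(t + ra) + gammaln(T - t + rb) - gammaln(T + ra + rb)
        - gammaln(ra) - gammaln(rb) + gammaln(ra + rb)
    )


def exact_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    phi: float,
    library_sizes_a: np.ndarray | None = None,
    library_sizes_b: np.ndarray | None = None,
) -> tuple[float, float]:
    """Two-sided exact test of equal means between two groups of NB counts.

    Counts are equalized to the geometric-mean library size, summed per
    group, and the conditional probability of the observed split of the
    total is compared against all possible splits: the two-sided p-value is
    the sum of the probabilities of every outcome no more likely than the
    observed one, capped at 1.  With phi=0 and equal libraries this is the
    conditional binomial test.

    Returns ``(log2_fc, p)`` where log2_fc is log2 of the ratio of
    normalized group means (B over A), with a 0.5 pseudo-count added to both
    means when either is zero.
    """
    counts_a = np.atleast_1d(np.asarray(counts_a, dtype=float))
    counts_b = np.atleast_1d(np.asarray(counts_b, dtype=float))
    if phi < 0:
        raise ValueError("phi must be >= 0")
    if np.any(counts_a < 0) or np.any(counts_b < 0):
        raise ValueError("counts must be non-negative")
    n_a, n_b = len(counts_a), len(counts_b)
    if library_sizes_a is None:
        library_sizes_a = np.ones(n_a)
    if library_sizes_b is None:
        library_sizes_b = np.ones(n_b)
    libs = np.concatenate([library_sizes_a, library_sizes_b]).astype(float)
    pseudo = equalize_libraries(
        np.concatenate([counts_a, counts_b]), libs
    )
    mean_a = pseudo[:n_a].mean()
    mean_b = pseudo[n_a:].mean()
    if mean_a == 0 or mean_b == 0:
        log2_fc = float(np.log2((mean_b + 0.5) / (mean_a + 0.5)))
    else:
        log2_fc = float(np.log2(mean_b / mean_a))

    s_a = int(round(pseudo[:n_a].sum()))
    s_b = int(round(pseudo[n_a:].sum()))
    T = s_a + s_b
    if T == 0:
        return 0.0, 1.0
    logpmf = _conditional_log_pmf(T, n_a, n_b, phi)
    obs = logpmf[s_a]
    # sum of outcomes with probability <= observed (tolerance for float ties)
    mask = logpmf <= obs + 1e-10
    p = float(np.exp(logpmf[mask]).sum())
    return log2_fc, min(p, 1.0)


def exact_test_table(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    phi: float,
    library_sizes_a: np.ndarray,
    library_sizes_b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise exact tests for a features x samples pair of matrices.

    Returns arrays ``(log2_fc, p)`` of length n_features.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    n = counts_a.shape[0]
    lfc = np.empty(n)
    pvals = np.empty(n)
    for i in range(n):
        lfc[i], pvals[i] = exact_test(
            counts_a[i], counts_b[i], phi, library_sizes_a, library_sizes_b
        )
    return lfc, pvals


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
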