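"""Exact NB conditional test, dispersion estimation, BH adjustment."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import betabinom, binom

from binsplice.count_statistics import (
    bh_adjust,
    equalize_libraries,
    estimate_common_dispersion,
    exact_test,
)


def enumeration_pvalue(s_a: int, s_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Independent oracle: brute-force sum over every split of the total of
    the conditional pmf, keeping outcomes no more likely than the observed
    one.  Uses scipy's frozen distributions, not the package's formulas."""
    T = s_a + s_b
    if T == 0:
        return 1.0
    if phi == 0:
        dist = binom(T, n_a / (n_a + n_b))
    else:
        dist = betabinom(T, n_a / phi, n_b / phi)
    pmf = dist.pmf(np.arange(T + 1))
    obs = pmf[s_a]
    return float(min(pmf[pmf <= obs * (1 + 1e-12)].sum(), 1.0))


@pytest.mark.parametrize("phi", [0.0, 0.2])
def test_exact_test_matches_enumeration_small_totals(phi):
    """p equals brute-force enumeration of the conditional distribution for
    a sweep of splits (the exhaustive totals<=30 sweep runs in acceptance)."""
    for T in (1, 4, 9, 17, 30):
        for s_a in range(T + 1):
            counts_a = np.array([s_a, 0, 0])
            counts_b = np.array([T - s_a, 0, 0])
            _, p = exact_test(counts_a, counts_b, phi)
            assert p == pytest.approx(enumeration_pvalue(s_a, T - s_a, 3, 3, phi),
                                      abs=1e-9)


def test_conditional_binomial_closed_form():
    """phi=0, equal libraries, 1 vs 1 sample, 0 vs 10 reads: the conditional
    Binomial(10, 1/2) gives p = 2 * (1/2)^10."""
    _, p = exact_test(np.array([0]), np.array([10]), phi=0.0)
    assert p == pytest.approx(2 * 0.5 ** 10, abs=1e-12)


def test_three_versus_seven_split():
    # hand enumeration over the 11 splits of Binomial(10, 1/2)
    _, p = exact_test(np.array([3]), np.array([7]), phi=0.0)
    expected = sum(
        math.comb(10, t) * 0.5 ** 10
        for t in range(11)
        if math.comb(10, t) <= math.comb(10, 3)
    )
    assert p == pytest.approx(expected, abs=1e-12)
    assert p == pytest.approx(0.34375, abs=1e-9)


def test_perfect_symmetry_gives_p_one():
    lfc, p = exact_test(np.array([10, 10]), np.array([10, 10]), phi=0.1)
    assert p == 1.0
    assert lfc == 0.0


def test_all_zero_counts_convention():
    lfc, p = exact_test(np.array([0, 0]), np.array([0, 0]), phi=0.2)
    assert (lfc, p) == (0.0, 1.0)


def test_negative_inputs_rejected():
    with pytest.raises(ValueError):
        exact_test(np.array([-1]), np.array([3]), phi=0.0)
    with pytest.raises(ValueError):
        exact_test(np.array([1]), np.array([3]), phi=-0.5)


def test_log2fc_invariant_under_library_scaling():
    rng = np.random.default_rng(3)
    counts_a = rng.poisson(40, size=3).astype(float)
    counts_b = rng.poisson(90, size=3).astype(float)
    libs = np.full(3, 1e6)
    lfc1, _ = exact_test(counts_a, counts_b, 0.1, libs, libs)
    # scaling counts and library sizes together: fold change is unchanged
    # (p is not: the total evidence doubles)
    lfc2, _ = exact_test(2 * counts_a, 2 * counts_b, 0.1, 2 * libs, 2 * libs)
    assert lfc2 == pytest.approx(lfc1, abs=1e-9)


def test_equalize_libraries_geometric_mean():
    counts = np.array([10.0, 10.0])
    out = equalize_libraries(counts, np.array([100.0, 400.0]))
    # reference = sqrt(100*400) = 200
    assert out == pytest.approx([20.0, 5.0])


def test_dispersion_poisson_data_near_zero():
    rng = np.random.default_rng(0)
    counts = rng.poisson(60, size=(200, 6))
    groups = np.array(["a"] * 3 + ["b"] * 3)
    est = estimate_common_dispersion(counts, groups, np.full(6, counts.sum() / 6))
    assert est.phi < 0.02


def test_dispersion_recovers_nb_truth():
    rng = np.random.default_rng(1)
    phi = 0.2
    r = 1 / phi
    mu = rng.uniform(20, 200, size=500)
    counts = rng.negative_binomial(r, r / (r + mu[:, None]), size=(500, 6))
    groups = np.array(["a"] * 3 + ["b"] * 3)
    est = estimate_common_dispersion(counts, groups, np.full(6, 1.0))
    assert 0.15 <= est.phi <= 0.25


def test_dispersion_identical_replicates_boundary():
    counts = np.full((1, 6), 25)
    groups = np.array(["a"] * 3 + ["b"] * 3)
    est = estimate_common_dispersion(counts, groups, np.full(6, 1.0))
    assert est.phi == 0.0


def test_dispersion_all_zero_rejected():
    with pytest.raises(ValueError):
        estimate_common_dispersion(np.zeros((5, 6)),
                                   np.array(["a"] * 3 + ["b"] * 3))


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Reference BH step-up written independently."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def test_bh_hand_example():
    out = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_bh_trivial_cases():
    assert bh_adjust([0.3]) == pytest.approx([0.3])
    assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
    assert bh_adjust([]).size == 0


def test_bh_matches_independent_step_up():
    rng = np.random.default_rng(7)
    for _ in range(100):
        p = rng.uniform(size=rng.integers(1, 50))
        assert bh_adjust(p) == pytest.approx(bh_oracle(p), abs=1e-12)


@settings(derandomize=True, deadline=None, max_examples=50)
@given(
    st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30)
)
def test_bh_properties(pvals):
    """BH output stays in [0,1], dominates the raw p, and is monotone in
    p-rank."""
    p = np.array(pvals)
    adj = bh_adjust(p)
    assert ((adj >= p - 1e-12) & (adj <= 1 + 1e-12)).all()
    order = np.argsort(p, kind="mergesort")
    assert (np.diff(adj[order]) >= -1e-12).all()


@settings(derandomize=True, deadline=None, max_examples=40)
@given(
    st.lists(st.integers(min_value=0, max_value=40), min_size=2, max_size=4),
    st.lists(st.integers(min_value=0, max_value=40), min_size=2, max_size=4),
    st.sampled_from([0.0, 0.05, 0.3]),
)
def test_exact_test_p_valid_and_symmetric(counts_a, counts_b, phi):
    """p is a probability, and swapping the groups flips the sign of the
    fold change while leaving p unchanged."""
    a, b = np.array(counts_a, dtype=float), np.array(counts_b, dtype=float)
    lfc_ab, p_ab = exact_test(a, b, phi)
    lfc_ba, p_ba = exact_test(b, a, phi)
    assert 0 <= p_ab <= 1
    assert p_ba == pytest.approx(p_ab, abs=1e-9)
    if len(a) == len(b):
        assert lfc_ba == pytest.approx(-lfc_ab, abs=1e-9)
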