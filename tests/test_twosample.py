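"""The ART and comparator two-sample tests.

Each statistic is checked against an independent brute-force oracle written
directly from its definition, and the shared permutation engine is checked
against exhaustive enumeration of all relabellings at small sample sizes.
"""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from circart.core import TWO_PI, AngleSample, geodesic_distance
from circart.twosample import (
    DEFAULT_N_PERMUTATIONS,
    TEST_NAMES,
    CrossSampleTieError,
    art_statistic,
    art_test,
    permutation_pvalue,
    rao_spacing_frequency_statistic,
    rao_spacing_frequency_test,
    run_test,
    watson_u2_pvalue_asymptotic,
    watson_u2_statistic,
    watson_u2_test,
    watson_wheeler_statistic,
    watson_wheeler_test,
)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive loops, no shared code)
# ---------------------------------------------------------------------------


def oracle_art(a1, a2):
    total = 0.0
    for x in a1:
        for y in a2:
            delta = abs(x - y) % TWO_PI
            total += min(delta, TWO_PI - delta)
    return total


def oracle_wu2(a1, a2):
    """Watson U2 from the d_k definition: scan the pooled circular order and
    track the difference between the fractions of each sample seen."""
    m, n = len(a1), len(a2)
    T = m + n
    pooled = [(v, 1) for v in a1] + [(v, 2) for v in a2]
    pooled.sort(key=lambda t: (t[0], t[1]))  # sample 1 first on exact ties
    seen1 = seen2 = 0
    d = []
    for _, lab in pooled:
        if lab == 1:
            seen1 += 1
        else:
            seen2 += 1
        d.append(seen1 / m - seen2 / n)
    dbar = sum(d) / T
    return (m * n) / T**2 * sum((dk - dbar) ** 2 for dk in d)


def oracle_ww(a1, a2):
    """Watson-Wheeler W from circular ranks -> uniform scores -> resultant."""
    m, n = len(a1), len(a2)
    T = m + n
    pooled = sorted([(v, 1) for v in a1] + [(v, 2) for v in a2])
    c = s = 0.0
    for rank, (_, lab) in enumerate(pooled, start=1):
        if lab == 1:
            c += math.cos(2 * math.pi * rank / T)
            s += math.sin(2 * math.pi * rank / T)
    r1_sq = c * c + s * s
    return 2.0 * (r1_sq / m + r1_sq / n)


def oracle_rsf(a1, a2):
    """Count sample-2 points in each circular arc between consecutive sorted
    sample-1 points, then sum absolute deviations from n/m."""
    m, n = len(a1), len(a2)
    anchors = sorted(a1)
    counts = []
    for i in range(m):
        lo = anchors[i]
        hi = anchors[(i + 1) % m]
        if i < m - 1:
            counts.append(sum(lo < y < hi for y in a2))
        else:  # wrap-around arc
            counts.append(sum(y > lo or y < hi for y in a2))
    assert sum(counts) == n
    return sum(abs(f - n / m) for f in counts)


def exhaustive_permutation_p(stat, a1, a2):
    """Exact permutation p-value over all C(m+n, m) relabellings."""
    m = len(a1)
    pooled = np.concatenate([a1, a2])
    obs = stat(AngleSample(a1), AngleSample(a2))
    exceed = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), m):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        val = stat(AngleSample(pooled[mask]), AngleSample(pooled[~mask]))
        exceed += val >= obs - 1e-12
        total += 1
    return exceed / total


@pytest.fixture
def random_samples():
    rng = np.random.default_rng(2024)
    return rng.uniform(0, TWO_PI, 12), rng.uniform(0, TWO_PI, 9)


# ---------------------------------------------------------------------------
# ART
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "a1, a2, expected",
    [
        ([0.0], [np.pi], np.pi),
        ([0.0], [np.pi / 2, np.pi], 3 * np.pi / 2),
        ([2.3], [2.3], 0.0),
    ],
)
def test_art_statistic_examples(a1, a2, expected):
    assert art_statistic(a1, a2) == pytest.approx(expected, abs=1e-12)


def test_art_statistic_symmetric_and_matches_oracle(random_samples):
    a1, a2 = random_samples
    g = art_statistic(a1, a2)
    assert g == art_statistic(a2, a1)
    assert g == pytest.approx(oracle_art(a1, a2), rel=1e-12)


def test_art_statistic_rejects_empty():
    with pytest.raises(ValueError):
        art_statistic([], [1.0])


# ---------------------------------------------------------------------------
# Permutation engine
# ---------------------------------------------------------------------------


def test_permutation_pvalue_formula_and_lattice(random_samples):
    a1, a2 = random_samples
    n_perm = 499
    p, obs, q = permutation_pvalue(art_statistic, a1, a2, n_perm, seed=3)
    assert p == (q + 1) / (n_perm + 1)
    assert 0 <= q <= n_perm
    # p lives on the lattice {k/(N+1)}
    assert (p * (n_perm + 1)) == pytest.approx(round(p * (n_perm + 1)), abs=1e-9)
    assert obs == pytest.approx(art_statistic(a1, a2), rel=1e-9)


def test_permutation_pvalue_seed_determinism(random_samples):
    a1, a2 = random_samples
    r1 = permutation_pvalue(art_statistic, a1, a2, 200, seed=7)
    r2 = permutation_pvalue(art_statistic, a1, a2, 200, seed=7)
    assert r1 == r2


def test_permutation_pvalue_generic_statistic_path():
    """A user-supplied statistic (not one of the built-ins) takes the
    slow per-relabelling path and still obeys the (Q+1)/(N+1) contract."""

    def mean_direction_gap(s1, s2):
        d1 = math.atan2(np.sin(s1.angles).sum(), np.cos(s1.angles).sum())
        d2 = math.atan2(np.sin(s2.angles).sum(), np.cos(s2.angles).sum())
        return geodesic_distance(d1, d2)

    rng = np.random.default_rng(5)
    a1, a2 = rng.uniform(0, TWO_PI, 6), rng.uniform(0, TWO_PI, 5)
    p, obs, q = permutation_pvalue(mean_direction_gap, a1, a2, 99, seed=1)
    assert p == (q + 1) / 100
    assert obs == pytest.approx(mean_direction_gap(AngleSample(a1), AngleSample(a2)))


def test_permutation_pvalue_rejects_bad_count(random_samples):
    a1, a2 = random_samples
    with pytest.raises(ValueError):
        permutation_pvalue(art_statistic, a1, a2, 0, seed=1)


@pytest.mark.parametrize("stat", [art_statistic, watson_u2_statistic, watson_wheeler_statistic])
def test_monte_carlo_matches_exhaustive_enumeration(stat):
    """m = n = 4: the Monte-Carlo p converges to the exact p over all
    C(8, 4) = 70 relabellings within 3 binomial standard errors."""
    rng = np.random.default_rng(99)
    a1 = rng.uniform(0, TWO_PI, 4)
    a2 = rng.uniform(2.0, 2.0 + 1.0, 4) % TWO_PI
    n_perm = 4000
    p_exact = exhaustive_permutation_p(stat, a1, a2)
    p_mc, _, _ = permutation_pvalue(stat, a1, a2, n_perm, seed=11)
    tol = 3 * math.sqrt(p_exact * (1 - p_exact) / n_perm) + 1 / (n_perm + 1)
    assert abs(p_mc - p_exact) <= tol


def test_null_pvalues_near_uniform():
    """Under identical continuous generators the ART p-value is (sub)uniform:
    the empirical CDF stays within the 1% Kolmogorov-Smirnov band."""
    rng = np.random.default_rng(31)
    pvals = []
    for _ in range(1000):
        a1 = rng.uniform(0, TWO_PI, 10)
        a2 = rng.uniform(0, TWO_PI, 10)
        seed = int(rng.integers(2**31))
        p, _, _ = permutation_pvalue(art_statistic, a1, a2, 199, seed=seed)
        pvals.append(p)
    ks = sps.kstest(pvals, "uniform").statistic
    assert ks < 1.63 / math.sqrt(len(pvals))  # 1% critical value


# ---------------------------------------------------------------------------
# Watson's U2
# ---------------------------------------------------------------------------


def test_watson_u2_matches_oracle():
    a1 = [0.1, 0.2, 0.3]
    a2 = [3.1, 3.2, 3.3]
    assert watson_u2_statistic(a1, a2) == pytest.approx(oracle_wu2(a1, a2), rel=1e-12)


def test_watson_u2_random_oracle_and_invariances(random_samples):
    a1, a2 = random_samples
    u2 = watson_u2_statistic(a1, a2)
    assert u2 == pytest.approx(oracle_wu2(list(a1), list(a2)), rel=1e-10)
    assert watson_u2_statistic(a2, a1) == pytest.approx(u2, abs=1e-12)
    rot1 = (a1 + 1.234) % TWO_PI
    rot2 = (a2 + 1.234) % TWO_PI
    assert watson_u2_statistic(rot1, rot2) == pytest.approx(u2, abs=1e-12)


def test_watson_u2_needs_three_points():
    with pytest.raises(ValueError):
        watson_u2_statistic([0.1], [0.2])


def test_watson_u2_asymptotic_pvalue_series():
    # independent 50-term alternating series
    u2 = 0.5
    expected = 2 * sum(
        (-1) ** (k - 1) * math.exp(-2 * k**2 * math.pi**2 * u2) for k in range(1, 51)
    )
    assert watson_u2_pvalue_asymptotic(u2) == pytest.approx(expected, rel=1e-9)
    assert watson_u2_pvalue_asymptotic(1e-12) == pytest.approx(1.0)
    assert watson_u2_pvalue_asymptotic(0.1) > watson_u2_pvalue_asymptotic(0.2)
    with pytest.raises(ValueError):
        watson_u2_pvalue_asymptotic(-0.1)


# ---------------------------------------------------------------------------
# Watson-Wheeler
# ---------------------------------------------------------------------------


def test_watson_wheeler_zero_resultant_configuration():
    # sample 1 occupies ranks 1 and 3 of 4: scores pi/2 and 3 pi/2 cancel
    w = watson_wheeler_statistic([0.1, 1.0], [0.5, 1.5])
    assert w == pytest.approx(0.0, abs=1e-12)
    res = watson_wheeler_test([0.1, 1.0], [0.5, 1.5])
    assert res.p_value == pytest.approx(1.0)


def test_watson_wheeler_matches_oracle():
    a1 = [0.1, 0.2]
    a2 = [3.0, 3.1]
    assert watson_wheeler_statistic(a1, a2) == pytest.approx(oracle_ww(a1, a2), rel=1e-12)


def test_watson_wheeler_symmetry_and_rotation(random_samples):
    a1, a2 = random_samples
    w = watson_wheeler_statistic(a1, a2)
    assert w == pytest.approx(oracle_ww(list(a1), list(a2)), rel=1e-10)
    assert watson_wheeler_statistic(a2, a1) == pytest.approx(w, abs=1e-10)


def test_watson_wheeler_tie_error_and_jitter():
    with pytest.raises(CrossSampleTieError):
        watson_wheeler_statistic([0.5, 1.0], [0.5, 2.0])
    # jitter escape hatch perturbs by ~1e-9 rad and proceeds
    w = watson_wheeler_statistic([0.5, 1.0], [0.5, 2.0], jitter=True, seed=0)
    assert w >= 0.0
    with pytest.raises(CrossSampleTieError):
        watson_wheeler_test([0.5, 1.0], [0.5, 2.0], method="permutation", n_permutations=9, seed=0)


# ---------------------------------------------------------------------------
# Rao spacing frequencies
# ---------------------------------------------------------------------------


def test_rsf_statistic_one_arc_holds_everything():
    a1 = [0.0, np.pi / 2, np.pi, 3 * np.pi / 2]
    a2 = [0.1, 0.2, 0.3, 0.4]
    # f = (4, 0, 0, 0) against expectation n/m = 1 each
    assert rao_spacing_frequency_statistic(a1, a2) == pytest.approx(6.0)


def test_rsf_statistic_perfect_interleaving():
    a1 = [0.0, np.pi / 2, np.pi, 3 * np.pi / 2]
    a2 = [0.2, 0.2 + np.pi / 2, 0.2 + np.pi, 0.2 + 3 * np.pi / 2]
    assert rao_spacing_frequency_statistic(a1, a2) == 0.0
    res = rao_spacing_frequency_test(a1, a2, n_permutations=399, seed=2)
    assert res.p_value > 0.5


def test_rsf_matches_oracle(random_samples):
    a1, a2 = random_samples
    assert rao_spacing_frequency_statistic(a1, a2) == pytest.approx(
        oracle_rsf(list(a1), list(a2))
    )


def test_rsf_needs_two_anchor_points():
    with pytest.raises(ValueError):
        rao_spacing_frequency_statistic([0.5], [1.0, 2.0])


# ---------------------------------------------------------------------------
# Dispatch and cross-cutting invariants
# ---------------------------------------------------------------------------


def test_run_test_dispatch_identity(random_samples):
    a1, a2 = random_samples
    via_dispatch = run_test("ART", a1, a2, n_permutations=299, seed=4)
    direct = art_test(a1, a2, n_permutations=299, seed=4)
    assert via_dispatch == direct


def test_run_test_unknown_name(random_samples):
    a1, a2 = random_samples
    with pytest.raises(ValueError, match="ART"):
        run_test("XYZ", a1, a2)


def test_default_permutation_budget():
    assert DEFAULT_N_PERMUTATIONS == 10_000


@pytest.mark.parametrize("name", TEST_NAMES)
def test_all_tests_rotation_invariant(name, random_samples):
    """A common rotation of both samples leaves the statistic (to 1e-10) and,
    at fixed seed, the permutation p-value unchanged."""
    a1, a2 = random_samples
    base = run_test(name, a1, a2, n_permutations=199, seed=8)
    rot = run_test(name, (a1 + 2.5) % TWO_PI, (a2 + 2.5) % TWO_PI, n_permutations=199, seed=8)
    assert rot.statistic == pytest.approx(base.statistic, abs=1e-10)
    if base.method == "permutation":
        assert rot.p_value == base.p_value
    else:
        assert rot.p_value == pytest.approx(base.p_value, abs=1e-10)
    assert base.statistic >= 0
    assert 0 < base.p_value <= 1


@pytest.mark.parametrize("name", TEST_NAMES)
def test_result_metadata(name, random_samples):
    a1, a2 = random_samples
    res = run_test(name, a1, a2, n_permutations=99, seed=0)
    assert res.test_name == name
    assert (res.m, res.n) == (12, 9)
    if res.method == "permutation":
        assert res.p_value == (res.n_exceeding + 1) / (res.n_permutations + 1)
        assert res.p_value >= 1 / (res.n_permutations + 1)
    else:
        assert res.n_permutations is None
    assert name in res.summary()
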