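"""Two-sample tests for circular data.

The centrepiece is the angular randomisation test (ART): its statistic G is
the sum of geodesic distances over all cross-sample pairs,

    G = sum_i sum_j D(phi_i, psi_j),

with significance assessed by permutation, p = (Q + 1)/(N + 1), where Q counts
relabellings whose statistic is at least the observed G*.  ART is upper-tail
only, exactly as defined.

Five comparators are provided: Watson's U2 with asymptotic (WU2) or
permutation (pWU2) p-values, the Watson-Wheeler uniform-scores test with
asymptotic (WW) or permutation (pWW) p-values, and a Rao spacing-frequencies
test (Rsf) with permutation inference.

All permutation tests share one engine: a matrix of independent uniformly
random relabellings of the pooled sample, drawn in pooled-index space so that
rotating both samples by a common angle leaves every relabelled grouping (and
hence the p-value, for a fixed seed) unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import stats as _sps

from .core import AngleSample, TWO_PI, as_angle_sample, geodesic_distance

TEST_NAMES = ("ART", "WU2", "pWU2", "WW", "pWW", "Rsf")

DEFAULT_N_PERMUTATIONS = 10_000

__all__ = [
    "TEST_NAMES",
    "DEFAULT_N_PERMUTATIONS",
    "TestResult",
    "CrossSampleTieError",
    "art_statistic",
    "art_test",
    "permutation_pvalue",
    "watson_u2_statistic",
    "watson_u2_pvalue_asymptotic",
    "watson_u2_test",
    "watson_wheeler_statistic",
    "watson_wheeler_test",
    "rao_spacing_frequency_statistic",
    "rao_spacing_frequency_test",
    "run_test",
]


class CrossSampleTieError(ValueError):
    """Raised when exact cross-sample ties invalidate a rank-based statistic."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample circular test.

    Attributes
    ----------
    test_name : str
        One of ``ART, WU2, pWU2, WW, pWW, Rsf``.
    statistic : float
        Observed test statistic (G* for ART, U2 for Watson, W for
        Watson-Wheeler, the spacing-frequencies discrepancy for Rsf).
    p_value : float
        In ``(0, 1]``; for permutation inference exactly ``(Q+1)/(N+1)``.
    method : str
        ``"permutation"`` or ``"asymptotic"``.
    m, n : int
        Sample sizes.
    n_permutations, n_exceeding, seed : optional
        Permutation count N, exceedance count Q and RNG seed (permutation
        method only).
    """

    test_name: str
    statistic: float
    p_value: float
    method: str
    m: int
    n: int
    n_permutations: Optional[int] = None
    n_exceeding: Optional[int] = None
    seed: Optional[int] = None

    def summary(self) -> str:
        lines = [
            f"{self.test_name} two-sample test for circular data",
            f"  sample sizes     m = {self.m}, n = {self.n}",
            f"  statistic        {self.statistic:.6g}",
            f"  p-value          {self.p_value:.6g}",
            f"  method           {self.method}",
        ]
        if self.method == "permutation":
            lines.append(f"  permutations     N = {self.n_permutations}, Q = {self.n_exceeding}")
            if self.seed is not None:
                lines.append(f"  seed             {self.seed}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Permutation engine
# ---------------------------------------------------------------------------


class _PermutationContext:
    """Precomputed pooled-sample quantities shared by the batch statistics.

    Relabellings are boolean matrices Z of shape (N, T) in pooled-index
    space; Z[r, i] marks pooled point i as belonging to "sample 1" in
    relabelling r.  Rank-based statistics reorder columns by the circular
    sort of the pooled values (ties broken by original pooled position, so
    sample-1 points sort before equal sample-2 points).
    """

    def __init__(self, a1: np.ndarray, a2: np.ndarray):
        self.m = a1.size
        self.n = a2.size
        self.T = self.m + self.n
        self.pooled = np.concatenate([a1, a2])
        self.z_obs = np.zeros(self.T, dtype=bool)
        self.z_obs[: self.m] = True
        self._order = None
        self._dist = None
        self._scores = None

    @property
    def order(self) -> np.ndarray:
        if self._order is None:
            self._order = np.argsort(self.pooled, kind="stable")
        return self._order

    @property
    def dist(self) -> np.ndarray:
        if self._dist is None:
            self._dist = geodesic_distance(self.pooled[:, None], self.pooled[None, :])
        return self._dist

    @property
    def scores(self) -> tuple[np.ndarray, np.ndarray]:
        """Uniform scores cos/sin at circular ranks 1..T, in sorted order."""
        if self._scores is None:
            beta = TWO_PI * np.arange(1, self.T + 1) / self.T
            self._scores = (np.cos(beta), np.sin(beta))
        return self._scores

    def has_cross_sample_ties(self) -> bool:
        vals1 = set(self.pooled[: self.m].tolist())
        vals2 = set(self.pooled[self.m:].tolist())
        return bool(vals1 & vals2)

    def label_matrix(self, n_permutations: int, rng: np.random.Generator) -> np.ndarray:
        base = np.broadcast_to(self.z_obs, (n_permutations, self.T))
        return rng.permuted(base.copy(), axis=1)


def _count_exceedances(perm: np.ndarray, observed: float) -> int:
    """Q = number of relabellings with statistic weakly greater than observed.

    Mathematical ties (e.g. the complement relabelling of a symmetric
    statistic, or coinciding rank patterns) can land a hair's breadth below
    the observed value in floating point; a small relative tolerance keeps
    the weak inequality weak.
    """
    eps = 1e-9 * (1.0 + abs(observed))
    return int(np.count_nonzero(perm >= observed - eps))


def _batch_art(ctx: _PermutationContext, Z: np.ndarray) -> np.ndarray:
    """Cross-sample geodesic distance sums for each relabelling row of Z."""
    Zf = Z.astype(float)
    D = ctx.dist
    rowsum = D.sum(axis=1)
    A = Zf @ D
    within = np.einsum("rt,rt->r", A, Zf)
    return Zf @ rowsum - within


def _batch_wu2(ctx: _PermutationContext, Z: np.ndarray) -> np.ndarray:
    """Watson U2 from the pooled circular ordering, per relabelling row."""
    Zs = Z[:, ctx.order]
    m, n, T = ctx.m, ctx.n, ctx.T
    cum1 = np.cumsum(Zs, axis=1) / m
    cum2 = np.cumsum(~Zs, axis=1) / n
    d = cum1 - cum2
    d -= d.mean(axis=1, keepdims=True)
    return (m * n) / T**2 * np.einsum("rt,rt->r", d, d)


def _batch_ww(ctx: _PermutationContext, Z: np.ndarray) -> np.ndarray:
    """Watson-Wheeler uniform-scores statistic per relabelling row.

    W = 2 (R1^2/m + R2^2/n) = 2 T R1^2 / (m n) since uniform scores sum to
    zero; asymptotically chi-square with 2 df.
    """
    Zs = Z[:, ctx.order].astype(float)
    c, s = ctx.scores
    C1 = Zs @ c
    S1 = Zs @ s
    return 2.0 * ctx.T * (C1**2 + S1**2) / (ctx.m * ctx.n)


def _batch_rsf(ctx: _PermutationContext, Z: np.ndarray) -> np.ndarray:
    """Rao spacing-frequencies discrepancy per relabelling row.

    Sample 1's points cut the circle into m arcs; f_i counts sample-2 points
    in arc i and the statistic is sum_i |f_i - n/m|.
    """
    Zs = Z[:, ctx.order]
    m, n, T = ctx.m, ctx.n, ctx.T
    # row-major nonzero gives, per row, the ascending sorted positions of
    # sample 1's points; every row holds exactly m of them
    pos = np.nonzero(Zs)[1].reshape(-1, m)
    inner = np.diff(pos, axis=1) - 1
    wrap = (pos[:, :1] + T - pos[:, -1:]) - 1
    f = np.concatenate([inner, wrap], axis=1)
    return np.abs(f - n / m).sum(axis=1)


_BATCH_BY_NAME: dict[str, Callable[[_PermutationContext, np.ndarray], np.ndarray]] = {
    "ART": _batch_art,
    "WU2": _batch_wu2,
    "WW": _batch_ww,
    "Rsf": _batch_rsf,
}


def _resolve_batch(statistic) -> Optional[Callable]:
    """Map a public statistic callable to its vectorised batch form."""
    mapping = {
        art_statistic: _batch_art,
        watson_u2_statistic: _batch_wu2,
        watson_wheeler_statistic: _batch_ww,
        rao_spacing_frequency_statistic: _batch_rsf,
    }
    return mapping.get(statistic)


def permutation_pvalue(
    statistic: Callable,
    s1,
    s2,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: Optional[int] = None,
) -> tuple[float, float, int]:
    """Permutation p-value for any two-sample statistic.

    Draws ``n_permutations`` independent uniformly random relabellings of the
    pooled m+n values into groups of sizes m and n, counts Q = number of
    relabellings with statistic weakly greater than the observed value, and
    returns ``(p, observed, Q)`` with p = (Q+1)/(N+1).  Deterministic given
    ``seed``.

    Known statistics (ART, Watson U2, Watson-Wheeler, Rao spacing
    frequencies) run through a vectorised engine; any other pure function of
    two AngleSamples is evaluated relabelling by relabelling.
    """
    if n_permutations < 1:
        raise ValueError(f"n_permutations must be >= 1, got {n_permutations}")
    s1 = as_angle_sample(s1)
    s2 = as_angle_sample(s2)
    rng = np.random.default_rng(seed)
    ctx = _PermutationContext(s1.angles, s2.angles)
    batch = _resolve_batch(statistic)
    if statistic is watson_wheeler_statistic and ctx.has_cross_sample_ties():
        raise CrossSampleTieError(
            "exact cross-sample ties break the uniform-scores ranking"
        )
    Z = ctx.label_matrix(n_permutations, rng)
    if batch is not None:
        observed = float(batch(ctx, ctx.z_obs[None, :])[0])
        perm = batch(ctx, Z)
    else:
        observed = float(statistic(s1, s2))
        perm = np.array(
            [
                float(statistic(AngleSample(ctx.pooled[row]), AngleSample(ctx.pooled[~row])))
                for row in Z
            ]
        )
    q = _count_exceedances(perm, observed)
    p = (q + 1) / (n_permutations + 1)
    return p, observed, q


# ---------------------------------------------------------------------------
# ART
# ---------------------------------------------------------------------------


def art_statistic(s1, s2) -> float:
    """ART statistic G: sum of geodesic distances over all cross-sample pairs.

    Symmetric in the two samples; no scalar multiplier is applied.
    """
    s1 = as_angle_sample(s1)
    s2 = as_angle_sample(s2)
    return float(geodesic_distance(s1.angles[:, None], s2.angles[None, :]).sum())


def art_test(
    s1,
    s2,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: Optional[int] = None,
) -> TestResult:
    """Angular randomisation test: permutation inference on the G statistic."""
    s1 = as_angle_sample(s1)
    s2 = as_angle_sample(s2)
    p, g_obs, q = permutation_pvalue(art_statistic, s1, s2, n_permutations, seed)
    return TestResult(
        "ART", g_obs, p, "permutation", s1.size, s2.size,
        n_permutations=n_permutations, n_exceeding=q, seed=seed,
    )


# ---------------------------------------------------------------------------
# Watson's U2
# ---------------------------------------------------------------------------


def watson_u2_statistic(s1, s2) -> float:
    """Two-sample Watson U2 from the pooled circular ordering.

    Scanning the pooled sorted sample, with d_k the difference between the
    fractions of each sample seen so far, U2 = (m n / T^2) * sum_k (d_k -
    dbar)^2.  Invariant under a common rotation and under swapping the
    samples.  Exact cross-sample ties are broken deterministically by placing
    sample-1 values first (an infinitesimal positive offset on sample 2).
    """
    s1 = as_angle_sample(s1)
    s2 = as_angle_sample(s2)
    if s1.size + s2.size < 3:
        raise ValueError("Watson U2 needs a combined sample of at least 3 angles")
    ctx = _PermutationContext(s1.angles, s2.angles)
    return float(_batch_wu2(ctx, ctx.z_obs[None, :])[0])


def watson_u2_pvalue_asymptotic(u2: float) -> float:
    """Asymptotic tail probability for Watson's U2.

    p = 2 * sum_{k>=1} (-1)^(k-1) exp(-2 k^2 pi^2 u2), truncated once terms
    fall below 1e-10 in magnitude (at least one term), clamped to (0, 1].
    Below u2 = 0.05 the alternating series converges too slowly and the
    Jacobi theta transformation of the same function is summed instead:
    p = 1 - sqrt(2 / (pi u2)) * sum_{j>=0} exp(-(2j+1)^2 / (8 u2)).
    """
    if u2 < 0:
        raise ValueError(f"U2 must be non-negative, got {u2}")
    if u2 < 0.05:
        if u2 == 0.0:
            return 1.0
        total = 0.0
        j = 0
        while True:
            term = math.exp(-((2 * j + 1) ** 2) / (8.0 * u2))
            total += term
            if term < 1e-12 * max(total, 1.0):
                break
            j += 1
        p = 1.0 - math.sqrt(2.0 / (math.pi * u2)) * total
    else:
        total = 0.0
        k = 1
        while True:
            term = (-1.0) ** (k - 1) * math.exp(-2.0 * k * k * math.pi * math.pi * u2)
            total += term
            if abs(term) < 1e-10:
                break
            k += 1
        p = 2.0 * total
    return min(max(p, math.ulp(0.0)), 1.0)


def watson_u2_test(
    s1,
    s2,
    method: str = "asymptotic",
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: Optional[int] = None,
) -> TestResult:
    """Watson's U2 test, with asymptotic (WU2) or permutation (pWU2) p-value."""
    s1 = as_angle_sample(s1)
    s2 = as_angle_sample(s2)
    if method == "asymptotic":
        u2 = watson_u2_statistic(s1, s2)
        p = watson_u2_pvalue_asymptotic(u2)
        return TestResult("WU2", u2, p, "asymptotic", s1.size, s2.size)
    if method == "permutation":
        p, u2, q = permutation_pvalue(watson_u2_statistic, s1, s2, n_permutations, seed)
        return TestResult(
            "pWU2", u2, p, "permutation", s1.size, s2.size,
            n_permutations=n_permutations, n_exceeding=q, seed=seed,
        )
    raise ValueError(f"method must be 'asymptotic' or 'permutation', got {method!r}")


# ---------------------------------------------------------------------------
# Watson-Wheeler (uniform scores)
# ---------------------------------------------------------------------------


def _check_ww_ties(ctx: _PermutationContext, jitter: bool, seed: Optional[int]) -> _PermutationContext:
    if not ctx.has_cross_sample_ties():
        return ctx
    if not jitter:
        raise CrossSampleTieError(
            "exact cross-sample ties break the uniform-scores ranking; "
            "pass jitter=True to apply a seeded 1e-9 rad perturbation"
        )
    rng = np.random.default_rng(seed)
    a2 = np.mod(ctx.pooled[ctx.m:] + rng.uniform(-1e-9, 1e-9, ctx.n), TWO_PI)
    return _PermutationContext(ctx.pooled[: ctx.m], a2)


def watson_wheeler_statistic(s1, s2, jitter: bool = False, seed: Optional[int] = None) -> float:
    """Watson-Wheeler two-sample uniform-scores statistic W.

    Pooled circular ranks r map to uniform scores beta = 2 pi r / T; with R1
    the resultant length of sample 1's scores, W = 2 T R1^2 / (m n),
    asymptotically chi-square with 2 degrees of freedom.  Exact cross-sample
    ties raise :class:`CrossSampleTieError` unless ``jitter`` is set.
    """
    s1 = as_angle_sample(s1)
    s2 = as_angle_sample(s2)
    if s1.size + s2.size < 3:
        raise ValueError("Watson-Wheeler needs a combined sample of at least 3 angles")
    ctx = _PermutationContext(s1.angles, s2.angles)
    ctx = _check_ww_ties(ctx, jitter, seed)
    return float(_batch_ww(ctx, ctx.z_obs[None, :])[0])


def watson_wheeler_test(
    s1,
    s2,
    method: str = "asymptotic",
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: Optional[int] = None,
    jitter: bool = False,
) -> TestResult:
    """Watson-Wheeler test, asymptotic (WW) or permutation (pWW) inference."""
    s1 = as_angle_sample(s1)
    s2 = as_angle_sample(s2)
    w = watson_wheeler_statistic(s1, s2, jitter=jitter, seed=seed)
    if method == "asymptotic":
        p = float(_sps.chi2.sf(w, df=2))
        p = min(max(p, math.ulp(0.0)), 1.0)
        return TestResult("WW", w, p, "asymptotic", s1.size, s2.size)
    if method == "permutation":
        p, w, q = permutation_pvalue(watson_wheeler_statistic, s1, s2, n_permutations, seed)
        return TestResult(
            "pWW", w, p, "permutation", s1.size, s2.size,
            n_permutations=n_permutations, n_exceeding=q, seed=seed,
        )
    raise ValueError(f"method must be 'asymptotic' or 'permutation', got {method!r}")


# ---------------------------------------------------------------------------
# Rao spacing frequencies
# ---------------------------------------------------------------------------


def rao_spacing_frequency_statistic(s1, s2) -> float:
    """Spacing-frequencies discrepancy sum_i |f_i - n/m|.

    The m circular arcs between consecutive order statistics of sample 1
    receive spacing frequencies f_1..f_m of sample-2 points (sum f_i = n);
    the statistic measures their departure from the uniform expectation n/m.
    Anchored on sample 1, hence not symmetric in the two samples.
    """
    s1 = as_angle_sample(s1)
    s2 = as_angle_sample(s2)
    if s1.size < 2:
        raise ValueError("the spacing-frequencies statistic needs m >= 2 anchor points")
    ctx = _PermutationContext(s1.angles, s2.angles)
    return float(_batch_rsf(ctx, ctx.z_obs[None, :])[0])


def rao_spacing_frequency_test(
    s1,
    s2,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: Optional[int] = None,
) -> TestResult:
    """Rao spacing-frequencies test with permutation inference."""
    s1 = as_angle_sample(s1)
    s2 = as_angle_sample(s2)
    if s1.size < 2:
        raise ValueError("the spacing-frequencies statistic needs m >= 2 anchor points")
    p, stat, q = permutation_pvalue(rao_spacing_frequency_statistic, s1, s2, n_permutations, seed)
    return TestResult(
        "Rsf", stat, p, "permutation", s1.size, s2.size,
        n_permutations=n_permutations, n_exceeding=q, seed=seed,
    )


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------


def run_test(
    name: str,
    s1,
    s2,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: Optional[int] = None,
) -> TestResult:
    """Run one of the six tests by name.

    ``ART``, ``pWU2``, ``pWW`` and ``Rsf`` use permutation inference with
    ``n_permutations`` relabellings and ``seed``; ``WU2`` and ``WW`` use their
    asymptotic p-values.
    """
    if name == "ART":
        return art_test(s1, s2, n_permutations, seed)
    if name == "WU2":
        return watson_u2_test(s1, s2, method="asymptotic")
    if name == "pWU2":
        return watson_u2_test(s1, s2, method="permutation", n_permutations=n_permutations, seed=seed)
    if name == "WW":
        return watson_wheeler_test(s1, s2, method="asymptotic")
    if name == "pWW":
        return watson_wheeler_test(s1, s2, method="permutation", n_permutations=n_permutations, seed=seed)
    if name == "Rsf":
        return rao_spacing_frequency_test(s1, s2, n_permutations, seed)
    raise ValueError(f"unknown test {name!r}; valid names: {', '.join(TEST_NAMES)}")
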