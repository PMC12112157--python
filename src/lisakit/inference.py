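"""Permutation-based significance assessment.

Global statistics use total randomization (the whole value vector is
shuffled across locations); local statistics use conditional randomization
(the focal value stays fixed, the remaining n-1 values are shuffled across
the other locations).  Each location draws its permutations from a random
stream seeded by (master seed, time key, location index), so results are
independent of iteration order and of which methods are enabled.

The pseudo p-value is tail-wise one-sided with min-tail selection and no
doubling::

    R_up = #{s in S : s >= observed},  R_down = #{s in S : s <= observed}
    p* = (min(R_up, R_down) + 1) / (M + 1)

so p* >= 1/(M+1) always.  Statistics are additionally standardized against
the permuted set S (sample sd), and empirical significance bounds at level
alpha are reported per tail (nearest-rank quantiles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .errors import DegenerateInputError, InferenceFailureError, WeightError
from .stats import (
    GLOBAL_STATS,
    SELF_INCLUDED_METHODS,
    ZScoreVector,
    _as_z,
    focal_exclusion_moments,
)
from .weights import WeightMatrix

DEFAULT_PERMUTATIONS = 999
_EPS = 1e-12


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic with its empirical null summary."""

    observed: float
    permuted: np.ndarray
    n_perm: int
    pseudo_p: float
    tail: str  # "upper" | "lower"
    standardized: float  # NaN when sd(S) == 0
    lower_bound: float
    upper_bound: float
    significant: bool

    @property
    def permutation_mean(self) -> float:
        return float(np.mean(self.permuted))

    @property
    def permutation_sd(self) -> float:
        return float(np.std(self.permuted, ddof=1)) if self.n_perm > 1 else 0.0


def pseudo_p(observed: float, permuted) -> tuple[float, str]:
    """Min-tail pseudo p-value p* and the tail it was taken from."""
    permuted = np.asarray(permuted, dtype=float)
    m = permuted.size
    if m < 1:
        raise InferenceFailureError("need at least one permutation")
    r_up = int(np.sum(permuted >= observed))
    r_down = int(np.sum(permuted <= observed))
    tail = "upper" if r_up <= r_down else "lower"
    return (min(r_up, r_down) + 1) / (m + 1), tail


def standardize(observed: float, permuted) -> float:
    """(observed - mean(S)) / sd(S) with the sample sd; NaN when sd == 0."""
    permuted = np.asarray(permuted, dtype=float)
    sd = float(np.std(permuted, ddof=1)) if permuted.size > 1 else 0.0
    if sd <= 0.0:
        return float("nan")
    return float((observed - permuted.mean()) / sd)


def significance_bounds(permuted, alpha: float) -> tuple[float, float]:
    """Tail-wise nearest-rank empirical bounds at level alpha.

    lower = k-th smallest and upper = k-th largest permuted value with
    ``k = ceil(alpha * M)``, matching the tail-wise p* rule.
    """
    if not 0.0 < alpha < 0.5:
        raise ValueError(f"alpha must be in (0, 0.5), got {alpha}")
    s = np.sort(np.asarray(permuted, dtype=float))
    m = s.size
    k = max(1, int(np.ceil(alpha * m)))
    return float(s[k - 1]), float(s[m - k])


def build_result(observed: float, permuted, alpha: float) -> PermutationResult | None:
    """Assemble a :class:`PermutationResult`; None when observed is undefined."""
    if observed is None or not np.isfinite(observed):
        return None
    permuted = np.asarray(permuted, dtype=float)
    permuted = permuted[np.isfinite(permuted)]
    if permuted.size < 1:
        raise InferenceFailureError("no defined permutation replicates")
    p, tail = pseudo_p(observed, permuted)
    std = standardize(observed, permuted)
    lo, hi = significance_bounds(permuted, alpha)
    return PermutationResult(
        observed=float(observed),
        permuted=permuted,
        n_perm=permuted.size,
        pseudo_p=p,
        tail=tail,
        standardized=std,
        lower_bound=lo,
        upper_bound=hi,
        significant=bool(p <= alpha and np.isfinite(std)),
    )


# ---------------------------------------------------------------------------
# total randomization (global statistics)
# ---------------------------------------------------------------------------


def _permutation_matrix(z: np.ndarray, M: int, rng: np.random.Generator) -> np.ndarray:
    """M independent uniformly random permutations of z, one per row."""
    keys = rng.random((M, z.size))
    return z[np.argsort(keys, axis=1)]


def permute_global(
    stat,
    W: WeightMatrix,
    z,
    M: int = DEFAULT_PERMUTATIONS,
    seed=0,
    alpha: float = 0.05,
) -> PermutationResult:
    """Total-randomization permutation test for a global statistic.

    ``stat`` is a name from :data:`lisakit.stats.GLOBAL_STATS` or any
    callable ``stat(W, z) -> float``.  ``seed`` may be an int or a sequence
    of ints (SeedSequence entropy).
    """
    if M < 1:
        raise InferenceFailureError("M must be >= 1")
    fn = GLOBAL_STATS[stat] if isinstance(stat, str) else stat
    z = _as_z(z)
    observed = fn(W, z)
    rng = np.random.default_rng(seed)
    zperm = _permutation_matrix(z, M, rng)
    permuted = np.array([fn(W, zperm[r]) for r in range(M)])
    n_bad = int(np.sum(~np.isfinite(permuted)))
    if n_bad > M / 2:
        raise InferenceFailureError(
            f"statistic undefined on {n_bad}/{M} permutation replicates"
        )
    res = build_result(observed, permuted, alpha)
    if res is None:
        raise InferenceFailureError("observed global statistic is undefined")
    return res


# ---------------------------------------------------------------------------
# conditional randomization (local statistics)
# ---------------------------------------------------------------------------


def conditional_draws(
    z: np.ndarray, i: int, k: int, M: int, rng: np.random.Generator
) -> np.ndarray:
    """M draws of k values, without replacement, from z excluding index i.

    Returns an (M, k) array.  Because contiguity weights are equal within a
    row, only the drawn subset matters, not its arrangement.
    """
    pool = np.delete(z, i)
    if k > pool.size:
        raise WeightError(f"location {i}: {k} neighbors but only {pool.size} other values")
    keys = rng.random((M, pool.size))
    if k == pool.size:
        idx = np.argsort(keys, axis=1)
    else:
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    return pool[idx]


def _local_null(method: str, z: np.ndarray, i: int, draws: np.ndarray) -> np.ndarray:
    """Evaluate the local statistic at location i for each permuted draw."""
    n = z.size
    zi = z[i]
    k = draws.shape[1]
    nbr_mean = draws.mean(axis=1)
    if method == "local_moran":
        return zi * nbr_mean / (n - 1)
    if method == "local_geary":
        return ((zi - draws) ** 2).mean(axis=1)
    if method == "gi":
        mom = focal_exclusion_moments(z)
        bracket = (n / k - 1.0) / (n - 1)
        denom = mom.sd_excl[i] * np.sqrt(bracket)
        if mom.sd_excl[i] <= _EPS or bracket <= _EPS:
            return np.full(draws.shape[0], np.nan)
        return (nbr_mean - mom.mean_excl[i]) / denom
    if method == "gi_star":
        bracket = (n / (k + 1.0) - 1.0) / (n - 1)
        if bracket <= _EPS:
            return np.full(draws.shape[0], np.nan)
        return (zi + draws.sum(axis=1)) / (k + 1.0) / np.sqrt(bracket)
    raise KeyError(f"unknown local method {method!r}")


def _observed_local(method: str, W: WeightMatrix, W_self: WeightMatrix | None, z):
    from . import stats as _stats

    fn = _stats.LOCAL_STATS[method]
    if method in SELF_INCLUDED_METHODS:
        if W_self is None:
            raise WeightError(f"{method} needs the self-included weight matrix")
        return fn(W_self, z)
    return fn(W, z)


def permute_local_conditional(
    stat: str,
    W: WeightMatrix,
    z,
    i: int,
    M: int = DEFAULT_PERMUTATIONS,
    seed=0,
    alpha: float = 0.05,
    W_self: WeightMatrix | None = None,
) -> PermutationResult | None:
    """Conditional (focal-value-fixed) permutation test for one location.

    Returns None for islands / undefined statistics.  ``seed`` may be an int
    or a sequence of ints; the location index is appended so per-location
    streams are independent of execution order.
    """
    z = _as_z(z)
    if stat in SELF_INCLUDED_METHODS and W_self is None:
        from .weights import add_self, row_normalize

        W_self = row_normalize(add_self(WeightMatrix(
            base=W.base, matrix=W.base.copy(), index=W.index)))
    observed_vec = _observed_local(stat, W, W_self, z)
    observed = float(observed_vec[i])
    if not np.isfinite(observed):
        return None
    k = int(W.degrees()[i])
    entropy = [seed] if np.isscalar(seed) else list(seed)
    rng = np.random.default_rng(entropy + [int(i)])
    draws = conditional_draws(z, i, k, M, rng)
    permuted = _local_null(stat, z, i, draws)
    return build_result(observed, permuted, alpha)


def local_inference(
    methods: list[str],
    W: WeightMatrix,
    z,
    M: int = DEFAULT_PERMUTATIONS,
    seed=0,
    alpha: float = 0.05,
    W_self: WeightMatrix | None = None,
) -> dict[str, list[PermutationResult | None]]:
    """Conditional permutation inference for every location and method.

    All methods share the same per-location draws (one stream per location),
    so enabling or disabling a method never changes another method's results.
    """
    z = _as_z(z)
    observed = {m: _observed_local(m, W, W_self, z) for m in methods}
    degrees = W.degrees()
    entropy = [seed] if np.isscalar(seed) else list(seed)
    out: dict[str, list[PermutationResult | None]] = {m: [] for m in methods}
    for i in range(z.size):
        k = int(degrees[i])
        if k == 0:
            for m in methods:
                out[m].append(None)
            continue
        rng = np.random.default_rng(entropy + [int(i)])
        draws = conditional_draws(z, i, k, M, rng)
        for m in methods:
            obs = float(observed[m][i])
            if not np.isfinite(obs):
                out[m].append(None)
                continue
            out[m].append(build_result(obs, _local_null(m, z, i, draws), alpha))
    return out


def kde_density(permuted, grid: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE (Silverman bandwidth) of the permuted set.

    Evaluated on a regular grid spanning [min - 3h, max + 3h]; the trapezoid
    integral of the output is ~1.
    """
    permuted = np.asarray(permuted, dtype=float)
    if permuted.size < 2:
        raise DegenerateInputError("need at least 2 permuted values for a KDE")
    if np.std(permuted, ddof=1) <= 0.0:
        raise DegenerateInputError("degenerate permuted set: zero spread")
    kde = sp_stats.gaussian_kde(permuted, bw_method="silverman")
    h = float(kde.factor * permuted.std(ddof=1))
    xs = np.linspace(permuted.min() - 3 * h, permuted.max() + 3 * h, grid)
    return xs, kde(xs)
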