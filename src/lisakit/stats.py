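"""Deterministic spatial association statistics on z-normalized values.

All statistics consume a z-score vector (sample standard deviation,
divisor n-1) and a row-normalized binary weight matrix.  With those
conventions:

* global Moran's I  ``I = sum_i z_i lag_i / (n-1)`` coincides with the
  classic ``(n/S0) * sum_ij W_ij z_i z_j / sum z^2`` form,
* global Geary's C  ``C = sum_ij W_ij (z_i - z_j)^2 / (2n)`` is the
  textbook Geary statistic,
* the Getis-Ord Gi/Gi* are the Ord-Getis z-forms; Gi* uses the
  self-included matrix, Gi the self-excluded one.

Undefined results (islands, degenerate denominators) are returned as NaN
markers; downstream code treats NaN as "undefined", never folds it into
aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, WeightError
from .weights import WeightMatrix

_EPS = 1e-12


@dataclass(frozen=True)
class ZScoreVector:
    """z-normalized values with the raw moments they were derived from."""

    z: np.ndarray
    mu: float
    sigma: float

    @property
    def n(self) -> int:
        return self.z.size


def znormalize(x) -> ZScoreVector:
    """z-score normalize ``x`` with the sample standard deviation (n-1).

    Raises :class:`DegenerateInputError` on constant input (sigma == 0).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("need at least 2 values to normalize")
    if not np.all(np.isfinite(x)):
        raise DegenerateInputError("values must all be finite")
    mu = float(x.mean())
    sigma = float(x.std(ddof=1))
    if sigma <= 0.0:
        raise DegenerateInputError("constant input: standard deviation is zero")
    return ZScoreVector(z=(x - mu) / sigma, mu=mu, sigma=sigma)


def _as_z(z) -> np.ndarray:
    if isinstance(z, ZScoreVector):
        return z.z
    return np.asarray(z, dtype=float)


def _check(W: WeightMatrix, z: np.ndarray, include_self: bool) -> None:
    if z.size != W.n:
        raise WeightError(f"dimension mismatch: {z.size} values vs {W.n} areas")
    if not W.row_normalized:
        raise WeightError("weight matrix must be row-normalized")
    if W.includes_self != include_self:
        want = "self-included" if include_self else "self-excluded"
        raise WeightError(f"weight matrix must be {want} for this statistic")


def spatial_lag(W: WeightMatrix, z) -> np.ndarray:
    """Spatial lag ``lag_i = sum_j W_ij z_j`` (weighted neighbor mean).

    Island entries are NaN.
    """
    z = _as_z(z)
    _check(W, z, include_self=False)
    lag = W.matrix @ z
    lag[W.islands()] = np.nan
    return lag


def _mask(W: WeightMatrix) -> np.ndarray:
    return np.diff(W.base.indptr) > 0


def global_moran(W: WeightMatrix, z) -> float:
    """Global Moran's I; islands are excluded from the sum."""
    z = _as_z(z)
    _check(W, z, include_self=False)
    m = _mask(W)
    if not m.any():
        return float("nan")
    lag = W.matrix @ z
    return float(np.sum(z[m] * lag[m]) / (z.size - 1))


def local_moran(W: WeightMatrix, z) -> np.ndarray:
    """Local Moran's I_i = z_i * lag_i / (n-1); islands NaN.

    Summing the defined entries recovers the global Moran's I exactly.
    """
    z = _as_z(z)
    _check(W, z, include_self=False)
    lag = W.matrix @ z
    out = z * lag / (z.size - 1)
    out[~_mask(W)] = np.nan
    return out


def global_geary(W: WeightMatrix, z) -> float:
    """Global Geary's C = sum_ij W_ij (z_i - z_j)^2 / (2n)."""
    z = _as_z(z)
    _check(W, z, include_self=False)
    if not _mask(W).any():
        return float("nan")
    return float(np.nansum(local_geary(W, z)) / (2.0 * z.size))


def local_geary(W: WeightMatrix, z) -> np.ndarray:
    """Local Geary's C_i = sum_j W_ij (z_i - z_j)^2 >= 0; islands NaN."""
    z = _as_z(z)
    _check(W, z, include_self=False)
    rowsum = W.matrix.sum(axis=1)
    out = z * z * rowsum - 2.0 * z * (W.matrix @ z) + W.matrix @ (z * z)
    out = np.maximum(out, 0.0)  # guard tiny negative round-off
    out[~_mask(W)] = np.nan
    return out


def general_g(W: WeightMatrix, z) -> float:
    """Getis-Ord General G on z values.

    ``G = sum_{i != j} W_ij z_i z_j / sum_{i != j} z_i z_j``; NaN when the
    denominator vanishes.  Interpretation is deferred entirely to the
    permutation standardization.
    """
    z = _as_z(z)
    _check(W, z, include_self=False)
    den = float(np.sum(z) ** 2 - np.sum(z * z))
    if abs(den) < _EPS:
        return float("nan")
    num = float(np.sum(z * (W.matrix @ z)))
    return num / den


@dataclass(frozen=True)
class FocalExclusionMoments:
    """Mean and sd of z over all locations except the focal one."""

    mean_excl: np.ndarray
    sd_excl: np.ndarray


def focal_exclusion_moments(z) -> FocalExclusionMoments:
    """Leave-one-out mean z̄(i) and sd S(i) over the n-1 non-focal values.

    S(i) uses the population divisor over the n-1 entries (Ord-Getis form).
    """
    z = _as_z(z)
    n = z.size
    if n < 2:
        raise DegenerateInputError("need at least 2 values")
    total = z.sum()
    sq = (z * z).sum()
    mean_excl = (total - z) / (n - 1)
    var = (sq - z * z) / (n - 1) - mean_excl**2
    sd_excl = np.sqrt(np.maximum(var, 0.0))
    return FocalExclusionMoments(mean_excl=mean_excl, sd_excl=sd_excl)


def _row_sq_sums(W: WeightMatrix) -> np.ndarray:
    m2 = W.matrix.copy()
    m2.data = m2.data**2
    return m2.sum(axis=1)


def gi_star(W_self: WeightMatrix, z) -> np.ndarray:
    """Getis-Ord Gi* (focal value included via the self-included matrix).

    ``Gi*_i = (sum_j W_ij z_j) / sqrt([n sum_j W_ij^2 - 1] / (n-1))``;
    NaN where the bracket is <= 0 (e.g. uniform weights over all areas).
    """
    z = _as_z(z)
    _check(W_self, z, include_self=True)
    n = z.size
    lag = W_self.matrix @ z
    bracket = (n * _row_sq_sums(W_self) - 1.0) / (n - 1)
    out = np.full(n, np.nan)
    # islands carry no neighborhood information: no statistic, even with self
    ok = _mask(W_self) & (bracket > _EPS)
    out[ok] = lag[ok] / np.sqrt(bracket[ok])
    return out


def gi(W: WeightMatrix, z) -> np.ndarray:
    """Getis-Ord Gi (focal value excluded).

    ``Gi_i = (sum_j W_ij z_j - z̄(i) sum_j W_ij)
    / (S(i) sqrt([n sum_j W_ij^2 - (sum_j W_ij)^2] / (n-1)))``
    with leave-one-out moments z̄(i), S(i); NaN for islands, S(i)=0, or a
    non-positive bracket.
    """
    z = _as_z(z)
    _check(W, z, include_self=False)
    n = z.size
    mom = focal_exclusion_moments(z)
    lag = W.matrix @ z
    wsum = W.matrix.sum(axis=1)
    bracket = (n * _row_sq_sums(W) - wsum**2) / (n - 1)
    out = np.full(n, np.nan)
    ok = _mask(W) & (bracket > _EPS) & (mom.sd_excl > _EPS)
    out[ok] = (lag[ok] - mom.mean_excl[ok] * wsum[ok]) / (
        mom.sd_excl[ok] * np.sqrt(bracket[ok])
    )
    return out


#: statistic registries used by the inference and pipeline layers
GLOBAL_STATS = {
    "moran": global_moran,
    "geary": global_geary,
    "general_g": general_g,
}

LOCAL_STATS = {
    "local_moran": local_moran,
    "local_geary": local_geary,
    "gi": gi,
    "gi_star": gi_star,
}

#: local methods whose weight matrix includes the focal location
SELF_INCLUDED_METHODS = frozenset({"gi_star"})
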