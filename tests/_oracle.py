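"""Independent brute-force reference implementations.

Naive double-loop versions of every spatial statistic, written directly
from the defining sums over a dense weight matrix.  They share no code with
the package's vectorized implementations and exist purely as oracles.
"""

import math

import numpy as np


def dense(W):
    """Dense working matrix of a WeightMatrix."""
    return W.matrix.todense()


def znorm_naive(x):
    x = list(map(float, x))
    n = len(x)
    mu = sum(x) / n
    var = sum((v - mu) ** 2 for v in x) / (n - 1)
    s = math.sqrt(var)
    return [(v - mu) / s for v in x]


def lag_naive(Wd, z):
    n = len(z)
    out = []
    for i in range(n):
        if all(Wd[i, j] == 0 for j in range(n)):
            out.append(float("nan"))
        else:
            out.append(sum(Wd[i, j] * z[j] for j in range(n)))
    return out


def global_moran_naive(Wd, z):
    n = len(z)
    total = 0.0
    for i in range(n):
        if all(Wd[i, j] == 0 for j in range(n)):
            continue
        for j in range(n):
            total += Wd[i, j] * z[i] * z[j]
    return total / (n - 1)


def local_moran_naive(Wd, z):
    n = len(z)
    lag = lag_naive(Wd, z)
    return [z[i] * lag[i] / (n - 1) for i in range(n)]


def global_geary_naive(Wd, z):
    n = len(z)
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += Wd[i, j] * (z[i] - z[j]) ** 2
    return total / (2.0 * n)


def local_geary_naive(Wd, z):
    n = len(z)
    out = []
    for i in range(n):
        if all(Wd[i, j] == 0 for j in range(n)):
            out.append(float("nan"))
            continue
        out.append(sum(Wd[i, j] * (z[i] - z[j]) ** 2 for j in range(n)))
    return out


def general_g_naive(Wd, z):
    n = len(z)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num += Wd[i, j] * z[i] * z[j]
            den += z[i] * z[j]
    if abs(den) < 1e-12:
        return float("nan")
    return num / den


def gi_star_naive(Wd, z):
    """Self-included weights expected in Wd."""
    n = len(z)
    out = []
    for i in range(n):
        ssq = sum(Wd[i, j] ** 2 for j in range(n))
        bracket = (n * ssq - 1.0) / (n - 1)
        row = [Wd[i, j] for j in range(n)]
        offdiag = [row[j] for j in range(n) if j != i]
        if bracket <= 1e-12 or all(w == 0 for w in offdiag):
            out.append(float("nan"))
            continue
        lag = sum(Wd[i, j] * z[j] for j in range(n))
        out.append(lag / math.sqrt(bracket))
    return out


def gi_naive(Wd, z):
    """Self-excluded weights expected in Wd."""
    n = len(z)
    out = []
    for i in range(n):
        if all(Wd[i, j] == 0 for j in range(n)):
            out.append(float("nan"))
            continue
        others = [z[j] for j in range(n) if j != i]
        mean_excl = sum(others) / (n - 1)
        var_excl = sum((v - mean_excl) ** 2 for v in others) / (n - 1)
        sd_excl = math.sqrt(var_excl)
        wsum = sum(Wd[i, j] for j in range(n))
        ssq = sum(Wd[i, j] ** 2 for j in range(n))
        bracket = (n * ssq - wsum**2) / (n - 1)
        if sd_excl <= 1e-12 or bracket <= 1e-12:
            out.append(float("nan"))
            continue
        lag = sum(Wd[i, j] * z[j] for j in range(n))
        out.append((lag - mean_excl * wsum) / (sd_excl * math.sqrt(bracket)))
    return out


def assert_close(a, b, tol=1e-10):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    assert a.shape == b.shape
    both_nan = np.isnan(a) & np.isnan(b)
    diff = np.abs(a - b)
    diff[both_nan] = 0.0
    assert np.all(np.isnan(a) == np.isnan(b)), "undefined markers disagree"
    assert np.nanmax(diff) <= tol, f"max deviation {np.nanmax(diff)}"
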