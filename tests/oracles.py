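"""Independent enumeration oracles used by the test suite.

These deliberately avoid the package's numerical routes:

* Fisher oracle weights are exact integers from :func:`math.comb`
  (the package uses ``gammaln``); the two-sided p-value is an exact
  integer-arithmetic sum converted through :class:`fractions.Fraction`;
  tie comparisons are exact-integer comparisons implementing the
  ``mass <= observed * (1 + 1e-7)`` rule without any floating point.
* Conditional-MLE and CI roots are found by plain bisection on
  ``logsumexp``-based tail/mean evaluations (the package uses damped
  Newton / max-shift normalisation and different brackets).
* The enrichment oracle enumerates hypergeometric tail mass as exact
  fractions.
* The interval oracle is a brute-force scan.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy.special import logsumexp

# The tie guard 1 + 1e-7 as the exact rational value of the IEEE double,
# so guard comparisons are exact-integer arithmetic.
_G = Fraction(1 + 1e-7)


def _guard_leq(wx: int, wa: int) -> bool:
    """Exact-integer version of ``wx <= wa * (1 + 1e-7)``."""
    return wx * _G.denominator <= wa * _G.numerator


def enumerate_tables(n_max: int):
    """All (a, b, c, d) tables with a+b+c+d <= n_max, as an (m, 4) array."""
    rows = []
    for n in range(n_max + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    rows.append((a, b, c, n - a - b - c))
    return np.array(rows, dtype=np.int64)


def oracle_fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p via exact integer enumeration."""
    K, M, n = a + b, c + d, a + c
    lo, hi = max(0, n - M), min(K, n)
    if lo == hi:
        return 1.0
    weights = [math.comb(K, x) * math.comb(M, n - x) for x in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    num = sum(w for w in weights if _guard_leq(w, w_obs))
    return min(1.0, float(Fraction(num, sum(weights))))


def _oracle_support(a, b, c, d):
    K, M, n = a + b, c + d, a + c
    lo, hi = max(0, n - M), min(K, n)
    x = np.arange(lo, hi + 1)
    logw = np.array(
        [math.log(math.comb(K, xi) * math.comb(M, n - xi)) for xi in x]
    )
    return x, logw


def _bisect_root(f, lo: float, hi: float, iters: int = 120) -> float:
    """Plain bisection for f increasing through 0 on [lo, hi]."""
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def oracle_fisher_or_ci(a: int, b: int, c: int, d: int, alpha: float = 0.05):
    """Conditional-MLE OR and exact conditional CI via bisection on
    logsumexp-evaluated tails with exact comb weights."""
    x, logw = _oracle_support(a, b, c, d)
    if len(x) == 1:
        return math.nan, 0.0, math.inf
    i = a - x[0]
    half = alpha / 2

    def mean(t):
        z = logw + x * t
        return float((np.exp(z - logsumexp(z)) * x).sum())

    def upper_tail(t):
        z = logw + x * t
        return math.exp(logsumexp(z[i:]) - logsumexp(z))

    def lower_tail(t):
        z = logw + x * t
        return math.exp(logsumexp(z[: i + 1]) - logsumexp(z))

    if a == x[0]:
        or_est = 0.0
    elif a == x[-1]:
        or_est = math.inf
    else:
        or_est = math.exp(_bisect_root(lambda t: mean(t) - a, -90.0, 90.0))
    low = 0.0 if a == x[0] else math.exp(
        _bisect_root(lambda t: upper_tail(t) - half, -90.0, 90.0))
    high = math.inf if a == x[-1] else math.exp(
        _bisect_root(lambda t: half - lower_tail(t), -90.0, 90.0))
    return or_est, low, high


def oracle_fisher_batch(tables: np.ndarray, alpha: float = 0.05, chunk: int = 100_000):
    """Vectorised oracle over many tables.

    p-values are exact-integer sums shared per margin class; OR/CI roots
    come from global bisection over logsumexp-free normalised weights
    built from exact :func:`math.comb` integers.
    """
    tables = np.asarray(tables, dtype=np.int64)
    m = len(tables)
    out = {
        "p": np.empty(m),
        "oddsratio": np.empty(m),
        "ci_low": np.empty(m),
        "ci_high": np.empty(m),
    }

    # ---- exact-integer p-values, cached per margin class -----------------
    cache: dict[tuple[int, int, int], tuple[list[int], list[int], int]] = {}
    for idx in range(m):
        a, b, c, d = (int(v) for v in tables[idx])
        K, M, n = a + b, c + d, a + c
        key = (K, M, n)
        ent = cache.get(key)
        if ent is None:
            lo = max(0, n - M)
            hi = min(K, n)
            weights = [math.comb(K, x) * math.comb(M, n - x) for x in range(lo, hi + 1)]
            order = sorted(range(len(weights)), key=weights.__getitem__)
            ws = [weights[j] for j in order]
            prefix = [0]
            for w in ws:
                prefix.append(prefix[-1] + w)
            ent = (weights, ws, prefix)
            cache[key] = ent
        weights, ws, prefix = ent
        if len(weights) == 1:
            out["p"][idx] = 1.0
            continue
        lo = max(0, n - M)
        w_obs = weights[a - lo]
        # binary search: largest j with ws[j] <= w_obs * guard (exact ints)
        lo_j, hi_j = 0, len(ws)
        while lo_j < hi_j:
            mid = (lo_j + hi_j) // 2
            if _guard_leq(ws[mid], w_obs):
                lo_j = mid + 1
            else:
                hi_j = mid
        out["p"][idx] = min(1.0, float(Fraction(prefix[lo_j], prefix[-1])))

    # ---- OR and CI by global bisection with exact-comb weights ----------
    for s in range(0, m, chunk):
        block = tables[s: s + chunk]
        res = _oracle_roots_block(block, cache, alpha)
        for k in ("oddsratio", "ci_low", "ci_high"):
            out[k][s: s + len(block)] = res[k]
    return out


def _oracle_roots_block(tables: np.ndarray, cache, alpha: float):
    a = tables[:, 0]
    K = tables[:, 0] + tables[:, 1]
    M = tables[:, 2] + tables[:, 3]
    n = tables[:, 0] + tables[:, 2]
    lo = np.maximum(0, n - M)
    hi = np.minimum(K, n)
    width = int((hi - lo).max()) + 1 if len(tables) else 1
    x = lo[:, None] + np.arange(width)[None, :]
    valid = x <= hi[:, None]
    logw = np.full(x.shape, -np.inf)
    for i in range(len(tables)):
        weights = cache[(int(K[i]), int(M[i]), int(n[i]))][0]
        logw[i, : len(weights)] = np.log(np.array(weights, dtype=float))
    xc = np.where(valid, x, lo[:, None])
    half = alpha / 2
    ge_obs = x >= a[:, None]
    le_obs = x <= a[:, None]
    at_lo = a == lo
    at_hi = a == hi
    degenerate = lo == hi
    interior = ~(at_lo | at_hi)

    def masses(t):
        z = logw + xc * t[:, None]
        z -= z.max(axis=1, keepdims=True)
        w = np.exp(z)
        return w / w.sum(axis=1, keepdims=True)

    def solve(fvals_fn, active):
        lo_t = np.full(len(tables), -90.0)
        hi_t = np.full(len(tables), 90.0)
        for _ in range(80):
            mid = 0.5 * (lo_t + hi_t)
            below = fvals_fn(mid) < 0.0
            lo_t = np.where(active & below, mid, lo_t)
            hi_t = np.where(active & ~below, mid, hi_t)
        return 0.5 * (lo_t + hi_t)

    t_mle = solve(lambda t: (masses(t) * xc).sum(axis=1) - a, interior)
    or_est = np.where(interior, np.exp(t_mle), np.nan)
    or_est[at_lo & ~degenerate] = 0.0
    or_est[at_hi & ~degenerate] = np.inf

    t_low = solve(lambda t: (masses(t) * ge_obs).sum(axis=1) - half, ~at_lo & ~degenerate)
    ci_low = np.where(~at_lo & ~degenerate, np.exp(t_low), 0.0)

    t_high = solve(lambda t: half - (masses(t) * le_obs).sum(axis=1), ~at_hi & ~degenerate)
    ci_high = np.where(~at_hi & ~degenerate, np.exp(t_high), np.inf)
    return {"oddsratio": or_est, "ci_low": ci_low, "ci_high": ci_high}


def oracle_hypergeom_tail(k: int, n_universe: int, n_set: int, n_drawn: int) -> float:
    """P(X >= k) for X ~ Hypergeom(n_universe, n_set, n_drawn), exact."""
    total = math.comb(n_universe, n_drawn)
    num = sum(
        math.comb(n_set, x) * math.comb(n_universe - n_set, n_drawn - x)
        for x in range(k, min(n_set, n_drawn) + 1)
    )
    return float(Fraction(num, total))


def brute_force_overlaps(genes, chrom: str, start: int, end: int):
    """All gene ids overlapping [start, end) on chrom by linear scan."""
    return sorted(
        g.gene_id
        for g in genes
        if g.chrom == chrom and g.start < end and start < g.end
    )
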