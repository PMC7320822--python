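"""Independent brute-force oracles used to validate the implementation.

These deliberately take different computational routes from the package:
hat-matrix projections instead of reduced-model QR for the ANOVA, triple
loops for the TOM, direct hypergeometric summation for enrichment, and
numerical integration of the chi-square density for Fisher's combination.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, lgamma

import numpy as np
from scipy.integrate import quad

FACTORS = ("variety", "location", "stage")


def _onehot(labels) -> np.ndarray:
    labels = list(labels)
    levels = sorted(set(labels))
    out = np.zeros((len(labels), len(levels)))
    for i, l in enumerate(labels):
        out[i, levels.index(l)] = 1.0
    return out


def _hat(M: np.ndarray) -> np.ndarray:
    return M @ np.linalg.pinv(M)


def anova_oracle(y: np.ndarray, design_table) -> dict[str, tuple[float, int]]:
    """Classical balanced-design ANOVA via projection (hat) matrices.

    For each term, the projection is the hat matrix of the span including the
    term minus the hat matrix of the span of all lower-order terms; on
    balanced designs this is the classical orthogonal decomposition.
    Returns {term: (SS, df)} including the residual.
    """
    n = len(y)
    ones = np.ones((n, 1))
    main = {f: _onehot(design_table[f]) for f in FACTORS}

    def interaction(fs):
        labels = list(zip(*(design_table[f] for f in fs)))
        return _onehot([str(t) for t in labels])

    spans = {(): ones}
    for r in (1, 2, 3):
        for fs in combinations(FACTORS, r):
            spans[fs] = interaction(fs) if r > 1 else main[fs[0]]

    def span_matrix(term_sets):
        return np.hstack([spans[t] for t in [()] + list(term_sets)])

    all_terms = [fs for r in (1, 2, 3) for fs in combinations(FACTORS, r)]
    result: dict[str, tuple[float, int]] = {}
    for fs in all_terms:
        lower = [g for g in all_terms if set(g) < set(fs)]
        with_term = span_matrix(lower + [fs])
        without = span_matrix(lower)
        P = _hat(with_term) - _hat(without)
        ss = float(y @ P @ y)
        df = int(np.prod([len(set(design_table[f])) - 1 for f in fs]))
        result[":".join(fs)] = (ss, df)
    full = span_matrix(all_terms)
    resid = y - _hat(full) @ y
    df_res = n - int(round(np.trace(_hat(full))))
    result["residual"] = (float(resid @ resid), df_res)
    return result


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Topological overlap by explicit triple loops (unit-diagonal adjacency)."""
    n = a.shape[0]
    k = a.sum(axis=1) - 1.0
    t = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            t[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return t


def hypergeom_tail_oracle(k: int, n_universe: int, n_set: int, n_selected: int) -> float:
    """P(overlap >= k) by direct summation of the hypergeometric pmf."""
    total = comb(n_universe, n_selected)
    upper = min(n_set, n_selected)
    return sum(
        comb(n_set, x) * comb(n_universe - n_set, n_selected - x) for x in range(k, upper + 1)
    ) / total


def chi2_sf_oracle(x: float, df: int) -> float:
    """Chi-square upper tail by numerical integration of the density."""
    half = df / 2.0
    lognorm = half * np.log(2.0) + lgamma(half)

    def dens(t):
        return np.exp((half - 1.0) * np.log(t) - t / 2.0 - lognorm)

    val, _ = quad(dens, x, np.inf, limit=200)
    return val


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Step-up BH by the textbook formula: adj_(i) = min_{j>=i} p_(j) m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj_sorted, 0.0, 1.0)
    return out
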