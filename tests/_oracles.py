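"""Independent brute-force oracles used to check the implementation.

Everything here is written from the definitions in plain Python (loops,
enumeration, exact rational arithmetic) and deliberately shares no code
with the package.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def bf_neighborhood(values, k, box_fraction):
    """All cells within the distance of the n-th nearest to cell k."""
    m = len(values)
    n = max(1, math.floor(box_fraction * m))
    dists = [abs(values[j] - values[k]) for j in range(m)]
    radius = sorted(dists)[n - 1]
    return {j for j in range(m) if dists[j] <= radius}


def bf_counts(u_values, v_values, k, box_fraction):
    """(m, m_u, m_v, m_uv) by direct set construction."""
    nu = bf_neighborhood(u_values, k, box_fraction)
    nv = bf_neighborhood(v_values, k, box_fraction)
    return len(u_values), len(nu), len(nv), len(nu & nv)


def closed_form_rho_hat(m, m_u, m_v, m_uv):
    """sqrt(m-1) (m m_uv - m_u m_v) / sqrt(m_u m_v (m-m_u) (m-m_v))."""
    return (
        math.sqrt(m - 1)
        * (m * m_uv - m_u * m_v)
        / math.sqrt(m_u * m_v * (m - m_u) * (m - m_v))
    )


def hypergeom_upper_tail(N, S, M, r):
    """P(X >= r) by exact rational enumeration of the pmf."""
    denom = math.comb(N, M)
    total = Fraction(0)
    for t in range(r, min(S, M) + 1):
        total += Fraction(math.comb(S, t) * math.comb(N - S, M - t), denom)
    return float(total)


def bh_stepup(p_values):
    """Benjamini-Hochberg adjusted p-values, hand-rolled step-up."""
    n = len(p_values)
    order = sorted(range(n), key=lambda i: p_values[i])
    adj = [0.0] * n
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p_values[i] * n / rank_from_top)
        adj[i] = running_min
    return adj


def _ks_distance(a, b):
    points = sorted(set(a) | set(b))
    d = 0.0
    for x in points:
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        d = max(d, abs(fa - fb))
    return d


def ks_exact_pvalue(a, b):
    """Exact two-sided KS p by enumerating all label assignments.

    Under the null the pooled values are exchangeable; p is the fraction
    of the C(n_a + n_b, n_a) splits with D at least the observed D.
    """
    observed = _ks_distance(a, b)
    pooled = list(a) + list(b)
    n_a = len(a)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        grp_a = [pooled[i] for i in idx]
        grp_b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if _ks_distance(grp_a, grp_b) >= observed - 1e-12:
            count += 1
    return count / total
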