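"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the dip oracle solves
a linear program over unimodal CDFs, the Kendall oracle counts pairs and
enumerates permutations, and the Fisher oracle enumerates every 2x2 table
with the observed margins.
"""

import itertools
import math

import numpy as np
from scipy.optimize import linprog

_BIG = 1e7


def dip_lp_oracle(sample) -> float:
    """Minimal sup-distance between the ECDF and a unimodal CDF.

    A unimodal CDF is convex left of its mode and concave right of it,
    with at most one atom (at the mode).  For the minimising G the mode can
    be taken at a data point, so we solve one LP per candidate mode k:
    variables are G at each data point plus the left limit h at x_k (the
    atom), the objective is the band half-width d.
    """
    x = np.sort(np.asarray(sample, float))
    n = len(x)
    assert len(np.unique(x)) == n, "oracle assumes distinct values"
    best = np.inf
    for k in range(n):  # mode (possible atom) at x_k
        nv = n + 2          # g_0..g_{n-1}, h, d
        hi, di = n, n + 1
        A, b = [], []

        def le(coefs, rhs):
            row = np.zeros(nv)
            for i, c in coefs:
                row[i] += c
            A.append(row)
            b.append(rhs)

        for j in range(n):
            Fj = (j + 1) / n
            Fjm = j / n
            if j == k:
                le([(j, 1), (di, -1)], Fj)      # g_k <= F(x_k) + d
                le([(j, -1), (di, -1)], -Fj)    # g_k >= F(x_k) - d
                le([(hi, 1), (di, -1)], Fjm)    # h within the left-limit band
                le([(hi, -1), (di, -1)], -Fjm)
            else:
                le([(j, 1), (di, -1)], Fjm)     # g_j <= F(x_j^-) + d
                le([(j, -1), (di, -1)], -Fj)    # g_j >= F(x_j) - d
        le([(0, -1)], 0.0)
        le([(n - 1, 1)], 1.0)
        le([(hi, -1)], 0.0)
        # monotone, with h spliced in at position k
        for j in range(n - 1):
            if j == k - 1:
                le([(j, 1), (hi, -1)], 0.0)
            else:
                le([(j, 1), (j + 1, -1)], 0.0)
        le([(hi, 1), (k, -1)], 0.0)

        def var(j):
            return hi if j == k else j

        # convex chain over points 0..k (h at k), led in from (x_0-BIG, 0)
        left = list(range(k + 1))
        xs = [x[0] - _BIG] + [x[j] for j in left]
        ids = [None] + left
        for a in range(len(xs) - 2):
            d1 = xs[a + 1] - xs[a]
            d2 = xs[a + 2] - xs[a + 1]
            coefs = []
            if ids[a] is not None:
                coefs.append((var(ids[a]), -1 / d1))
            coefs.append((var(ids[a + 1]), 1 / d1 + 1 / d2))
            coefs.append((var(ids[a + 2]), -1 / d2))
            le(coefs, 0.0)
        # concave chain over points k..n-1 (g_k at k), led out to (x_n-1+BIG, 1)
        right = list(range(k, n))
        xs = [x[j] for j in right] + [x[-1] + _BIG]
        ids = right + [None]
        for a in range(len(xs) - 2):
            d1 = xs[a + 1] - xs[a]
            d2 = xs[a + 2] - xs[a + 1]
            coefs = [(ids[a], 1 / d1)]
            rhs = 0.0
            if ids[a + 1] is None:
                rhs += (1 / d1 + 1 / d2)
            else:
                coefs.append((ids[a + 1], -(1 / d1) - (1 / d2)))
            if ids[a + 2] is None:
                rhs -= 1 / d2
            elif a + 2 < len(ids):
                coefs.append((ids[a + 2], 1 / d2))
            le(coefs, rhs)
        c = np.zeros(nv)
        c[di] = 1.0
        res = linprog(c, A_ub=np.array(A), b_ub=np.array(b),
                      bounds=[(None, None)] * nv, method="highs")
        if res.status == 0:
            best = min(best, res.fun)
    return float(best)


def kendall_tau_b_bruteforce(x, y) -> float:
    """tau-b by explicit O(n^2) concordant/discordant pair counting."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[j] - x[i])
            dy = np.sign(y[j] - y[i])
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx == dy:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    if denom == 0:
        return float("nan")
    return (conc - disc) / denom


def _tie_term(v):
    _, counts = np.unique(v, return_counts=True)
    return sum(c * (c - 1) / 2 for c in counts)


def kendall_exact_p_enumeration(x, y) -> float:
    """Two-sided exact p by enumerating every permutation of y (no ties)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    t_obs = abs(kendall_tau_b_bruteforce(x, y))
    count = total = 0
    for perm in itertools.permutations(y):
        t = abs(kendall_tau_b_bruteforce(x, np.array(perm)))
        count += (t >= t_obs - 1e-12)
        total += 1
    return count / total


def _hypergeom_table_prob(a, b, c, d):
    """P of the 2x2 table under fixed margins (hypergeometric)."""
    return math.exp(
        _lchoose(a + b, a) + _lchoose(c + d, c) - _lchoose(a + b + c + d, a + c))


def _lchoose(n, k):
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_enumeration_oracle(a, b, c, d, alternative="two-sided") -> float:
    """Fisher p by exhaustive enumeration over tables with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    p_obs = _hypergeom_table_prob(a, b, c, d)
    p = 0.0
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        bb, cc, dd = r1 - aa, c1 - aa, r2 - (c1 - aa)
        if min(bb, cc, dd) < 0:
            continue
        pt = _hypergeom_table_prob(aa, bb, cc, dd)
        if alternative == "two-sided":
            if pt <= p_obs * (1 + 1e-9):
                p += pt
        elif alternative == "greater":
            if aa >= a:
                p += pt
        elif alternative == "less":
            if aa <= a:
                p += pt
        else:
            raise ValueError(alternative)
    return min(1.0, p)
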