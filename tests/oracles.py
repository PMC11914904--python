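"""Independent brute-force oracles used by the test suite.

Every function here recomputes a quantity by exhaustive enumeration or a
closed form, deliberately sharing no code with the package's own
implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# linear programming: basic-feasible-solution enumeration


def lp_max_oracle(S: np.ndarray, lower: np.ndarray, upper: np.ndarray,
                  c: np.ndarray, tol: float = 1e-7) -> float | None:
    """Maximum of c.v over {v : S v = 0, lower <= v <= upper} by
    enumerating vertices (n - rank(S) active bounds, remaining variables
    solved from the equalities).  Returns None when infeasible.  Assumes
    finite bounds, so the optimum (if feasible) is attained at a vertex.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    n = S.shape[1]
    r = np.linalg.matrix_rank(S) if S.size else 0
    k = n - r  # number of bounds to activate
    best = None
    for fixed_vars_t in itertools.combinations(range(n), k):
        fixed_vars = list(fixed_vars_t)
        free_vars = [j for j in range(n) if j not in fixed_vars]
        A_free = S[:, free_vars]
        for bounds_choice in itertools.product((0, 1), repeat=k):
            v = np.zeros(n)
            for j, side in zip(fixed_vars, bounds_choice):
                v[j] = lower[j] if side == 0 else upper[j]
            b = -S[:, fixed_vars] @ v[fixed_vars] if k else np.zeros(S.shape[0])
            if free_vars:
                sol, *_ = np.linalg.lstsq(A_free, b, rcond=None)
                v[free_vars] = sol
            if np.max(np.abs(S @ v)) > tol:
                continue
            if np.any(v < lower - tol) or np.any(v > upper + tol):
                continue
            val = float(c @ v)
            if best is None or val > best:
                best = val
    return best


# ---------------------------------------------------------------------------
# alignment enumeration


def local_align_oracle(a: str, b: str, submat: dict[tuple[str, str], int],
                       gap_open: int = 11, gap_extend: int = 1) -> int:
    """Optimal local alignment score by enumerating every monotone set of
    aligned columns; unaligned residues strictly between consecutive
    columns form affine gaps (open + L*extend each).  Score floor 0."""
    na, nb = len(a), len(b)
    best = 0

    def gap_cost(d: int) -> int:
        return gap_open + d * gap_extend if d > 0 else 0

    for k in range(1, min(na, nb) + 1):
        for ai in itertools.combinations(range(na), k):
            for bi in itertools.combinations(range(nb), k):
                score = 0
                for t in range(k):
                    score += submat[(a[ai[t]], b[bi[t]])]
                    if t:
                        score -= gap_cost(ai[t] - ai[t - 1] - 1)
                        score -= gap_cost(bi[t] - bi[t - 1] - 1)
                if score > best:
                    best = score
    return best


def semiglobal_align_oracle(q: str, r: str) -> int:
    """Best semi-global score (query fully aligned, free reference end
    gaps) with match +1 / mismatch -1 / gap -2 (linear), by enumerating
    monotone matchings of query positions onto reference positions;
    unmatched query residues and skipped internal reference residues
    each cost -2."""
    nq, nr = len(q), len(r)
    best = -2 * nq  # query entirely gapped
    for k in range(1, min(nq, nr) + 1):
        for qi in itertools.combinations(range(nq), k):
            for ri in itertools.combinations(range(nr), k):
                score = 0
                for t in range(k):
                    score += 1 if q[qi[t]] == r[ri[t]] else -1
                    if t:
                        score -= 2 * (qi[t] - qi[t - 1] - 1)
                        score -= 2 * (ri[t] - ri[t - 1] - 1)
                score -= 2 * (qi[0] + (nq - 1 - qi[-1]))  # unmatched query ends
                if score > best:
                    best = score
    return best


# ---------------------------------------------------------------------------
# exact rank-test p-values


def rank_sum_exact_p(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group labelings
    (midranks for ties; deviation of U from its null mean)."""
    a, b = list(a), list(b)
    pooled = a + b
    n, na = len(pooled), len(a)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        midrank = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = midrank
        i = j + 1

    def u_of(idx: tuple[int, ...]) -> float:
        r1 = sum(ranks[i] for i in idx)
        return r1 - na * (na + 1) / 2

    mean_u = na * (n - na) / 2
    obs = abs(u_of(tuple(range(na))) - mean_u)
    count = total = 0
    for idx in itertools.combinations(range(n), na):
        count += abs(u_of(idx) - mean_u) >= obs - 1e-12
        total += 1
    return count / total


def signed_rank_exact_p(diffs) -> float:
    """Two-sided exact Wilcoxon signed-rank p by enumerating all 2^n sign
    assignments of the nonzero differences (midranks of |d|)."""
    d = [x for x in diffs if x != 0]
    n = len(d)
    mags = [abs(x) for x in d]
    order = sorted(range(n), key=lambda i: mags[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and mags[order[j + 1]] == mags[order[i]]:
            j += 1
        midrank = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = midrank
        i = j + 1
    mean_w = n * (n + 1) / 4
    w_obs = sum(r for x, r in zip(d, ranks) if x > 0)
    obs = abs(w_obs - mean_w)
    count = total = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        count += abs(w - mean_w) >= obs - 1e-12
        total += 1
    return count / total


def kendall_tau_b_oracle(x, y) -> float:
    """tau-b by direct concordant/discordant pair counting."""
    x, y = list(x), list(y)
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = (x[i] > x[j]) - (x[i] < x[j])
            dy = (y[i] > y[j]) - (y[i] < y[j])
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
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - sum_tie_term(x)) * (n0 - sum_tie_term(y)))
    return (conc - disc) / denom


def sum_tie_term(v) -> float:
    from collections import Counter

    return sum(t * (t - 1) // 2 for t in Counter(v).values())


def bh_oracle(p) -> list[float]:
    """Step-up BH adjustment by the textbook definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


# ---------------------------------------------------------------------------
# PERMANOVA by definition


def permanova_f_oracle(D: np.ndarray, labels) -> tuple[float, float]:
    """(pseudo-F, R^2) from the sums-of-squares definition."""
    labels = np.asarray(labels)
    n = len(labels)
    D2 = np.asarray(D, dtype=float) ** 2
    ss_total = sum(D2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in set(labels.tolist()):
        idx = [i for i in range(n) if labels[i] == g]
        ss_within += sum(
            D2[i, j] for i in idx for j in idx if i < j
        ) / len(idx)
    a = len(set(labels.tolist()))
    ss_among = ss_total - ss_within
    f = (ss_among / (a - 1)) / (ss_within / (n - a))
    return f, ss_among / ss_total


def permanova_exact_p_oracle(D: np.ndarray, labels) -> float:
    """Exact p over all distinct label arrangements (observed included)."""
    from sympy.utilities.iterables import multiset_permutations

    f_obs, _ = permanova_f_oracle(D, labels)
    count = total = 0
    for lab in multiset_permutations(list(labels)):
        f, _ = permanova_f_oracle(D, lab)
        count += f >= f_obs - 1e-12
        total += 1
    return count / total
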