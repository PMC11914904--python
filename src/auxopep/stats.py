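"""Statistical layer: rank correlations, rank-sum/signed-rank tests,
Benjamini-Hochberg FDR, PCoA, PERMANOVA and the differential-peptidase
screen.

Exact null distributions are used where small sample sizes permit
(enumeration of labelings, sign flips or label arrangements); otherwise
tie-corrected normal approximations with continuity correction.  All
permutation procedures are deterministic under a caller-supplied seed and
use the add-one convention p = (1 + #{T_perm >= T_obs}) / (1 + n_perm),
so a Monte-Carlo p-value is never exactly zero.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    effect_label: str = ""
    effect: float | None = None
    note: str = ""  # 'degenerate' when the statistic is undefined


# ---------------------------------------------------------------------------
# rank correlation with an ordered factor


def _kendall_numerator(x: np.ndarray, y: np.ndarray) -> int:
    s = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            s += int(np.sign(x[j] - x[i]) * np.sign(y[j] - y[i]))
    return s


def kendall_ordered(values, region_rank) -> TestResult:
    """Kendall tau-b between a metric and an ordered factor (e.g. gut
    region coded 1-4), with tie correction.

    Two-sided p by exhaustive permutation of the value vector when
    n <= 8, else the tie-corrected normal approximation.
    """
    x = np.asarray(values, dtype=float)
    r = np.asarray(region_rank, dtype=float)
    if len(x) != len(r) or len(x) < 3:
        raise InputError("kendall_ordered needs equal-length vectors, n >= 3")
    if len(np.unique(r)) < 2:
        raise InputError("ordered factor must have at least 2 distinct levels")
    if len(np.unique(x)) < 2:
        return TestResult(float("nan"), float("nan"), effect_label="tau",
                          note="degenerate: constant values")
    n = len(x)
    tau, p_approx = sps.kendalltau(r, x, variant="b")
    if n <= 8:
        s_obs = abs(_kendall_numerator(r, x))
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            s = abs(_kendall_numerator(r, x[list(perm)]))
            count += s >= s_obs
            total += 1
        p = count / total
    else:
        p = float(p_approx)
    return TestResult(float(tau), float(p), effect_label="tau", effect=float(tau))


# ---------------------------------------------------------------------------
# rank-sum and signed-rank tests


def wilcoxon_rank_sum(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test: exact by enumeration when
    n_a + n_b <= 12 with no ties, else tie-corrected normal approximation
    with continuity correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InputError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return TestResult(float(res.statistic), float(res.pvalue), effect_label="U")


def wilcoxon_signed_rank(paired_diffs) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences; zero
    differences are dropped first.  Exact sign-flip enumeration when the
    remaining n <= 12 without tied magnitudes, else normal approximation
    with continuity correction.  All-zero differences give p = 1,
    flagged degenerate."""
    d = np.asarray(paired_diffs, dtype=float)
    if d.size == 0:
        raise InputError("empty difference vector")
    nz = d[d != 0]
    if nz.size == 0:
        return TestResult(0.0, 1.0, effect_label="W",
                          note="degenerate: all differences zero")
    no_ties = len(np.unique(np.abs(nz))) == len(nz)
    method = "exact" if (len(nz) <= 12 and no_ties) else "approx"
    res = sps.wilcoxon(nz, alternative="two-sided", method=method,
                       correction=True, zero_method="wilcox")
    return TestResult(float(res.statistic), float(res.pvalue), effect_label="W")


# ---------------------------------------------------------------------------
# multiple testing


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order
    preserved, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


# ---------------------------------------------------------------------------
# correlation matrix between auxotrophy and peptidase abundances


def spearman_matrix(aux_abund: pd.DataFrame, pep_abund: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho for every (amino acid, peptidase) pair of per-sample
    abundance columns, with BH adjustment computed jointly across the
    whole matrix.

    Returns a tidy frame: amino_acid, merops_id, rho, p_value,
    p_adjusted, note ('degenerate' for constant columns).
    """
    shared = aux_abund.index.intersection(pep_abund.index)
    if len(shared) < 4:
        raise InputError("spearman_matrix needs >= 4 shared samples")
    A = aux_abund.loc[shared]
    P = pep_abund.loc[shared]
    rows = []
    for aa in A.columns:
        xa = A[aa].to_numpy(dtype=float)
        for mid in P.columns:
            yp = P[mid].to_numpy(dtype=float)
            if len(np.unique(xa)) < 2 or len(np.unique(yp)) < 2:
                rows.append((aa, mid, np.nan, np.nan, "degenerate"))
                continue
            rho, p = sps.spearmanr(xa, yp)
            rows.append((aa, mid, float(rho), float(p), ""))
    df = pd.DataFrame(rows, columns=["amino_acid", "merops_id", "rho", "p_value", "note"])
    df["p_adjusted"] = np.nan
    ok = df["p_value"].notna()
    if ok.any():
        df.loc[ok, "p_adjusted"] = bh_fdr(df.loc[ok, "p_value"].to_numpy())
    return df[["amino_acid", "merops_id", "rho", "p_value", "p_adjusted", "note"]]


# ---------------------------------------------------------------------------
# ordination and PERMANOVA


def _check_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise InputError("distance matrix must be square")
    if np.max(np.abs(D - D.T)) > 1e-9:
        raise InputError("distance matrix must be symmetric (tolerance 1e-9)")
    if np.max(np.abs(np.diag(D))) > 1e-9:
        raise InputError("distance matrix must have a zero diagonal")
    return D


def pcoa(distance_matrix) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinate analysis by double-centering of -D^2/2.

    Returns (coordinates, eigenvalues): coordinates span the
    positive-eigenvalue axes sorted by decreasing eigenvalue; the full
    eigenvalue spectrum (negatives included, uncorrected) is returned
    alongside.
    """
    D = _check_distance_matrix(distance_matrix)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    pos = eigvals > 1e-12 * max(1.0, abs(eigvals[0]))
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    return coords, eigvals


def _permanova_ss(D2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and group labels."""
    n = D2.shape[0]
    ss_total = D2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = D2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total, ss_within


def _count_arrangements(counts: list[int]) -> int:
    total = math.factorial(sum(counts))
    for c in counts:
        total //= math.factorial(c)
    return total


def permanova(distance_matrix, groups, n_perm: int = 999, seed: int = 0) -> TestResult:
    """One-way PERMANOVA on a distance matrix.

    Pseudo-F from the distance-based sums of squares; p-value by free
    permutation of sample labels with the add-one convention, or by full
    enumeration of distinct label arrangements when there are at most
    10,000 of them (then the observed arrangement is part of the null
    set).  Effect size R^2 = SS_among / SS_total.
    """
    D = _check_distance_matrix(distance_matrix)
    labels = np.asarray(groups)
    if len(labels) != D.shape[0]:
        raise InputError("group labels must match the distance matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise InputError("PERMANOVA needs at least 2 groups")
    if counts.min() < 2:
        raise InputError("every group needs n >= 2 (within-group SS undefined)")
    a = len(uniq)
    n = len(labels)
    D2 = D ** 2
    ss_total, ss_within = _permanova_ss(D2, labels)
    ss_among = ss_total - ss_within
    if ss_within <= 1e-300:
        f_obs = np.inf
    else:
        f_obs = (ss_among / (a - 1)) / (ss_within / (n - a))
    r2 = ss_among / ss_total if ss_total > 0 else 0.0

    def f_of(lab: np.ndarray) -> float:
        st, sw = _permanova_ss(D2, lab)
        if sw <= 1e-300:
            return np.inf
        return ((st - sw) / (a - 1)) / (sw / (n - a))

    eps = 1e-12
    n_arrangements = _count_arrangements(list(counts))
    if n_arrangements <= 10_000:
        from sympy.utilities.iterables import multiset_permutations

        count = 0
        for lab in multiset_permutations(list(labels)):
            count += f_of(np.asarray(lab)) >= f_obs - eps
        p = count / n_arrangements
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            count += f_of(rng.permutation(labels)) >= f_obs - eps
        p = (1 + count) / (1 + n_perm)
    return TestResult(float(f_obs), float(p), effect_label="R2", effect=float(r2))


# ---------------------------------------------------------------------------
# differential peptidase screen


def differential_peptidase_screen(
    pep_abund_group_a: pd.DataFrame,
    pep_abund_group_b: pd.DataFrame,
    paired: bool = False,
    min_median_pct: float = 1.0,
    alpha: float = 0.001,
    adjust: bool = True,
) -> pd.DataFrame:
    """Screen peptidases for differential abundance between two sample
    groups.

    Peptidases are retained when their median relative abundance reaches
    *min_median_pct* percent in either group (or both); each retained
    peptidase is tested with the signed-rank test (paired mode, matched
    sample identifiers required) or the rank-sum test, p-values are
    BH-adjusted, and significance is flagged at adjusted p < *alpha*
    (raw p when ``adjust=False``).  Direction is the sign of the median
    difference (A - B).
    """
    shared_cols = pep_abund_group_a.columns.intersection(pep_abund_group_b.columns)
    thr = min_median_pct / 100.0
    A = pep_abund_group_a[shared_cols].dropna(how="all")
    B = pep_abund_group_b[shared_cols].dropna(how="all")
    if paired:
        matched = A.index.intersection(B.index)
        if len(matched) == 0:
            raise InputError("paired mode requires matched sample identifiers")
        A, B = A.loc[matched], B.loc[matched]
    rows = []
    for mid in shared_cols:
        xa = A[mid].to_numpy(dtype=float)
        xb = B[mid].to_numpy(dtype=float)
        med_a, med_b = float(np.median(xa)), float(np.median(xb))
        if med_a < thr and med_b < thr:
            continue
        if paired:
            res = wilcoxon_signed_rank(xa - xb)
        else:
            res = wilcoxon_rank_sum(xa, xb)
        direction = "up_in_A" if med_a > med_b else ("up_in_B" if med_b > med_a else "none")
        rows.append((mid, res.statistic, res.p_value, med_a, med_b, direction))
    if not rows:
        logger.warning("differential screen: no peptidase passed the "
                       "%g%%-median prevalence filter", min_median_pct)
        return pd.DataFrame(
            columns=["merops_id", "statistic", "p_value", "p_adjusted",
                     "median_A", "median_B", "direction", "significant"]
        )
    df = pd.DataFrame(rows, columns=["merops_id", "statistic", "p_value",
                                     "median_A", "median_B", "direction"])
    df["p_adjusted"] = bh_fdr(df["p_value"].to_numpy())
    df["significant"] = (df["p_adjusted"] if adjust else df["p_value"]) < alpha
    return df[["merops_id", "statistic", "p_value", "p_adjusted",
               "median_A", "median_B", "direction", "significant"]]
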