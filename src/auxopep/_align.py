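"""Dynamic-programming alignment kernels (numba-compiled).

Two scoring schemes are used by the pipeline:

* semi-global nucleotide alignment for ASV-to-16S mapping: the ASV (query)
  is aligned end-to-end, end gaps on the reference are free; match +1,
  mismatch -1, gap -2 (linear).
* local protein alignment with affine gaps (Gotoh) under BLOSUM62 for the
  peptidase homology scan: gap of length L costs open + L*extend
  (BLAST convention, default 11 + L); pairs involving X score 0.

Both kernels are deterministic: ties are broken in a fixed order
(diagonal > up > left).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# --- alphabets -------------------------------------------------------------

_NT_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
# IUPAC ambiguity codes: never match anything (scored as mismatch)
_NT_AMBIG = set("RYSWKMBDHVN")

_AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_CODE = {c: i for i, c in enumerate(_AA_ALPHABET)}


def encode_nt(seq: str) -> np.ndarray:
    """Encode a nucleotide sequence; ambiguity codes get unique codes >= 4
    so they never match.  Raises ValueError on non-IUPAC characters."""
    out = np.empty(len(seq), dtype=np.int8)
    for i, c in enumerate(seq):
        if c in _NT_CODE:
            out[i] = _NT_CODE[c]
        elif c in _NT_AMBIG:
            out[i] = 4
        else:
            raise ValueError(f"non-IUPAC nucleotide character {c!r} at position {i}")
    return out


def encode_aa(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int8)
    for i, c in enumerate(seq):
        code = _AA_CODE.get(c)
        if code is None:
            raise ValueError(f"unknown amino-acid character {c!r} at position {i}")
        out[i] = code
    return out


_REVCOMP = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 over :data:`_AA_ALPHABET`, with any pair involving X
    (or the stop symbol) overridden to 0."""
    from Bio.Align import substitution_matrices

    bl = substitution_matrices.load("BLOSUM62")
    n = len(_AA_ALPHABET)
    mat = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(_AA_ALPHABET):
        for j, b in enumerate(_AA_ALPHABET):
            if a in ("X", "*") or b in ("X", "*"):
                mat[i, j] = 0
            else:
                mat[i, j] = int(bl[a, b])
    return mat


_BLOSUM62: np.ndarray | None = None


def get_blosum62() -> np.ndarray:
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = blosum62_matrix()
    return _BLOSUM62


# --- semi-global nucleotide alignment --------------------------------------


@njit(cache=False)
def semiglobal_nt_kernel(q, r):  # pragma: no cover - compiled
    """Align query *q* end-to-end against reference *r* with free end gaps
    on the reference.  Returns (score, matches, diag_cols, total_cols):
    matches = identical aligned pairs, diag_cols = query positions aligned
    to a reference base, total_cols = alignment columns spanning the query
    (diagonal moves plus internal gap columns)."""
    n = q.shape[0]
    m = r.shape[0]
    NEG = -1_000_000
    H = np.empty((n + 1, m + 1), dtype=np.int32)
    P = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 start, 1 diag, 2 up, 3 left
    for j in range(m + 1):
        H[0, j] = 0
    for i in range(1, n + 1):
        H[i, 0] = -2 * i
        P[i, 0] = 2
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            s = 1 if (qi == r[j - 1] and qi < 4) else -1
            best = H[i - 1, j - 1] + s
            ptr = 1
            up = H[i - 1, j] - 2
            if up > best:
                best = up
                ptr = 2
            left = H[i, j - 1] - 2
            if left > best:
                best = left
                ptr = 3
            H[i, j] = best
            P[i, j] = ptr
    # free trailing reference gap: best cell in last row
    jend = 0
    score = NEG
    for j in range(m + 1):
        if H[n, j] > score:
            score = H[n, j]
            jend = j
    # traceback
    i = n
    j = jend
    matches = 0
    diag_cols = 0
    total_cols = 0
    while i > 0:
        ptr = P[i, j]
        if ptr == 1:
            if q[i - 1] == r[j - 1] and q[i - 1] < 4:
                matches += 1
            diag_cols += 1
            total_cols += 1
            i -= 1
            j -= 1
        elif ptr == 2:
            total_cols += 1
            i -= 1
        else:
            total_cols += 1
            j -= 1
    return score, matches, diag_cols, total_cols


def semiglobal_identity(query: np.ndarray, ref: np.ndarray) -> tuple[float, float, int]:
    """Percent identity and query coverage of the best semi-global alignment.

    Returns (identity_pct, query_coverage_pct, score); identity is
    matches over alignment columns spanning the query, coverage the
    fraction of query positions aligned to a reference base.
    """
    score, matches, diag_cols, total_cols = semiglobal_nt_kernel(query, ref)
    if total_cols == 0:
        return 0.0, 0.0, int(score)
    identity = 100.0 * matches / total_cols
    coverage = 100.0 * diag_cols / query.shape[0]
    return identity, coverage, int(score)


# --- local affine-gap protein alignment (Gotoh) -----------------------------


@njit(cache=False)
def local_affine_kernel(a, b, submat, gap_open, gap_extend):  # pragma: no cover
    """Optimal local alignment score with affine gaps; a gap of length L
    costs gap_open + L*gap_extend.  Returns (score, a_start, a_end,
    b_start, b_end) with 1-based inclusive spans; zero score gives empty
    spans (0, 0, 0, 0)."""
    n = a.shape[0]
    m = b.shape[0]
    NEG = -1_000_000
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in b (vertical)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in a (horizontal)
    best = 0
    bi = 0
    bj = 0
    go_ge = gap_open + gap_extend
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = H[i - 1, j] - go_ge
            if E[i - 1, j] - gap_extend > e:
                e = E[i - 1, j] - gap_extend
            E[i, j] = e
            f = H[i, j - 1] - go_ge
            if F[i, j - 1] - gap_extend > f:
                f = F[i, j - 1] - gap_extend
            F[i, j] = f
            h = H[i - 1, j - 1] + submat[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    if best == 0:
        return 0, 0, 0, 0, 0
    # traceback from (bi, bj) in state H until a zero cell
    i = bi
    j = bj
    state = 0  # 0 = H, 1 = E, 2 = F
    while True:
        if state == 0:
            if H[i, j] == 0:
                break
            if H[i, j] == H[i - 1, j - 1] + submat[a[i - 1], b[j - 1]]:
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            if E[i, j] == H[i - 1, j] - go_ge:
                i -= 1
                state = 0
            else:
                i -= 1
        else:
            if F[i, j] == H[i, j - 1] - go_ge:
                j -= 1
                state = 0
            else:
                j -= 1
    return best, i + 1, bi, j + 1, bj


def warm_up() -> None:
    """Trigger numba compilation of both kernels on tiny inputs."""
    semiglobal_nt_kernel(encode_nt("ACGT"), encode_nt("ACGT"))
    local_affine_kernel(encode_aa("AR"), encode_aa("AR"), get_blosum62(), 11, 1)
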