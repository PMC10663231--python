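"""Global protein alignment with affine gaps (Gotoh algorithm).

Used by the engine-free phylogeny path to turn sequence pairs into
p-distances. Co-optimal alignments can disagree on identity count and on
alignment length, so the optimum is made unique by a lexicographic
objective: maximize score, then maximize identities, then minimize aligned
columns. All three are additive per column, which lets the DP run on a
single packed integer ``score*K^2 + identities*K + substitution_columns``
with ``K`` larger than any attainable count.

Gap cost convention: a gap of length L costs ``gap_open + (L-1)*gap_extend``.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

NEG = -(2**62)


@lru_cache(maxsize=None)
def _blosum62_lookup() -> np.ndarray:
    """26x26 integer score lookup over A..Z; letters unknown to BLOSUM62 map
    onto the X row."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    alphabet = mat.alphabet
    lookup = np.zeros((26, 26), dtype=np.int64)
    x_idx = alphabet.index("X")
    for i in range(26):
        ci = chr(ord("A") + i)
        ai = alphabet.index(ci) if ci in alphabet else x_idx
        for j in range(26):
            cj = chr(ord("A") + j)
            aj = alphabet.index(cj) if cj in alphabet else x_idx
            lookup[i, j] = int(mat[ai, aj])
    return lookup


def _score_lookup(matrix) -> np.ndarray:
    if isinstance(matrix, str):
        if matrix.upper() == "BLOSUM62":
            return _blosum62_lookup()
        raise ValueError(f"unknown substitution matrix {matrix!r}")
    if isinstance(matrix, tuple) and len(matrix) == 2:
        match, mismatch = matrix
        lookup = np.full((26, 26), int(mismatch), dtype=np.int64)
        np.fill_diagonal(lookup, int(match))
        return lookup
    if isinstance(matrix, np.ndarray) and matrix.shape == (26, 26):
        return matrix.astype(np.int64)
    raise ValueError("matrix must be 'BLOSUM62', (match, mismatch) or a 26x26 array")


def _digitize(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).astype(np.int64)
    arr = arr - ord("A")
    if arr.min() < 0 or arr.max() > 25:
        raise ValueError(f"sequence contains non-alphabetic characters: {seq!r}")
    return arr


def align_stats(
    a: str,
    b: str,
    matrix="BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> tuple[int, int, int]:
    """Optimal global alignment of ``a`` and ``b``.

    Returns ``(score, identities, aligned_columns)`` under the lexicographic
    objective (max score, max identities, min columns). Global pairwise
    alignments contain no dual-gap columns, so ``aligned_columns`` is also
    the p-distance denominator.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if gap_open < 0 or gap_extend < 0:
        raise ValueError("gap penalties must be non-negative")
    sa, sb = _digitize(a), _digitize(b)
    n, m = len(sa), len(sb)
    lookup = _score_lookup(matrix)

    K = min(n, m) + 1  # strict bound on identities and substitution columns
    K2 = K * K
    open_c = -gap_open * K2
    ext_c = -gap_extend * K2
    # per-column packed value for a substitution step
    sub_step = lookup[np.ix_(sa, sb)] * K2 + (sa[:, None] == sb[None, :]) * K + 1

    # rows over j=0..m; X = gap in b (vertical), Y = gap in a (horizontal)
    M = np.full(m + 1, NEG, dtype=np.int64)
    X = np.full(m + 1, NEG, dtype=np.int64)
    Y = np.full(m + 1, NEG, dtype=np.int64)
    M[0] = 0
    if m >= 1:
        Y[1] = open_c
        if m >= 2:
            Y[2:] = open_c + ext_c * np.arange(1, m)
    H_prev = np.maximum(np.maximum(M, X), Y)
    M_prev, X_prev, Y_prev = M, X, Y

    js = np.arange(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        M = np.full(m + 1, NEG, dtype=np.int64)
        M[1:] = H_prev[:-1] + sub_step[i - 1]
        X = np.maximum(
            X_prev + ext_c,
            np.maximum(M_prev, Y_prev) + open_c,
        )
        # X[0] handles the leading vertical gap
        X[0] = open_c + ext_c * (i - 1)
        U = np.maximum(M, X)
        # Y[j] = max(Y[j-1]+ext, U[j-1]+open); solved by prefix max of
        # V[k] = U[k] + open - (k+1)*ext  =>  Y[j] = j*ext + max_{k<j} V[k]
        V = U + open_c - (js + 1) * ext_c
        Y = np.full(m + 1, NEG, dtype=np.int64)
        if m >= 1:
            Y[1:] = js[1:] * ext_c + np.maximum.accumulate(V[:-1])
        H_prev = np.maximum(np.maximum(M, X), Y)
        M_prev, X_prev, Y_prev = M, X, Y

    C = int(H_prev[m])
    subcols = C % K
    rem = (C - subcols) // K
    ident = rem % K
    score = (rem - ident) // K
    columns = n + m - subcols
    return score, ident, columns


def p_distance(
    a: str,
    b: str,
    matrix="BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> float:
    """1 - identities / aligned columns of the optimal global alignment."""
    _, ident, columns = align_stats(a, b, matrix, gap_open, gap_extend)
    return 1.0 - ident / columns
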