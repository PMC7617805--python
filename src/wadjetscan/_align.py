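"""Shared affine-gap dynamic programming core.

Every aligner in the package — pairwise Needleman-Wunsch, local
profile-to-sequence search, and the profile-profile merges of the
progressive aligner — reduces to one affine-gap DP over a precomputed
cell-score matrix ``S`` where ``S[i, j]`` is the score of pairing row
item ``i`` of A with column item ``j`` of B.

Gap convention: a gap of length L costs ``gap_open + (L - 1) * gap_extend``
(the first gapped position pays the opening penalty).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_TO_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
X_INDEX = 20
N_SYMBOLS = 21  # 20 amino acids + X
GAP = "-"

_NEG = -1.0e30

_BLOSUM62: np.ndarray | None = None


def encode(seq: str) -> np.ndarray:
    """Encode a protein as integer codes; unknown residues collapse to X."""
    return np.fromiter(
        (AA_TO_INDEX.get(c, X_INDEX) for c in seq), dtype=np.int64, count=len(seq)
    )


def decode(codes: np.ndarray) -> str:
    table = ALPHABET + "X"
    return "".join(table[c] for c in codes)


def blosum62() -> np.ndarray:
    """21x21 BLOSUM62 matrix; the X row/column scores zero against everything."""
    global _BLOSUM62
    if _BLOSUM62 is None:
        raw = substitution_matrices.load("BLOSUM62")
        m = np.zeros((N_SYMBOLS, N_SYMBOLS))
        for i, a in enumerate(ALPHABET):
            for j, b in enumerate(ALPHABET):
                m[i, j] = raw[a, b]
        _BLOSUM62 = m
    return _BLOSUM62


@dataclass
class DpResult:
    """Outcome of one affine-gap DP.

    ``a_cols``/``b_cols`` give, per alignment column, the 0-based index
    consumed from A resp. B, or None for a gap. They are None entirely
    when the DP was run score-only.
    """

    score: float
    a_cols: list | None = None
    b_cols: list | None = None

    def span_a(self) -> tuple[int, int]:
        """0-based half-open interval of A positions covered by the path."""
        if not self.a_cols:
            return (0, 0)
        idx = [i for i in self.a_cols if i is not None]
        if not idx:
            return (0, 0)
        return (idx[0], idx[-1] + 1)


def affine_dp(
    S: np.ndarray,
    gap_open: float,
    gap_extend: float,
    *,
    local: bool = False,
    traceback: bool = False,
) -> DpResult:
    """Affine-gap DP over a precomputed (m x n) cell-score matrix.

    ``local=False`` is global Needleman-Wunsch (end gaps penalized);
    ``local=True`` is Smith-Waterman (score floored at zero, best cell
    anywhere). Ties prefer match over gap-in-B over gap-in-A, making the
    traceback deterministic.
    """
    S = np.asarray(S, dtype=np.float64)
    m, n = S.shape
    M = np.full((m + 1, n + 1), _NEG)
    X = np.full((m + 1, n + 1), _NEG)  # gap in B (consumes A)
    Y = np.full((m + 1, n + 1), _NEG)  # gap in A (consumes B)
    M[0, 0] = 0.0
    if local:
        M[0, :] = 0.0
        M[:, 0] = 0.0
    else:
        if m:
            X[1:, 0] = -(gap_open + np.arange(m) * gap_extend)
        if n:
            Y[0, 1:] = -(gap_open + np.arange(n) * gap_extend)

    if traceback:
        # pointer codes: pM 0=diag M, 1=diag X, 2=diag Y, 3=local start
        #                pX 0=open from M, 1=extend X, 2=open from Y
        #                pY 0=open from M, 1=extend Y, 2=open from X
        pM = np.zeros((m + 1, n + 1), dtype=np.uint8)
        pX = np.zeros((m + 1, n + 1), dtype=np.uint8)
        pY = np.zeros((m + 1, n + 1), dtype=np.uint8)
        if not local:
            if m >= 2:
                pX[2:, 0] = 1
            if n >= 2:
                pY[0, 2:] = 1

    js = np.arange(1, n + 1, dtype=np.float64)
    for i in range(1, m + 1):
        dM = M[i - 1, :-1]
        dX = X[i - 1, :-1]
        dY = Y[i - 1, :-1]
        diag = np.maximum(np.maximum(dM, dX), dY)
        if traceback:
            choice = np.where(diag == dM, 0, np.where(diag == dX, 1, 2)).astype(np.uint8)
        if local:
            if traceback:
                choice = np.where(diag <= 0.0, 3, choice).astype(np.uint8)
            diag = np.maximum(diag, 0.0)
        M[i, 1:] = S[i - 1, :] + diag
        if traceback:
            pM[i, 1:] = choice

        # full Gotoh transitions: a gap may open from either the match
        # state or the opposite gap state (adjacent opposing gap runs can
        # beat a severe mismatch when both would be extensions)
        from_m = M[i - 1, 1:] - gap_open
        from_x = X[i - 1, 1:] - gap_extend
        from_y = Y[i - 1, 1:] - gap_open
        X[i, 1:] = np.maximum(np.maximum(from_m, from_x), from_y)
        if traceback:
            pX[i, 1:] = np.where(
                from_m >= np.maximum(from_x, from_y),
                0,
                np.where(from_x >= from_y, 1, 2),
            )

        # Y has a within-row dependence; solve it with a running maximum:
        # Y[i,j] = max(max(M,X)[i,j-1]-open, Y[i,j-1]-ext)  <=>
        # Z[j] = Y[i,j]+ext*j = max(Z[j-1], max(M,X)[i,j-1]-open+ext*j)
        open_src = np.maximum(M[i, :-1], X[i, :-1])
        zc = (open_src - gap_open) + gap_extend * js
        Z = np.maximum.accumulate(np.concatenate(([Y[i, 0]], zc)))[1:]
        Y[i, 1:] = Z - gap_extend * js
        if traceback:
            pY[i, 1:] = np.where(
                Z == zc, np.where(M[i, :-1] >= X[i, :-1], 0, 2), 1
            )

    if local:
        body = M[1:, 1:] if m and n else np.zeros((1, 1))
        best = float(body.max()) if m and n else 0.0
        if best <= 0.0:
            return DpResult(0.0, [] if traceback else None, [] if traceback else None)
        flat = int(np.argmax(body))
        ei, ej = divmod(flat, body.shape[1])
        end_i, end_j, state = ei + 1, ej + 1, 0
        score = best
    else:
        finals = (float(M[m, n]), float(X[m, n]), float(Y[m, n]))
        state = int(np.argmax(finals))  # prefers M on ties
        score = max(finals)
        end_i, end_j = m, n

    if not traceback:
        return DpResult(score)

    a_cols: list = []
    b_cols: list = []
    i, j, st = end_i, end_j, state
    while not (i == 0 and j == 0):
        if st == 0:  # match state
            a_cols.append(i - 1)
            b_cols.append(j - 1)
            c = pM[i, j]
            i -= 1
            j -= 1
            if local and c == 3:
                break
            st = int(c)
        elif st == 1:  # gap in B
            a_cols.append(i - 1)
            b_cols.append(None)
            c = pX[i, j]
            i -= 1
            st = (0, 1, 2)[c]
        else:  # gap in A
            a_cols.append(None)
            b_cols.append(j - 1)
            c = pY[i, j]
            j -= 1
            st = (0, 2, 1)[c]
    a_cols.reverse()
    b_cols.reverse()
    return DpResult(score, a_cols, b_cols)


def global_align(
    a: str,
    b: str,
    *,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    sub: np.ndarray | None = None,
) -> tuple[float, str, str]:
    """Global alignment of two proteins; returns (score, gapped_a, gapped_b)."""
    if sub is None:
        sub = blosum62()
    ia, ib = encode(a), encode(b)
    S = sub[ia[:, None], ib[None, :]] if len(ia) and len(ib) else np.zeros((len(ia), len(ib)))
    r = affine_dp(S, gap_open, gap_extend, traceback=True)
    ga = "".join(a[i] if i is not None else GAP for i in r.a_cols)
    gb = "".join(b[j] if j is not None else GAP for j in r.b_cols)
    return r.score, ga, gb
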