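"""Dynamic-programming alignment kernels (numba-compiled).

Gap convention: the first base of a gap costs ``gap_open`` and every
further base ``gap_extend`` (both negative).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -(10**9)

_ENCODE = np.full(128, 4, dtype=np.int8)  # 4 = anything non-ACGT (N / ambiguity)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@njit(cache=True)
def _sw_affine(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover - numba
    n, m = len(q), len(t)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full(m + 1, NEG_INF, dtype=np.int64)  # gap in query row buffer
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 up, 3 left
    eptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1: E opened from H (left)
    fptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1: F opened from H (up)
    Fcol = np.full(m + 1, NEG_INF, dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        e = NEG_INF
        for j in range(1, m + 1):
            s = match if (q[i - 1] == t[j - 1] and q[i - 1] < 4) else mismatch
            # E: gap in query along this row
            e_open = H[i, j - 1] + gap_open
            e_ext = e + gap_extend
            if e_open >= e_ext:
                e = e_open
                eptr[i, j] = 1
            else:
                e = e_ext
            # F: gap in target down this column
            f_open = H[i - 1, j] + gap_open
            f_ext = Fcol[j] + gap_extend
            if f_open >= f_ext:
                Fcol[j] = f_open
                fptr[i, j] = 1
            else:
                Fcol[j] = f_ext
            h = H[i - 1, j - 1] + s
            hv = h
            p = 1
            if Fcol[j] > hv:
                hv = Fcol[j]
                p = 2
            if e > hv:
                hv = e
                p = 3
            if hv <= 0:
                hv = 0
                p = 0
            H[i, j] = hv
            ptr[i, j] = p
            if hv > best:
                best = hv
                bi = i
                bj = j
    # traceback with explicit gap-chain states: 0=H, 2=F, 3=E
    i, j = bi, bj
    matches = 0
    columns = 0
    state = 0
    while i > 0 and j > 0:
        if state == 0:
            p = ptr[i, j]
            if p == 0:
                break
            if p == 1:
                columns += 1
                if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                    matches += 1
                i -= 1
                j -= 1
            else:
                state = p
        elif state == 2:  # F: consume query base
            columns += 1
            opened = fptr[i, j] == 1
            i -= 1
            if opened:
                state = 0
        else:  # E: consume target base
            columns += 1
            opened = eptr[i, j] == 1
            j -= 1
            if opened:
                state = 0
    return best, i, bi, j, bj, matches, columns


def sw_affine(query: str, target: str, scoring=(1, -2, -5, -1)):
    """Best local alignment of query vs target (given orientation).

    Returns (score, (q_start, q_end), (t_start, t_end), matches, columns)
    with 0-based half-open intervals.
    """
    match, mismatch, go, ge = scoring
    score, qs, qe, ts, te, matches, columns = _sw_affine(
        encode(query), encode(target), match, mismatch, go, ge
    )
    return int(score), (int(qs), int(qe)), (int(ts), int(te)), int(matches), int(columns)


@njit(cache=True)
def _nw_affine_profile(S, gap_open, gap_extend):  # pragma: no cover - numba
    """Global alignment over a precomputed column-score matrix S (n x m)."""
    n, m = S.shape
    H = np.empty((n + 1, m + 1), dtype=np.float64)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    eptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    fptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    Fcol = np.full(m + 1, -1e18, dtype=np.float64)
    H[0, 0] = 0.0
    for j in range(1, m + 1):
        H[0, j] = gap_open + gap_extend * (j - 1)
        ptr[0, j] = 3
    for i in range(1, n + 1):
        H[i, 0] = gap_open + gap_extend * (i - 1)
        ptr[i, 0] = 2
    for i in range(1, n + 1):
        e = -1e18
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + gap_open
            e_ext = e + gap_extend
            if e_open >= e_ext:
                e = e_open
                eptr[i, j] = 1
            else:
                e = e_ext
            f_open = H[i - 1, j] + gap_open
            f_ext = Fcol[j] + gap_extend
            if f_open >= f_ext:
                Fcol[j] = f_open
                fptr[i, j] = 1
            else:
                Fcol[j] = f_ext
            h = H[i - 1, j - 1] + S[i - 1, j - 1]
            hv = h
            p = 1
            if Fcol[j] > hv:
                hv = Fcol[j]
                p = 2
            if e > hv:
                hv = e
                p = 3
            H[i, j] = hv
            ptr[i, j] = p
    return ptr, eptr, fptr, H[n, m]


def nw_affine_path(S: np.ndarray, gap_open: float, gap_extend: float):
    """Global alignment path over score matrix S.

    Returns (score, path) where path is a list of (i, j) pairs per column;
    i or j is -1 for a gap in that profile.
    """
    ptr, eptr, fptr, score = _nw_affine_profile(
        np.ascontiguousarray(S, dtype=np.float64), float(gap_open), float(gap_extend)
    )
    i, j = S.shape
    path: list[tuple[int, int]] = []
    state = 0
    while i > 0 or j > 0:
        if i == 0:
            path.append((-1, j - 1))
            j -= 1
            continue
        if j == 0:
            path.append((i - 1, -1))
            i -= 1
            continue
        if state == 0:
            p = ptr[i, j]
            if p == 1:
                path.append((i - 1, j - 1))
                i -= 1
                j -= 1
            else:
                state = p
        elif state == 2:
            path.append((i - 1, -1))
            opened = fptr[i, j] == 1
            i -= 1
            if opened:
                state = 0
        else:
            path.append((-1, j - 1))
            opened = eptr[i, j] == 1
            j -= 1
            if opened:
                state = 0
    path.reverse()
    return float(score), path


def pairwise_global_identity(a: str, b: str, scoring=(1, -1, -3, -1)) -> float:
    """Fraction of matching columns in a global alignment of two sequences."""
    ea, eb = encode(a), encode(b)
    S = np.where(
        (ea[:, None] == eb[None, :]) & (ea[:, None] < 4),
        float(scoring[0]),
        float(scoring[1]),
    )
    _, path = nw_affine_path(S, scoring[2], scoring[3])
    matches = sum(1 for i, j in path if i >= 0 and j >= 0 and a[i] == b[j] and a[i] in "ACGT")
    return matches / len(path) if path else 0.0
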