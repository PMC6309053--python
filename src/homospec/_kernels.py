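"""Numba inner loops for spectral candidate scoring and alignment DP.

These kernels are performance twins of pure-Python implementations in
``matching`` and ``mapping``; the test suite asserts agreement between the
two routes on random instances.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e18


@njit(cache=True)
def greedy_match_count(theo: np.ndarray, obs: np.ndarray, tol_ppm: float) -> int:
    """Greedy left-to-right one-to-one matching of sorted mass lists."""
    j = 0
    count = 0
    for i in range(theo.size):
        t = theo[i]
        tol = t * tol_ppm * 1e-6
        while j < obs.size and obs[j] < t - tol:
            j += 1
        if j < obs.size and obs[j] <= t + tol:
            count += 1
            j += 1
    return count


@njit(cache=True, inline="always")
def _has_match(obs: np.ndarray, t: float, tol_ppm: float) -> bool:
    if t <= 0.0:
        return False
    tol = t * tol_ppm * 1e-6
    j = np.searchsorted(obs, t - tol)
    return j < obs.size and obs[j] <= t + tol


@njit(cache=True)
def score_protein(
    P: np.ndarray,
    starts: np.ndarray,
    j_lo: np.ndarray,
    j_hi: np.ndarray,
    obs: np.ndarray,
    prec: float,
    tol_ppm: float,
    use_n: bool,
    use_c: bool,
    water: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Score every candidate segment of one protein against one spectrum,
    given per-start end ranges [j_lo[si], j_hi[si]].

    A candidate within precursor tolerance is scored as a greedy one-to-one
    match count on its merged unshifted ladder (delta 0); otherwise the
    score is the best split-site sum of unshifted and shifted matched
    cleavage sites over the requested ion series, capped at the observed
    peak count (one peak cannot support more sites than there are peaks in
    a one-to-one assignment).

    Exploits that every ladder-class membership test depends on only two of
    (start, end, site): with x the absolute cumulative-mass index of a
    cleavage site,

    - unshifted N and shifted C masses depend on (start, x),
    - shifted N and unshifted C masses depend on (end, x),

    so the four matched-flag tables are computed once per start or per end
    and shared across all candidates.  Returns flattened
    (starts, ends, scores, deltas).
    """
    L = P.size - 1
    n_cand = 0
    for si in range(starts.size):
        if j_hi[si] >= j_lo[si]:
            n_cand += j_hi[si] - j_lo[si] + 1
    out_start = np.empty(n_cand, np.int64)
    out_end = np.empty(n_cand, np.int64)
    out_score = np.zeros(n_cand, np.int64)
    out_delta = np.zeros(n_cand)

    e_min, e_max = L + 1, 0
    for si in range(starts.size):
        if j_hi[si] >= j_lo[si]:
            if j_lo[si] < e_min:
                e_min = j_lo[si]
            if j_hi[si] > e_max:
                e_max = j_hi[si]
    if n_cand == 0:
        return out_start, out_end, out_score, out_delta

    # start-keyed flags over x = 1..L-1: NU (unshifted N), SC (shifted C)
    n_s = starts.size
    NU = np.zeros((n_s, L), np.uint8)
    SC = np.zeros((n_s, L), np.uint8)
    for si in range(n_s):
        base = P[starts[si] - 1]
        for x in range(starts[si], L):
            if use_n and _has_match(obs, P[x] - base, tol_ppm):
                NU[si, x] = 1
            if use_c and _has_match(obs, prec - (P[x] - base), tol_ppm):
                SC[si, x] = 1
    # end-keyed flags: SN (shifted N), CU (unshifted C); ends e_min..e_max
    n_e = e_max - e_min + 1
    SN = np.zeros((n_e, L), np.uint8)
    CU = np.zeros((n_e, L), np.uint8)
    for ei in range(n_e):
        pj = P[e_min + ei]
        for x in range(1, e_min + ei):
            if use_n and _has_match(obs, prec - water - (pj - P[x]), tol_ppm):
                SN[ei, x] = 1
            if use_c and _has_match(obs, pj - P[x] + water, tol_ppm):
                CU[ei, x] = 1

    k = 0
    for si in range(n_s):
        i = starts[si]
        for j in range(j_lo[si], j_hi[si] + 1):
            ei = j - e_min
            seglen = j - i + 1
            segmass = P[j] - P[i - 1]
            delta = prec - (segmass + water)
            out_start[k] = i
            out_end[k] = j
            if abs(delta) <= prec * tol_ppm * 1e-6:
                nlad = (seglen - 1) if use_n else 0
                clad = (seglen - 1) if use_c else 0
                merged = np.empty(nlad + clad)
                pos = 0
                base = P[i - 1]
                if use_n:
                    for c in range(1, seglen):
                        merged[pos] = P[i - 1 + c] - base
                        pos += 1
                if use_c:
                    for c in range(1, seglen):
                        merged[pos] = segmass - (P[i - 1 + c] - base) + water
                        pos += 1
                merged = np.sort(merged)
                out_score[k] = greedy_match_count(merged, obs, tol_ppm)
                out_delta[k] = 0.0
            else:
                cur = 0
                for x in range(i, j):  # split s = 0: everything right of split
                    cur += SN[ei, x] + CU[ei, x]
                best = cur
                for x in range(i, j):  # site enters the left-of-split class
                    cur += NU[si, x] - SN[ei, x] + SC[si, x] - CU[ei, x]
                    if cur > best:
                        best = cur
                if best > obs.size:
                    best = obs.size
                out_score[k] = best
                out_delta[k] = delta
            k += 1
    return out_start, out_end, out_score, out_delta


@njit(cache=True)
def sw_score(q: np.ndarray, s: np.ndarray, sub: np.ndarray, go: float, ge: float) -> float:
    """Smith-Waterman local alignment score, affine gaps: a gap of length
    ``L`` costs ``go + L * ge``.  ``q``/``s`` are alphabet-index arrays."""
    m = s.size
    h_prev = np.zeros(m + 1)
    f = np.full(m + 1, NEG)
    best = 0.0
    for i in range(1, q.size + 1):
        h_cur = np.zeros(m + 1)
        e = NEG
        for j in range(1, m + 1):
            diag = h_prev[j - 1] + sub[q[i - 1], s[j - 1]]
            e = max(h_cur[j - 1] - go - ge, e - ge)
            f[j] = max(h_prev[j] - go - ge, f[j] - ge)
            h = max(0.0, diag, e, f[j])
            h_cur[j] = h
            if h > best:
                best = h
        h_prev = h_cur
    return best


@njit(cache=True)
def semiglobal_fill(
    q: np.ndarray, s: np.ndarray, sub: np.ndarray, go: float, ge: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fill matrices for a global-local alignment: global in the query,
    free entry/exit in the subject.  State X consumes query against a gap,
    state Y consumes subject against a gap; V is the cell maximum."""
    n = q.size
    m = s.size
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    V = np.full((n + 1, m + 1), NEG)
    for j in range(m + 1):
        V[0, j] = 0.0  # free subject prefix
    for i in range(1, n + 1):
        X[i, 0] = max(V[i - 1, 0] - go - ge, X[i - 1, 0] - ge)
        V[i, 0] = X[i, 0]
        for j in range(1, m + 1):
            M[i, j] = V[i - 1, j - 1] + sub[q[i - 1], s[j - 1]]
            X[i, j] = max(V[i - 1, j] - go - ge, X[i - 1, j] - ge)
            Y[i, j] = max(V[i, j - 1] - go - ge, Y[i, j - 1] - ge)
            V[i, j] = max(M[i, j], max(X[i, j], Y[i, j]))
    return M, X, Y, V
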