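import numpy as np
import pytest

from homospec.model import ProteinRecord, ProteomeDB


@pytest.fixture(scope="session")
def small_proteome():
    """Five random proteins, fixed seed."""
    from homospec.synthetic import generate_reference_proteome

    return generate_reference_proteome(5, (50, 80), seed=3)


@pytest.fixture()
def toy_db():
    return ProteomeDB([ProteinRecord("P1", "EPPLSQETFSDLWKLLPENNV")])


def naive_one_shift(obs, precursor, segment, tol_ppm, ion_series=("N", "C")):
    """Independent oracle for the one-unknown-shift alignment: naive flag
    computation and exhaustive split-site enumeration (smallest split wins
    ties), mirroring the operation's contract definition."""
    from homospec.masses import RESIDUE_MASS, WATER

    obs = list(obs)
    L = len(segment)
    masses = [RESIDUE_MASS[a] for a in segment]
    segmass = sum(masses) + WATER
    npm = [sum(masses[:c]) for c in range(1, L)]
    cpm = [sum(masses[c:]) + WATER for c in range(1, L)]
    prec = precursor
    delta = prec - segmass

    def greedy(theo):
        j, count = 0, 0
        for t in sorted(theo):
            tol = t * tol_ppm * 1e-6
            while j < len(obs) and obs[j] < t - tol:
                j += 1
            if j < len(obs) and obs[j] <= t + tol:
                count += 1
                j += 1
        return count

    def hit(t):
        if t <= 0:
            return False
        tol = t * tol_ppm * 1e-6
        return any(abs(o - t) <= tol for o in obs)

    use_n = "N" in ion_series
    use_c = "C" in ion_series
    if abs(delta) <= prec * tol_ppm * 1e-6:
        merged = (npm if use_n else []) + (cpm if use_c else [])
        return greedy(merged), 0.0, None

    nu = [hit(m) if use_n else False for m in npm]
    ns = [hit(m + delta) if use_n else False for m in npm]
    cu = [hit(m) if use_c else False for m in cpm]
    cs = [hit(m + delta) if use_c else False for m in cpm]
    best_s, best = 0, -1
    for s in range(L):
        score = sum(
            (nu[c - 1] if c <= s else ns[c - 1]) + (cs[c - 1] if c <= s else cu[c - 1])
            for c in range(1, L)
        )
        if score > best:
            best, best_s = score, s
    best = min(best, len(obs))
    left = [c for c in range(1, best_s + 1) if nu[c - 1] or cs[c - 1]]
    right = [c for c in range(best_s + 1, L) if ns[c - 1] or cu[c - 1]]
    r = max(left) if left else 0
    t = min(right) if right else L
    return best, delta, (r + 1, t)


def naive_global_local(query, subject, go=10.0, ge=4.0):
    """Independent oracle for the global-local alignment score: enumerate
    every subject substring and globally align the query against it with a
    memoized affine-gap recursion (a gap of length L costs go + L*ge)."""
    import functools

    from homospec.mapping import BLOSUM62, _INDEX

    q = [_INDEX[a] for a in query]

    def global_affine(s):
        @functools.lru_cache(maxsize=None)
        def rec(i, j, state):
            # best score aligning q[i:] with s[j:], given the previous
            # column's state ('M' start/match, 'X' gap in subject run,
            # 'Y' gap in query run)
            if i == len(q) and j == len(s):
                return 0.0
            best = -1e18
            if i < len(q) and j < len(s):
                best = max(best, BLOSUM62[q[i], s[j]] + rec(i + 1, j + 1, "M"))
            if i < len(q):
                cost = ge if state == "X" else go + ge
                best = max(best, -cost + rec(i + 1, j, "X"))
            if j < len(s):
                cost = ge if state == "Y" else go + ge
                best = max(best, -cost + rec(i, j + 1, "Y"))
            return best

        return rec(0, 0, "M")

    sub = [_INDEX[a] for a in subject]
    best = -1e18
    for a in range(len(subject)):
        for b in range(a + 1, len(subject) + 1):
            best = max(best, global_affine(tuple(sub[a:b])))
    return best
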