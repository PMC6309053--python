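"""Proteoform-spectrum matching with at most one unknown mass shift.

For each query spectrum the search enumerates candidate protein segments
(terminal truncations) whose unmodified mass lies within ``max_delta`` of
the precursor, scores each candidate by counting matched fragment masses
while allowing a single unknown mass shift ``delta = precursor - segment
mass`` localized at some split site, and reports the best proteoform-
spectrum match (PrSM).  A shuffled decoy database searched alongside the
targets supports spectrum-level false-discovery-rate filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._kernels import score_protein
from .masses import WATER, prefix_mass_array, residue_masses
from .model import DeconvolutedSpectrum, PrSM, ProteinRecord, ProteomeDB, sentinel_prsm


@dataclass
class SearchConfig:
    """Knobs of the database search stage.

    tol_ppm applies to both precursor and fragment masses; ``max_delta``
    bounds |delta| and hence the truncation enumeration; trim fractions
    bound how much of a protein's termini may be removed when enumerating
    candidate segments.
    """

    tol_ppm: float = 15.0
    max_delta: float = 500.0
    max_start_trim_fraction: float = 0.3
    max_end_trim_fraction: float = 0.3
    min_segment_length: int = 10
    ion_series: tuple[str, ...] = ("N", "C")

    def __post_init__(self) -> None:
        if self.tol_ppm < 0 or self.max_delta <= 0:
            raise ValueError("tolerances must be positive")
        series = set(self.ion_series)
        if not series or not series <= {"N", "C"}:
            raise ValueError("ion_series must be a non-empty subset of {'N','C'}")


def prefix_masses(segment: str) -> np.ndarray:
    """N-terminal fragment ladder of an unmodified segment: the cumulative
    residue masses at cleavage sites 1..L-1 (strictly increasing)."""
    rm = residue_masses(segment)
    return np.cumsum(rm)[:-1]


def suffix_masses(segment: str) -> np.ndarray:
    """C-terminal fragment ladder indexed by cleavage site 1..L-1: mass of
    residues c+1..L plus water (descending in c)."""
    rm = residue_masses(segment)
    return rm.sum() - np.cumsum(rm)[:-1] + WATER


def theoretical_fragments(
    segment: str,
    modification: Optional[tuple[int, float]] = None,
    ion_series: tuple[str, ...] = ("N", "C"),
) -> np.ndarray:
    """Sorted theoretical neutral fragment masses of a proteoform segment.

    ``modification`` is (site, mass) with the site 1-based within the
    segment; the shift is applied to every fragment spanning that residue:
    N-terminal fragments at cleavage sites >= site, C-terminal fragments at
    cleavage sites < site.
    """
    L = len(segment)
    parts = []
    if modification is not None:
        site, shift = modification
        if not 1 <= site <= L:
            raise ValueError("modification site outside segment")
    else:
        site, shift = 0, 0.0
    if "N" in ion_series:
        npm = prefix_masses(segment)
        if modification is not None:
            npm = npm + np.where(np.arange(1, L) >= site, shift, 0.0)
        parts.append(npm)
    if "C" in ion_series:
        cpm = suffix_masses(segment)
        if modification is not None:
            cpm = cpm + np.where(np.arange(1, L) < site, shift, 0.0)
        parts.append(cpm)
    if not parts:
        return np.empty(0)
    return np.sort(np.concatenate(parts))


def match_count(
    spectrum_fragments: Sequence[float], theoretical: Sequence[float], tol_ppm: float
) -> int:
    """Count theoretical masses explained by observed masses within a
    relative tolerance; greedy left-to-right pairing consumes each observed
    mass at most once.  Both lists must be sorted ascending."""
    if tol_ppm < 0:
        raise ValueError("tolerance must be non-negative")
    obs = np.asarray(spectrum_fragments, dtype=float)
    theo = np.asarray(theoretical, dtype=float)
    j = 0
    count = 0
    for t in theo:
        tol = t * tol_ppm * 1e-6
        while j < obs.size and obs[j] < t - tol:
            j += 1
        if j < obs.size and obs[j] <= t + tol:
            count += 1
            j += 1
    return count


def _matched_flags(theo: np.ndarray, obs: np.ndarray, tol_ppm: float) -> np.ndarray:
    """Independent per-mass flags: theoretical mass has >= 1 observed mass
    within tolerance (non-positive theoretical masses never match)."""
    theo = np.asarray(theo, dtype=float)
    flags = np.zeros(theo.size, dtype=bool)
    pos = theo > 0
    tol = np.abs(theo) * tol_ppm * 1e-6
    idx = np.searchsorted(obs, theo - tol)
    ok = pos & (idx < obs.size)
    flags[ok] = obs[idx[ok]] <= (theo + tol)[ok]
    return flags


def one_shift_align(
    spectrum: DeconvolutedSpectrum,
    segment: str,
    tol_ppm: float = 15.0,
    ion_series: tuple[str, ...] = ("N", "C"),
) -> tuple[int, float, Optional[tuple[int, int]]]:
    """Best alignment of a spectrum to a segment with zero or one unknown
    mass shift.

    If the precursor matches the unmodified segment mass within tolerance,
    the match is scored shift-free and no localization interval is
    reported.  Otherwise ``delta = precursor - segment mass`` is placed at
    the best split site s (sites <= s unshifted, sites > s shifted, in
    N-terminal cleavage coordinates, with the symmetric C-terminal
    contributions; the total is capped at the observed peak count, since a
    one-to-one peak assignment can never exceed it), and the interval
    [r+1, t] is reported, where r is the
    rightmost cleavage site with unshifted evidence left of the split and t
    the leftmost site with shifted evidence right of it (extended to the
    segment termini when a bounding matched site is absent).
    """
    if not segment:
        raise ValueError("empty segment")
    L = len(segment)
    obs = np.asarray(spectrum.fragment_masses, dtype=float)
    rm = residue_masses(segment)
    segmass = float(rm.sum() + WATER)
    delta = spectrum.precursor_mass - segmass
    use_n = "N" in ion_series
    use_c = "C" in ion_series
    npm = np.cumsum(rm)[:-1]
    cpm = rm.sum() - npm + WATER
    if abs(delta) <= spectrum.precursor_mass * tol_ppm * 1e-6:
        parts = ([npm] if use_n else []) + ([cpm] if use_c else [])
        merged = np.sort(np.concatenate(parts)) if parts else np.empty(0)
        return match_count(obs, merged, tol_ppm), 0.0, None

    zeros = np.zeros(L - 1, dtype=bool)
    nu = _matched_flags(npm, obs, tol_ppm) if use_n else zeros
    ns = _matched_flags(npm + delta, obs, tol_ppm) if use_n else zeros
    cu = _matched_flags(cpm, obs, tol_ppm) if use_c else zeros
    cs = _matched_flags(cpm + delta, obs, tol_ppm) if use_c else zeros

    # score(s) over split sites s = 0..L-1 via cumulative sums
    cnu = np.concatenate(([0], np.cumsum(nu)))[: L]
    cns = np.concatenate(([0], np.cumsum(ns)))[: L]
    ccu = np.concatenate(([0], np.cumsum(cu)))[: L]
    ccs = np.concatenate(([0], np.cumsum(cs)))[: L]
    scores = cnu + (ns.sum() - cns) + ccs + (cu.sum() - ccu)
    s_best = int(np.argmax(scores))  # smallest split on ties
    # cap at the peak count: one observed peak supports at most one site in
    # a one-to-one matching, so duplicated explanations cannot outscore a
    # complete match
    score = min(int(scores[s_best]), int(obs.size))

    sites = np.arange(1, L)
    left_evidence = sites[(nu | cs) & (sites <= s_best)]
    right_evidence = sites[(ns | cu) & (sites > s_best)]
    r = int(left_evidence.max()) if left_evidence.size else 0
    t = int(right_evidence.min()) if right_evidence.size else L
    return score, float(delta), (r + 1, t)


def _candidate_ranges(
    P: np.ndarray, prec: float, cfg: SearchConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-start end ranges [j_lo, j_hi] of candidate segments of one
    protein whose unmodified mass lies within max_delta of the precursor,
    subject to the truncation enumeration bounds."""
    L = P.size - 1
    max_start = 1 + int(np.floor(cfg.max_start_trim_fraction * L))
    min_end = L - int(np.floor(cfg.max_end_trim_fraction * L))
    starts = np.arange(1, max_start + 1, dtype=np.int64)
    lo = P[starts - 1] + (prec - cfg.max_delta - WATER)
    hi = P[starts - 1] + (prec + cfg.max_delta - WATER)
    j_lo = np.searchsorted(P, lo, side="left").astype(np.int64)
    j_hi = (np.searchsorted(P, hi, side="right") - 1).astype(np.int64)
    j_lo = np.maximum.reduce([j_lo, starts - 1 + cfg.min_segment_length,
                              np.full_like(starts, min_end)])
    j_hi = np.minimum(j_hi, L)
    return starts, j_lo, j_hi


def search_database(
    spectrum: DeconvolutedSpectrum, db: ProteomeDB, cfg: Optional[SearchConfig] = None
) -> PrSM:
    """Best PrSM for one spectrum over a (target + decoy) protein database.

    Ties are broken deterministically: higher score, then smaller |delta|,
    then lexicographically smallest (protein_id, start).  Returns a score-0
    sentinel when no candidate segment is mass-compatible.
    """
    cfg = cfg or SearchConfig()
    obs = np.asarray(spectrum.fragment_masses, dtype=float)
    prec = spectrum.precursor_mass
    use_n = "N" in cfg.ion_series
    use_c = "C" in cfg.ion_series
    best = None  # (-score, |delta|, protein_id, start, end, delta)
    for rec in sorted(db, key=lambda r: r.protein_id):
        P = db.prefix_masses(rec.protein_id)
        s_arr, j_lo, j_hi = _candidate_ranges(P, prec, cfg)
        if not (j_hi >= j_lo).any():
            continue
        starts, ends, scores, deltas = score_protein(
            P, s_arr, j_lo, j_hi, obs, prec, cfg.tol_ppm, use_n, use_c, WATER
        )
        if starts.size == 0:
            continue
        order = np.lexsort((starts, np.abs(deltas), -scores))
        k = order[0]
        key = (-int(scores[k]), abs(float(deltas[k])), rec.protein_id,
               int(starts[k]), int(ends[k]), float(deltas[k]))
        if best is None or key < best:
            best = key
    if best is None or -best[0] == 0:
        return sentinel_prsm(spectrum.spectrum_id)
    neg_score, _, pid, start, end, _ = best
    segment = db.sequence(pid)[start - 1 : end]
    score, delta, interval = one_shift_align(spectrum, segment, cfg.tol_ppm, cfg.ion_series)
    return PrSM(
        spectrum_id=spectrum.spectrum_id,
        protein_id=pid,
        start=start,
        end=end,
        score=score,
        delta=delta,
        shift_interval=interval,
        is_decoy=pid.startswith("DECOY_"),
    )


def build_decoy_db(db: ProteomeDB, seed: int) -> ProteomeDB:
    """One shuffled decoy per target protein (residue multiset preserved),
    ids prefixed ``DECOY_``; deterministic for a fixed seed."""
    for rec in db:
        if f"DECOY_{rec.protein_id}" in db:
            raise ValueError(f"decoy id collision for {rec.protein_id}")
    rng = np.random.default_rng(seed)
    records = []
    for rec in db:
        letters = np.array(list(rec.sequence))
        records.append(
            ProteinRecord("DECOY_" + rec.protein_id, "".join(rng.permutation(letters)))
        )
    return ProteomeDB(records)


@dataclass
class FdrResult:
    """Target-decoy threshold statistics at the chosen score cutoff."""

    threshold: float
    n_target: int
    n_decoy: int

    @property
    def decoy_proportion(self) -> float:
        total = self.n_target + self.n_decoy
        return self.n_decoy / total if total else 0.0


def fdr_threshold(prsms: Sequence[PrSM], fdr_level: float) -> FdrResult:
    """Smallest score threshold tau >= 1 with
    #decoy(score >= tau) / max(1, #target(score >= tau)) <= fdr_level.

    Score-0 sentinels are never accepted.  If no threshold satisfies the
    bound the result is an infinite threshold (nothing accepted).
    """
    if not 0.0 < fdr_level <= 1.0:
        raise ValueError("fdr_level must be in (0, 1]")
    tgt = np.sort(np.array([p.score for p in prsms if not p.is_decoy and p.score > 0]))
    dec = np.sort(np.array([p.score for p in prsms if p.is_decoy and p.score > 0]))
    for tau in sorted(set(tgt.tolist()) | set(dec.tolist()) | {1}):
        n_t = int(tgt.size - np.searchsorted(tgt, tau, side="left"))
        n_d = int(dec.size - np.searchsorted(dec, tau, side="left"))
        if n_d / max(1, n_t) <= fdr_level:
            return FdrResult(float(tau), n_t, n_d)
    return FdrResult(float("inf"), 0, 0)


def filter_fdr(prsms: Sequence[PrSM], fdr_level: float) -> list[PrSM]:
    """Spectrum-level FDR filter over best-per-spectrum PrSMs: accept
    everything at or above the target-decoy threshold, then drop decoys.
    Accepted PrSMs are returned with their ``accepted`` flag set."""
    res = fdr_threshold(prsms, fdr_level)
    accepted = []
    for p in prsms:
        if not p.is_decoy and p.score >= res.threshold:
            p.accepted = True
            accepted.append(p)
    return accepted
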