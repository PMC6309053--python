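"""Synthetic two-proteome benchmark generator.

Emulates the evaluation scenario in which spectra of one organism are
searched both against its own proteome (the reference) and against the
proteome of a close relative (the homolog): a reference proteome is drawn
at random, a homolog is derived from it by planting a controlled number of
residue-level mutations per protein, proteoforms are sampled as terminal
truncations with at most one modification, and deconvoluted spectra are
produced from their theoretical fragment ladders with peak dropout and
ppm-scale mass error.  Every spectrum carries its generating proteoform as
ground truth.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np

from .masses import AA20, WATER, peptide_mass
from .matching import prefix_masses, suffix_masses, theoretical_fragments
from .model import (
    DeconvolutedSpectrum,
    Modification,
    MutationEvent,
    ProteinRecord,
    ProteomeDB,
    Proteoform,
)

_AA = np.array(list(AA20))


def generate_reference_proteome(
    n_proteins: int,
    length_range: tuple[int, int],
    seed: int,
    composition: Optional[Sequence[float]] = None,
    id_prefix: str = "REF",
) -> ProteomeDB:
    """Draw ``n_proteins`` random protein sequences.

    Lengths are uniform over ``length_range`` (inclusive, within [20, 1000]);
    residues are i.i.d. from ``composition`` over the 20 standard amino acids
    (uniform by default).  Deterministic for a fixed seed.
    """
    lo, hi = length_range
    if n_proteins < 1 or not (20 <= lo <= hi <= 1000):
        raise ValueError("n_proteins >= 1 and 20 <= lo <= hi <= 1000 required")
    if composition is not None:
        composition = np.asarray(composition, dtype=float)
        if composition.size != 20 or (composition < 0).any():
            raise ValueError("composition must be 20 non-negative weights")
        composition = composition / composition.sum()
    rng = np.random.default_rng(seed)
    width = len(str(n_proteins))
    records = []
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_AA, size=length, p=composition))
        records.append(ProteinRecord(f"{id_prefix}_{i + 1:0{width}d}", seq))
    return ProteomeDB(records)


def apply_mutations(sequence: str, events: Sequence[MutationEvent]) -> str:
    """Replay a mutation log over a reference sequence.

    Events address reference coordinates and occupy distinct positions, so
    applying them in descending ``ref_pos`` order is exact.
    """
    chars = list(sequence)
    for ev in sorted(events, key=lambda e: e.ref_pos, reverse=True):
        idx = ev.ref_pos - 1
        if ev.kind == "substitution":
            if chars[idx] != ev.ref_aa:
                raise ValueError(f"event/sequence mismatch at {ev.ref_pos}")
            chars[idx] = ev.alt_aa
        elif ev.kind == "deletion":
            if chars[idx] != ev.ref_aa:
                raise ValueError(f"event/sequence mismatch at {ev.ref_pos}")
            del chars[idx]
        else:  # insertion before ref_pos
            chars.insert(idx, ev.alt_aa)
    return "".join(chars)


def mutate_proteome(
    ref: ProteomeDB,
    mutations_per_protein: int | Mapping[str, int],
    indel_fraction: float = 0.0,
    seed: int = 0,
    position_window: tuple[float, float] = (0.0, 1.0),
    id_map: Optional[Mapping[str, str]] = None,
) -> tuple[ProteomeDB, dict[str, list[MutationEvent]]]:
    """Derive a homolog proteome by planting residue-level mutations.

    Each protein receives exactly the requested number of events
    (per-residue counting: a single-residue insertion or deletion is one
    event) at distinct reference positions.  ``indel_fraction`` is the
    probability that an event is an indel rather than a substitution;
    ``position_window`` restricts event positions to a fractional span of
    the protein (used to keep mutations inside later-sampled segments).
    Returns the homolog database and the per-reference-protein event log;
    replaying the log over the reference reproduces the homolog exactly.
    """
    if not 0.0 <= indel_fraction <= 1.0:
        raise ValueError("indel_fraction must be in [0, 1]")
    lo_f, hi_f = position_window
    if not 0.0 <= lo_f < hi_f <= 1.0:
        raise ValueError("invalid position window")
    rng = np.random.default_rng(seed)
    records = []
    log: dict[str, list[MutationEvent]] = {}
    for rec in ref:
        k = (
            mutations_per_protein
            if isinstance(mutations_per_protein, int)
            else int(mutations_per_protein.get(rec.protein_id, 0))
        )
        L = len(rec.sequence)
        if k < 0 or k > L:
            raise ValueError(f"{rec.protein_id}: cannot plant {k} mutations in {L} aa")
        lo = max(1, int(np.floor(lo_f * L)) + 1)
        hi = max(lo, int(np.ceil(hi_f * L)))
        if hi - lo + 1 < k:
            raise ValueError(f"{rec.protein_id}: window too narrow for {k} mutations")
        positions = sorted(rng.choice(np.arange(lo, hi + 1), size=k, replace=False))
        events = []
        for pos in positions:
            pos = int(pos)
            ref_aa = rec.sequence[pos - 1]
            if rng.random() < indel_fraction:
                if rng.random() < 0.5:
                    events.append(MutationEvent("deletion", pos, ref_aa, ""))
                else:
                    alt = str(rng.choice(_AA))
                    events.append(MutationEvent("insertion", pos, "", alt))
            else:
                alt = str(rng.choice([a for a in AA20 if a != ref_aa]))
                events.append(MutationEvent("substitution", pos, ref_aa, alt))
        hom_id = (
            id_map[rec.protein_id]
            if id_map is not None
            else rec.protein_id.replace("REF", "HOM", 1)
            if rec.protein_id.startswith("REF")
            else f"HOM_{rec.protein_id}"
        )
        records.append(ProteinRecord(hom_id, apply_mutations(rec.sequence, events)))
        log[rec.protein_id] = events
    return ProteomeDB(records), log


def sample_proteoforms(
    db: ProteomeDB,
    n: int,
    truncation_model: tuple[float, float] = (0.1, 0.1),
    ptm_menu: Optional[Sequence[tuple[str, float]]] = None,
    ptm_probability: float = 0.0,
    seed: int = 0,
    min_length: int = 15,
    protein_ids: Optional[Sequence[str]] = None,
) -> list[Proteoform]:
    """Sample ``n`` proteoforms as terminal truncations of database proteins.

    ``truncation_model`` gives the maximum N- and C-terminal trim as
    fractions of protein length.  With probability ``ptm_probability`` a
    proteoform carries exactly one modification drawn uniformly from
    ``ptm_menu``, placed at a uniformly random (chemically unconstrained)
    site inside the segment.
    """
    if len(db) == 0:
        raise ValueError("empty database")
    if ptm_probability > 0 and not ptm_menu:
        raise ValueError("ptm_menu required when ptm_probability > 0")
    max_n, max_c = truncation_model
    rng = np.random.default_rng(seed)
    pool = list(protein_ids) if protein_ids is not None else [r.protein_id for r in db]
    out = []
    for _ in range(n):
        pid = pool[int(rng.integers(len(pool)))]
        L = len(db.sequence(pid))
        start = 1 + int(rng.integers(0, int(np.floor(max_n * L)) + 1))
        end = L - int(rng.integers(0, int(np.floor(max_c * L)) + 1))
        if end - start + 1 < min_length:  # clamp short draws back out
            end = min(L, start + min_length - 1)
            start = max(1, end - min_length + 1)
        mod = None
        if ptm_menu and rng.random() < ptm_probability:
            name, mass = ptm_menu[int(rng.integers(len(ptm_menu)))]
            site = int(rng.integers(start, end + 1))
            mod = Modification(site, float(mass), name)
        out.append(Proteoform(pid, start, end, mod))
    return out


def simulate_spectrum(
    pf: Proteoform,
    db: ProteomeDB,
    ion_series: tuple[str, ...] = ("N", "C"),
    peak_keep_probability: float = 1.0,
    mass_error_ppm: float = 0.0,
    seed: int = 0,
    spectrum_id: str = "S1",
    fragment_length_scale: Optional[float] = None,
) -> DeconvolutedSpectrum:
    """Produce the deconvoluted spectrum of a proteoform.

    Fragments are the theoretical ladder masses of the segment (modification
    shift applied to fragments that span the modified residue), each retained
    independently with ``peak_keep_probability`` and perturbed by Gaussian
    relative error of scale ``mass_error_ppm``; the precursor is the segment
    mass plus the modification shift, perturbed likewise.

    ``fragment_length_scale`` optionally adds instrument realism: the
    retention probability of a fragment of ``n`` residues is multiplied by
    ``exp(-n / scale)``, emulating the terminal-biased backbone-cleavage
    coverage of intact-protein MS/MS, where long interior fragments are
    rarely observed.  ``None`` (the default) retains every fragment with the
    same probability.
    """
    if not 0.0 <= peak_keep_probability <= 1.0:
        raise ValueError("peak_keep_probability must be in [0, 1]")
    if mass_error_ppm < 0:
        raise ValueError("mass_error_ppm must be >= 0")
    segment = pf.segment(db)  # raises if inconsistent with db
    L = len(segment)
    mod = pf.modification
    seg_mod = None if mod is None else (mod.site - pf.start + 1, mod.mass_shift)
    sites = np.arange(1, L)
    shift = 0.0 if seg_mod is None else seg_mod[1]
    mod_site = 0 if seg_mod is None else seg_mod[0]
    theo_parts: list[np.ndarray] = []
    length_parts: list[np.ndarray] = []
    if "N" in ion_series:  # fragment at site c spans residues 1..c
        masses = prefix_masses(segment) + np.where(sites >= mod_site, shift, 0.0)
        theo_parts.append(masses)
        length_parts.append(sites)
    if "C" in ion_series:  # fragment at site c spans residues c+1..L
        masses = suffix_masses(segment) + np.where(sites < mod_site, shift, 0.0)
        theo_parts.append(masses)
        length_parts.append(L - sites)
    theo = np.concatenate(theo_parts) if theo_parts else np.empty(0)
    lengths = np.concatenate(length_parts) if length_parts else np.empty(0)
    rng = np.random.default_rng(seed)
    precursor = peptide_mass(segment) + (0.0 if mod is None else mod.mass_shift)
    precursor *= 1.0 + rng.normal(0.0, mass_error_ppm) * 1e-6
    p_keep = np.full(theo.shape, peak_keep_probability)
    if fragment_length_scale is not None:
        p_keep = p_keep * np.exp(-lengths / float(fragment_length_scale))
    keep = rng.random(len(theo)) < p_keep
    frags = np.asarray(theo)[keep]
    if frags.size:
        frags = frags * (1.0 + rng.normal(0.0, mass_error_ppm, frags.size) * 1e-6)
        frags = np.sort(frags[(frags > 0) & (frags < precursor)])
        # drop near-duplicate masses (two series can coincide): 1 ppm guard
        if frags.size > 1:
            dup = np.diff(frags) <= frags[1:] * 1e-6
            frags = frags[np.concatenate(([True], ~dup))]
    return DeconvolutedSpectrum(spectrum_id, precursor, frags, truth=pf)
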