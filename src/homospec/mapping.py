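"""Mapping reference-database identifications onto homologous proteins.

Two-step procedure: (1) a BLOSUM62 Smith-Waterman local search of the
identified reference segment against every homolog protein, ranked by a
Karlin-Altschul E-value with an E-value cutoff; (2) a global-local
(semi-global) alignment of the segment onto the best homolog - global in
the query, free entry/exit in the subject - whose aligned subject slice is
the homologous protein segment.  Mutation counts and positions between the
two segments are read off the alignment columns.
"""

from __future__ import annotations

import math
import weakref
from typing import Optional

import numpy as np
from Bio.Align import substitution_matrices

from ._kernels import semiglobal_fill, sw_score
from .model import AlignmentResult, ProteomeDB

_B62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = str(_B62.alphabet)
_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}
#: BLOSUM62 as a dense float matrix over the Biopython alphabet order.
BLOSUM62 = np.asarray(_B62, dtype=float)

#: Gapped BLOSUM62 (open 11, extend 1) Karlin-Altschul constants.
LAMBDA_GAPPED = 0.267
K_GAPPED = 0.041


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_INDEX[aa] for aa in seq], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise ValueError(f"letter outside BLOSUM62 alphabet: {exc}") from exc


_DB_ENCODE_CACHE: "weakref.WeakKeyDictionary" = weakref.WeakKeyDictionary()


def _encoded_db(db: ProteomeDB) -> list[tuple[str, np.ndarray]]:
    """Subjects of ``db`` as (id, encoded) pairs sorted by id, cached per
    database instance."""
    cached = _DB_ENCODE_CACHE.get(db)
    if cached is None:
        cached = [
            (rec.protein_id, _encode(rec.sequence))
            for rec in sorted(db, key=lambda r: r.protein_id)
        ]
        _DB_ENCODE_CACHE[db] = cached
    return cached


def evalue(score: float, query_len: int, db_residues: int,
           lam: float = LAMBDA_GAPPED, k: float = K_GAPPED) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    return k * query_len * db_residues * math.exp(-lam * score)


def local_search(
    query_segment: str,
    db: ProteomeDB,
    evalue_cutoff: float = 0.01,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    lam: float = LAMBDA_GAPPED,
    k: float = K_GAPPED,
) -> Optional[tuple[str, float]]:
    """Best homologous protein for a query segment, or None.

    Scores every subject by Smith-Waterman with BLOSUM62 and affine gaps
    (a length-L gap costs open + L*extend); the best subject is the one
    with the smallest E-value (ties to the lexicographically smaller id);
    returns None when the best E-value exceeds the cutoff.
    """
    if not query_segment:
        raise ValueError("empty query")
    if len(db) == 0:
        raise ValueError("empty database")
    q = _encode(query_segment)
    n_total = db.total_residues
    best_id, best_score = None, -1.0
    for pid, enc in _encoded_db(db):
        score = sw_score(q, enc, BLOSUM62, gap_open, gap_extend)
        if score > best_score:
            best_id, best_score = pid, score
    e = evalue(best_score, len(query_segment), n_total, lam, k)
    if e > evalue_cutoff:
        return None
    return best_id, e


def global_local_align(
    query_segment: str,
    subject: str,
    gap_open: float = 10.0,
    gap_extend: float = 4.0,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentResult:
    """Best global-local alignment: the query aligned end to end, the
    subject free at both ends; BLOSUM62 scoring with a length-L gap costing
    ``gap_open + L * gap_extend``.

    Traceback is deterministic with preference diagonal > up (gap in
    subject) > left (gap in query); within a gap run, closing the gap is
    preferred over extending on score ties.  The alignment end is the
    leftmost maximal cell of the final query row.
    """
    if not query_segment or not subject:
        raise ValueError("both sequences must be non-empty")
    q = _encode(query_segment)
    s = _encode(subject)
    M, X, Y, V = semiglobal_fill(q, s, BLOSUM62, gap_open, gap_extend)
    n, m = q.size, s.size
    j = int(np.argmax(V[n, :]))  # leftmost maximum
    score = float(V[n, j])
    subject_end = j

    aq: list[str] = []
    asub: list[str] = []
    i = n
    state = "M" if V[i, j] == M[i, j] else ("X" if V[i, j] == X[i, j] else "Y")
    while i > 0:
        if state == "M":
            aq.append(query_segment[i - 1])
            asub.append(subject[j - 1])
            i, j = i - 1, j - 1
            state = "M" if V[i, j] == M[i, j] else ("X" if V[i, j] == X[i, j] else "Y")
        elif state == "X":
            aq.append(query_segment[i - 1])
            asub.append("-")
            came_open = X[i, j] == V[i - 1, j] - gap_open - gap_extend
            i = i - 1
            if came_open:
                state = "M" if V[i, j] == M[i, j] else ("X" if V[i, j] == X[i, j] else "Y")
            # else stay in X
        else:  # Y
            aq.append("-")
            asub.append(subject[j - 1])
            came_open = Y[i, j] == V[i, j - 1] - gap_open - gap_extend
            j = j - 1
            if came_open:
                state = "M" if V[i, j] == M[i, j] else ("X" if V[i, j] == X[i, j] else "Y")

    result = AlignmentResult(
        query_id=query_id,
        subject_id=subject_id,
        aligned_query="".join(reversed(aq)),
        aligned_subject="".join(reversed(asub)),
        subject_start=j + 1,
        subject_end=subject_end,
        score=score,
    )
    result.identity_pct = sequence_identity(result)
    result.mutation_count = count_mutations(result)
    result.mutation_positions = mutation_positions(result)
    return result


def count_mutations(a: AlignmentResult) -> int:
    """Mutations between the aligned segments: substitution columns (both
    residues, unequal) plus gap columns, one per column (so a two-residue
    indel counts as two)."""
    return sum(
        1
        for cq, cs in zip(a.aligned_query, a.aligned_subject)
        if cq == "-" or cs == "-" or cq != cs
    )


def sequence_identity(a: AlignmentResult) -> float:
    """Percent identical columns over the full alignment length (gap
    columns count in the denominator)."""
    cols = len(a.aligned_query)
    if cols == 0:
        return 0.0
    same = sum(1 for cq, cs in zip(a.aligned_query, a.aligned_subject) if cq == cs and cq != "-")
    return 100.0 * same / cols


def mutation_positions(a: AlignmentResult) -> list[int]:
    """1-based subject positions of every mutation column; a gap in the
    subject (query insertion) is mapped to the flanking subject position on
    its left (clamped to the alignment's first subject position)."""
    out = []
    spos = a.subject_start - 1
    for cq, cs in zip(a.aligned_query, a.aligned_subject):
        if cs != "-":
            spos += 1
        if cq == "-" or cs == "-" or cq != cs:
            out.append(max(spos, a.subject_start))
    return out


def query_to_subject_map(a: AlignmentResult) -> dict[int, int]:
    """Map 1-based query positions to 1-based subject positions through the
    alignment columns; query residues opposite a subject gap inherit the
    flanking subject position on their left (clamped to the span start)."""
    out: dict[int, int] = {}
    qpos = 0
    spos = a.subject_start - 1
    for cq, cs in zip(a.aligned_query, a.aligned_subject):
        if cs != "-":
            spos += 1
        if cq != "-":
            qpos += 1
            out[qpos] = max(spos, a.subject_start)
    return out
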