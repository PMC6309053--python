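"""Correctness metrics for homolog-database identifications.

A homolog-database PrSM is judged against the mapped homologous segment of
the same spectrum's reference identification: the *correct protein* call
requires the same homolog protein, the *correct segment* call additionally
requires the identical segment string.  Spectra are binned into subgroups
G0..G4 (reference proteoform without an unknown shift, the "perfect"
group) and H0..H4 (one unknown shift, the "mass shift" group) by the
number of mutations between the reference segment and its homologous
segment; the CP and CS rates of a subgroup are the fractions of its
spectra with correct-protein and correct-segment identifications.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import AlignmentResult, EvalRecord

SUBGROUP_ORDER = [f"{g}{k}" for g in ("G", "H") for k in range(5)]


def assess_identification(
    reported_protein_id: str,
    reported_segment: str,
    expected: AlignmentResult,
) -> tuple[bool, bool]:
    """Compare a homolog-database identification with the mapped homologous
    segment: correct protein iff the same homolog protein id; correct
    segment iff additionally the segment strings are identical (string
    equality, so coordinate off-by-ones with identical sequence still
    count)."""
    correct_protein = reported_protein_id == expected.subject_id
    correct_segment = correct_protein and reported_segment == expected.subject_segment
    return correct_protein, correct_segment


def assign_subgroup(group: str, mutation_count: int) -> str:
    """Subgroup label: G{k} for the perfect group, H{k} for the mass-shift
    group, k = mutation count; spectra with five or more mutations are
    excluded."""
    if group not in ("perfect", "mass_shift"):
        raise ValueError(f"unknown group {group!r}")
    if mutation_count > 4:
        return "excluded"
    return ("G" if group == "perfect" else "H") + str(mutation_count)


def _subgroup_of(record: EvalRecord) -> str:
    return assign_subgroup(record.group, record.mutation_count)


def compute_rates(
    records: Iterable[EvalRecord], accepted_ids: Optional[set[str]] = None
) -> pd.DataFrame:
    """Per-subgroup counts and rates.

    n_t counts every spectrum in the subgroup; n_p / n_s count only spectra
    whose homolog-database search was accepted (``accepted_ids`` restricts
    the correctness flags further when given) and was correct at the
    protein / segment level.  Empty subgroups are absent from the table.
    """
    counts: dict[str, list[int]] = {}
    for rec in records:
        label = _subgroup_of(rec)
        if label == "excluded":
            continue
        n_t, n_p, n_s = counts.setdefault(label, [0, 0, 0])
        counted = accepted_ids is None or rec.spectrum_id in accepted_ids
        counts[label] = [
            n_t + 1,
            n_p + int(rec.correct_protein and counted),
            n_s + int(rec.correct_segment and counted),
        ]
    rows = []
    for label in SUBGROUP_ORDER:
        if label not in counts:
            continue
        n_t, n_p, n_s = counts[label]
        rows.append(
            {
                "subgroup": label,
                "n_t": n_t,
                "n_p": n_p,
                "n_s": n_s,
                "cp_rate": round(100.0 * n_p / n_t, 2),
                "cs_rate": round(100.0 * n_s / n_t, 2),
            }
        )
    return pd.DataFrame(rows, columns=["subgroup", "n_t", "n_p", "n_s", "cp_rate", "cs_rate"])


def assess_localization(
    reported_interval: Optional[tuple[int, int]],
    required_positions: Sequence[int],
) -> bool:
    """True iff the reported shift interval covers every required position
    (all mutation positions, plus the modification site for the mass-shift
    group), in the same segment coordinate frame.  An empty requirement is
    vacuously satisfied; a non-empty requirement with no reported interval
    is not."""
    if not required_positions:
        return True
    if reported_interval is None:
        return False
    first, last = reported_interval
    return all(first <= p <= last for p in required_positions)


def identity_histogram(
    identities: Sequence[float], bin_width: float = 5.0
) -> pd.DataFrame:
    """Histogram of sequence identities over [0, 100]: half-open bins
    [lo, lo+width) with the top bin closed at 100; counts sum to the number
    of inputs."""
    if bin_width <= 0 or bin_width > 100:
        raise ValueError("bin_width must be in (0, 100]")
    edges = np.arange(0.0, 100.0, bin_width)
    edges = np.append(edges, 100.0)
    counts, _ = np.histogram(np.asarray(identities, dtype=float), bins=edges)
    return pd.DataFrame(
        {"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts}
    )
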