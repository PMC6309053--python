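"""Core domain types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .masses import RESIDUE_MASS, prefix_mass_array


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence (reference, homolog or decoy protein)."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - set(RESIDUE_MASS)
        if bad:
            raise ValueError(f"{self.protein_id}: non-standard letters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


class ProteomeDB:
    """An ordered collection of proteins with unique ids.

    Caches per-protein cumulative-mass arrays so repeated spectral searches
    do not recompute them.
    """

    def __init__(self, records: Sequence[ProteinRecord]):
        self.records: list[ProteinRecord] = list(records)
        self.by_id: dict[str, ProteinRecord] = {}
        for rec in self.records:
            if rec.protein_id in self.by_id:
                raise ValueError(f"duplicate protein id: {rec.protein_id}")
            self.by_id[rec.protein_id] = rec
        self._prefix: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.by_id

    def sequence(self, protein_id: str) -> str:
        return self.by_id[protein_id].sequence

    def prefix_masses(self, protein_id: str) -> np.ndarray:
        arr = self._prefix.get(protein_id)
        if arr is None:
            arr = prefix_mass_array(self.by_id[protein_id].sequence)
            self._prefix[protein_id] = arr
        return arr

    @property
    def total_residues(self) -> int:
        return sum(len(r) for r in self.records)

    def concat(self, other: "ProteomeDB") -> "ProteomeDB":
        return ProteomeDB(self.records + other.records)


@dataclass(frozen=True)
class MutationEvent:
    """One residue-level difference planted between reference and homolog.

    ``ref_pos`` is 1-based in the reference protein.  A substitution replaces
    ``ref_aa`` by ``alt_aa``; a deletion removes ``ref_aa`` (``alt_aa`` empty);
    an insertion inserts ``alt_aa`` immediately before ``ref_pos`` (``ref_aa``
    empty; ``ref_pos`` may be length+1 for a C-terminal insertion).
    """

    kind: str  # substitution | insertion | deletion
    ref_pos: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        if self.kind == "substitution" and (
            not self.ref_aa or not self.alt_aa or self.ref_aa == self.alt_aa
        ):
            raise ValueError("substitution needs distinct ref_aa and alt_aa")
        if self.kind == "insertion" and (self.ref_aa or not self.alt_aa):
            raise ValueError("insertion carries alt_aa only")
        if self.kind == "deletion" and (self.alt_aa or not self.ref_aa):
            raise ValueError("deletion carries ref_aa only")


@dataclass(frozen=True)
class Modification:
    """A single localized mass shift: ``site`` is 1-based in protein coordinates."""

    site: int
    mass_shift: float
    name: str = ""


@dataclass(frozen=True)
class Proteoform:
    """A protein segment [start, end] (1-based, inclusive) with at most one
    localized modification; ``modification.site`` lies within [start, end]."""

    protein_id: str
    start: int
    end: int
    modification: Optional[Modification] = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError("invalid segment bounds")
        if self.modification is not None and not (
            self.start <= self.modification.site <= self.end
        ):
            raise ValueError("modification site outside segment")

    def segment(self, db: ProteomeDB) -> str:
        seq = db.sequence(self.protein_id)
        if self.end > len(seq):
            raise ValueError(
                f"{self.protein_id}: segment end {self.end} beyond length {len(seq)}"
            )
        return seq[self.start - 1 : self.end]


@dataclass
class DeconvolutedSpectrum:
    """A query spectrum: neutral precursor mass plus neutral fragment masses.

    ``truth`` carries the generating proteoform for synthetic data; it is
    written to a sidecar file, never into the spectrum file itself, so the
    search stage stays blind.
    """

    spectrum_id: str
    precursor_mass: float
    fragment_masses: np.ndarray
    truth: Optional[Proteoform] = None

    def __post_init__(self) -> None:
        self.fragment_masses = np.asarray(self.fragment_masses, dtype=float)
        if self.fragment_masses.size:
            if (self.fragment_masses <= 0).any():
                raise ValueError(f"{self.spectrum_id}: non-positive fragment mass")
            if (np.diff(self.fragment_masses) < 0).any():
                raise ValueError(f"{self.spectrum_id}: fragments not sorted")
            if (self.fragment_masses >= self.precursor_mass).any():
                raise ValueError(f"{self.spectrum_id}: fragment >= precursor")


@dataclass
class PrSM:
    """A proteoform-spectrum match: best segment, score (matched-fragment
    count), unknown-shift mass ``delta`` and its localization interval
    (1-based positions within the reported segment)."""

    spectrum_id: str
    protein_id: str
    start: int
    end: int
    score: int
    delta: float
    shift_interval: Optional[tuple[int, int]] = None
    is_decoy: bool = False
    accepted: bool = False

    @property
    def is_sentinel(self) -> bool:
        return self.score == 0 and not self.protein_id

    def segment(self, db: ProteomeDB) -> str:
        return db.sequence(self.protein_id)[self.start - 1 : self.end]


def sentinel_prsm(spectrum_id: str) -> PrSM:
    """The no-candidate placeholder: score 0, no protein."""
    return PrSM(spectrum_id, "", 0, 0, score=0, delta=0.0)


@dataclass
class AlignmentResult:
    """A pairwise alignment of a query segment onto (part of) a subject
    protein.  ``aligned_query``/``aligned_subject`` are equal-length gapped
    strings; subject coordinates are 1-based inclusive."""

    query_id: str
    subject_id: str
    aligned_query: str
    aligned_subject: str
    subject_start: int
    subject_end: int
    score: float
    identity_pct: float = field(default=0.0)
    mutation_count: int = field(default=0)
    mutation_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ValueError("aligned strings differ in length")

    @property
    def subject_segment(self) -> str:
        return self.aligned_subject.replace("-", "")

    @property
    def query_segment(self) -> str:
        return self.aligned_query.replace("-", "")


@dataclass
class EvalRecord:
    """Per-spectrum correctness summary used to build the rate tables."""

    spectrum_id: str
    group: str  # "perfect" | "mass_shift"
    mutation_count: int
    correct_protein: bool
    correct_segment: bool
    localization_assessed: bool = False
    localization_correct: bool = False
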