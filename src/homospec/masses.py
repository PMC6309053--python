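"""Monoisotopic mass constants and helpers.

All masses in this package are neutral monoisotopic masses in daltons, the
convention of deconvoluted top-down spectra (charge states and isotope
envelopes are assumed to have been collapsed upstream).
"""

from __future__ import annotations

import numpy as np
from pyteomics import mass as _ptmass

#: The 20 standard amino-acid one-letter codes, alphabetical.
AA20: str = "ACDEFGHIKLMNPQRSTVWY"

#: Residue (amino-acid minus water) monoisotopic masses, Da.
RESIDUE_MASS: dict[str, float] = {aa: _ptmass.std_aa_mass[aa] for aa in AA20}

#: Monoisotopic mass of water, Da.
WATER: float = _ptmass.calculate_mass(formula="H2O")

#: Monoisotopic mass of HPO3 (phosphorylation mass shift), Da.
PHOSPHO: float = _ptmass.calculate_mass(formula="HPO3")

#: A small menu of common modification mass shifts, Da.
PTM_MENU_DEFAULT: list[tuple[str, float]] = [
    ("phospho", PHOSPHO),
    ("acetyl", _ptmass.calculate_mass(formula="C2H2O")),
    ("methyl", _ptmass.calculate_mass(formula="CH2")),
    ("oxidation", _ptmass.calculate_mass(formula="O")),
]

_MASS_ARRAY = np.zeros(128)
for _aa, _m in RESIDUE_MASS.items():
    _MASS_ARRAY[ord(_aa)] = _m


def residue_masses(sequence: str) -> np.ndarray:
    """Per-residue monoisotopic masses of ``sequence`` as a float array.

    Raises ValueError on any letter outside the 20 standard codes.
    """
    codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    out = _MASS_ARRAY[codes]
    if (out == 0).any():
        bad = sorted({c for c in sequence if c not in RESIDUE_MASS})
        raise ValueError(f"non-standard residue letter(s): {bad}")
    return out


def peptide_mass(sequence: str) -> float:
    """Neutral monoisotopic mass of an unmodified peptide/protein segment."""
    return float(residue_masses(sequence).sum() + WATER)


def prefix_mass_array(sequence: str) -> np.ndarray:
    """Cumulative residue masses: P[0]=0, P[i]=mass of residues 1..i."""
    out = np.zeros(len(sequence) + 1)
    np.cumsum(residue_masses(sequence), out=out[1:])
    return out
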