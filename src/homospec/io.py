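"""File formats: FASTA proteomes, the deconvoluted-spectrum block dialect,
and the tab-separated result tables.

The spectrum file is a minimal msalign-style text format::

    BEGIN IONS
    ID=<spectrum_id>
    PRECURSOR_MASS=<Da, 5 dp>
    <neutral fragment mass, one per line, Da, 5 dp>
    END IONS

Blank lines and ``#`` comments are tolerated anywhere.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    DeconvolutedSpectrum,
    Modification,
    PrSM,
    ProteinRecord,
    ProteomeDB,
    Proteoform,
)

# ---------------------------------------------------------------- FASTA


def write_fasta(db: ProteomeDB, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(rec.sequence), id=rec.protein_id, description="")
        for rec in db
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> ProteomeDB:
    return ProteomeDB(
        [ProteinRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    )


# ------------------------------------------------------------- spectra


def write_spectra(spectra: Iterable[DeconvolutedSpectrum], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sp in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"ID={sp.spectrum_id}\n")
            fh.write(f"PRECURSOR_MASS={sp.precursor_mass:.5f}\n")
            for m in sp.fragment_masses:
                fh.write(f"{m:.5f}\n")
            fh.write("END IONS\n")


def read_spectra(path: str | Path) -> list[DeconvolutedSpectrum]:
    spectra: list[DeconvolutedSpectrum] = []
    sid: Optional[str] = None
    prec = math.nan
    frags: list[float] = []
    in_block = False
    for lineno, raw in enumerate(open(path), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "BEGIN IONS":
            if in_block:
                raise ValueError(f"{path}:{lineno}: nested BEGIN IONS")
            in_block, sid, prec, frags = True, None, math.nan, []
        elif line == "END IONS":
            if not in_block or sid is None or math.isnan(prec):
                raise ValueError(f"{path}:{lineno}: incomplete spectrum block")
            spectra.append(
                DeconvolutedSpectrum(sid, prec, np.sort(np.asarray(frags)))
            )
            in_block = False
        elif line.startswith("ID="):
            sid = line[3:]
        elif line.startswith("PRECURSOR_MASS="):
            prec = float(line.split("=", 1)[1])
        else:
            if not in_block:
                raise ValueError(f"{path}:{lineno}: mass outside BEGIN/END block")
            frags.append(float(line))
    if in_block:
        raise ValueError(f"{path}: unterminated spectrum block")
    return spectra


# ------------------------------------------------------- truth sidecar


def write_truth(spectra: Iterable[DeconvolutedSpectrum], path: str | Path) -> None:
    rows = []
    for sp in spectra:
        pf = sp.truth
        if pf is None:
            continue
        mod = pf.modification
        rows.append(
            {
                "spectrum_id": sp.spectrum_id,
                "protein_id": pf.protein_id,
                "start": pf.start,
                "end": pf.end,
                "mod_site": 0 if mod is None else mod.site,
                "mod_mass": 0.0 if mod is None else mod.mass_shift,
            }
        )
    df = pd.DataFrame(
        rows, columns=["spectrum_id", "protein_id", "start", "end", "mod_site", "mod_mass"]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.5f")


def read_truth(path: str | Path) -> dict[str, Proteoform]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, Proteoform] = {}
    for row in df.itertuples(index=False):
        mod = None
        if int(row.mod_site) != 0:
            mod = Modification(int(row.mod_site), float(row.mod_mass))
        out[str(row.spectrum_id)] = Proteoform(
            str(row.protein_id), int(row.start), int(row.end), mod
        )
    return out


# ----------------------------------------------------------- PrSM TSV

PRSM_COLUMNS = [
    "spectrum_id",
    "protein_id",
    "start",
    "end",
    "score",
    "delta",
    "shift_first",
    "shift_last",
    "is_decoy",
    "accepted",
]


def prsm_frame(prsms: Iterable[PrSM]) -> pd.DataFrame:
    rows = []
    for p in prsms:
        first, last = p.shift_interval if p.shift_interval else (0, 0)
        rows.append(
            {
                "spectrum_id": p.spectrum_id,
                "protein_id": p.protein_id,
                "start": p.start,
                "end": p.end,
                "score": p.score,
                "delta": round(p.delta, 5),
                "shift_first": first,
                "shift_last": last,
                "is_decoy": int(p.is_decoy),
                "accepted": int(p.accepted),
            }
        )
    return pd.DataFrame(rows, columns=PRSM_COLUMNS)


def write_prsms(prsms: Iterable[PrSM], path: str | Path) -> None:
    prsm_frame(prsms).to_csv(path, sep="\t", index=False, float_format="%.5f")


def read_prsms(path: str | Path) -> list[PrSM]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        interval = None
        if int(row.shift_first) != 0 or int(row.shift_last) != 0:
            interval = (int(row.shift_first), int(row.shift_last))
        out.append(
            PrSM(
                spectrum_id=str(row.spectrum_id),
                protein_id=str(row.protein_id),
                start=int(row.start),
                end=int(row.end),
                score=int(row.score),
                delta=float(row.delta),
                shift_interval=interval,
                is_decoy=bool(int(row.is_decoy)),
                accepted=bool(int(row.accepted)),
            )
        )
    return out
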