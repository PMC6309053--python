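"""End-to-end benchmark: simulate -> search both databases -> map -> evaluate.

The experiment mirrors the two-database design: synthetic spectra are
searched against the reference proteome (with its shuffled decoys) and
against the homolog proteome (with its own decoys); accepted reference
identifications are mapped onto homologous segments by local search plus
global-local alignment; correctness metrics are computed per mutation-count
subgroup.  A single global seed is fanned out to per-stage child seeds by
hashing the stage name, so rerunning a stage in isolation is reproducible
and rerunning the whole experiment is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from . import mapping as mp
from .io import (
    write_fasta,
    write_prsms,
    write_spectra,
    write_truth,
)
from .masses import AA20, PTM_MENU_DEFAULT
from .matching import (
    SearchConfig,
    build_decoy_db,
    fdr_threshold,
    filter_fdr,
    search_database,
)
from .model import (
    AlignmentResult,
    DeconvolutedSpectrum,
    EvalRecord,
    PrSM,
    ProteomeDB,
    Proteoform,
)
from .synthetic import (
    generate_reference_proteome,
    mutate_proteome,
    sample_proteoforms,
    simulate_spectrum,
)

log = logging.getLogger("homospec")


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed derived from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def mutation_type_count(alphabet: Sequence[str] = AA20) -> int:
    """Number of ordered substitution types the mutation sampler supports:
    every residue can mutate to any of the other letters."""
    n = len(set(alphabet))
    return n * (n - 1)


@dataclass
class PipelineConfig:
    """Study conditions and search/alignment parameters of one experiment."""

    seed: int = 42
    # synthetic proteomes: one bin of proteins per planted mutation count
    proteins_per_bin: int = 20
    mutation_bins: tuple[int, ...] = (0, 1, 2, 3, 4)
    protein_length: tuple[int, int] = (80, 160)
    indel_fraction: float = 0.2
    mutation_window: tuple[float, float] = (0.1, 0.9)
    # proteoforms and spectra: per (mutation bin, group) subgroup
    spectra_per_subgroup: int = 200
    # which proteoform groups to simulate (perfect = no modification,
    # mass_shift = exactly one)
    groups: tuple[str, ...] = ("perfect", "mass_shift")
    # spectra of proteins absent from both databases (unidentifiable
    # background, as in real runs where many spectra match nothing); these
    # let decoys win best-per-spectrum matches and anchor the FDR threshold
    background_spectra: int = 1000
    truncation: tuple[float, float] = (0.2, 0.2)
    min_segment_length: int = 15
    ptm_menu: tuple[tuple[str, float], ...] = tuple(PTM_MENU_DEFAULT)
    dropout: float = 0.3
    # terminal-biased fragment observability: retention of an n-residue
    # fragment is further scaled by exp(-n / fragment_length_scale),
    # emulating the poor interior coverage of intact-protein MS/MS
    fragment_length_scale: Optional[float] = 70.0
    # per-spectrum fragmentation quality: each spectrum's retention is
    # additionally scaled by a factor drawn uniformly from this range,
    # emulating the wide spread of fragment counts in real runs (where a
    # large share of spectra are too peak-poor for confident identification)
    spectrum_quality: tuple[float, float] = (0.15, 1.0)
    mass_error_ppm: float = 0.0
    ion_series: tuple[str, ...] = ("N", "C")
    # search stage
    tol_ppm: float = 15.0
    fdr_level: float = 0.01
    max_delta: float = 500.0
    max_trim_fraction: float = 0.25
    min_search_length: int = 10
    # mapping stage
    evalue_cutoff: float = 0.01
    local_gap: tuple[float, float] = (11.0, 1.0)
    global_local_gap: tuple[float, float] = (10.0, 4.0)
    # reporting
    hist_bin_width: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_level <= 1.0:
            raise ValueError("fdr_level must be in (0, 1]")
        if min(self.tol_ppm, self.max_delta, self.evalue_cutoff) <= 0:
            raise ValueError("thresholds must be positive")

    def search_config(self) -> SearchConfig:
        return SearchConfig(
            tol_ppm=self.tol_ppm,
            max_delta=self.max_delta,
            max_start_trim_fraction=self.max_trim_fraction,
            max_end_trim_fraction=self.max_trim_fraction,
            min_segment_length=self.min_search_length,
            ion_series=tuple(self.ion_series),
        )

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["ptm_menu"] = [list(item) for item in self.ptm_menu]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = dict(data)
        for key in (
            "mutation_bins", "protein_length", "mutation_window", "truncation",
            "ion_series", "local_gap", "global_local_gap", "spectrum_quality",
            "groups",
        ):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        if "ptm_menu" in kwargs and kwargs["ptm_menu"] is not None:
            kwargs["ptm_menu"] = tuple(
                (str(n), float(m)) for n, m in kwargs["ptm_menu"]
            )
        return cls(**kwargs)


# ------------------------------------------------------------- stages


def simulate_stage(cfg: PipelineConfig):
    """Generate reference and homolog proteomes, proteoforms and spectra.

    Proteins are organised in bins of ``proteins_per_bin``; the proteins of
    bin k carry exactly k planted mutations, restricted to the central
    ``mutation_window`` fraction of the protein.  For each bin a perfect
    subgroup (no modification) and a mass-shift subgroup (exactly one
    modification) of spectra is simulated, plus unidentifiable background
    spectra from a contaminant proteome absent from both databases.
    """
    bins = cfg.mutation_bins
    n_proteins = cfg.proteins_per_bin * len(bins)
    ref = generate_reference_proteome(
        n_proteins, cfg.protein_length, child_seed(cfg.seed, "reference")
    )
    bin_of = {
        rec.protein_id: bins[i // cfg.proteins_per_bin]
        for i, rec in enumerate(ref)
    }
    hom, events = mutate_proteome(
        ref,
        bin_of,
        indel_fraction=cfg.indel_fraction,
        seed=child_seed(cfg.seed, "mutate"),
        position_window=cfg.mutation_window,
    )
    q_lo, q_hi = cfg.spectrum_quality
    spectra: list[DeconvolutedSpectrum] = []
    for k in bins:
        bin_ids = [pid for pid, b in bin_of.items() if b == k]
        group_specs = {"perfect": ("G", 0.0), "mass_shift": ("H", 1.0)}
        for group in cfg.groups:
            letter, ptm_p = group_specs[group]
            pfs = sample_proteoforms(
                ref,
                cfg.spectra_per_subgroup,
                truncation_model=cfg.truncation,
                ptm_menu=list(cfg.ptm_menu),
                ptm_probability=ptm_p,
                seed=child_seed(cfg.seed, f"proteoforms:{letter}{k}"),
                min_length=cfg.min_segment_length,
                protein_ids=bin_ids,
            )
            q_rng = np.random.default_rng(child_seed(cfg.seed, f"quality:{letter}{k}"))
            for i, pf in enumerate(pfs):
                sid = f"Q{letter}{k}_{i:04d}"
                quality = q_lo + (q_hi - q_lo) * q_rng.random()
                spectra.append(
                    simulate_spectrum(
                        pf,
                        ref,
                        ion_series=tuple(cfg.ion_series),
                        peak_keep_probability=(1.0 - cfg.dropout) * quality,
                        mass_error_ppm=cfg.mass_error_ppm,
                        seed=child_seed(cfg.seed, f"spectrum:{sid}"),
                        spectrum_id=sid,
                        fragment_length_scale=cfg.fragment_length_scale,
                    )
                )
    if cfg.background_spectra > 0:
        contaminants = generate_reference_proteome(
            max(5, cfg.proteins_per_bin * len(bins) // 2),
            cfg.protein_length,
            child_seed(cfg.seed, "background"),
            id_prefix="BG",
        )
        pfs = sample_proteoforms(
            contaminants,
            cfg.background_spectra,
            truncation_model=cfg.truncation,
            ptm_menu=list(cfg.ptm_menu),
            ptm_probability=0.5,
            seed=child_seed(cfg.seed, "proteoforms:background"),
            min_length=cfg.min_segment_length,
        )
        q_rng = np.random.default_rng(child_seed(cfg.seed, "quality:background"))
        for i, pf in enumerate(pfs):
            sid = f"QBG_{i:04d}"
            quality = q_lo + (q_hi - q_lo) * q_rng.random()
            spectra.append(
                simulate_spectrum(
                    pf,
                    contaminants,
                    ion_series=tuple(cfg.ion_series),
                    peak_keep_probability=(1.0 - cfg.dropout) * quality,
                    mass_error_ppm=cfg.mass_error_ppm,
                    seed=child_seed(cfg.seed, f"spectrum:{sid}"),
                    spectrum_id=sid,
                    fragment_length_scale=cfg.fragment_length_scale,
                )
            )
    return ref, hom, events, spectra


def search_stage(
    spectra: Sequence[DeconvolutedSpectrum],
    db: ProteomeDB,
    cfg: PipelineConfig,
    decoy_seed: int,
):
    """Search every spectrum against target + shuffled decoys, take the
    best PrSM per spectrum, and filter at the spectrum-level FDR."""
    decoys = build_decoy_db(db, decoy_seed)
    combined = db.concat(decoys)
    scfg = cfg.search_config()
    prsms = [search_database(sp, combined, scfg) for sp in spectra]
    accepted = filter_fdr(prsms, cfg.fdr_level)
    stats = fdr_threshold(prsms, cfg.fdr_level)
    return prsms, accepted, stats


def map_stage(
    accepted_ref: Sequence[PrSM],
    ref_db: ProteomeDB,
    hom_db: ProteomeDB,
    cfg: PipelineConfig,
) -> dict[str, tuple[AlignmentResult, float]]:
    """Map each accepted reference PrSM's segment to its homologous segment:
    local search for the best homolog protein (E-value cutoff), then a
    global-local alignment onto it.  Spectra without a homolog hit are
    excluded (logged, not silently dropped)."""
    go_l, ge_l = cfg.local_gap
    go_g, ge_g = cfg.global_local_gap
    out: dict[str, tuple[AlignmentResult, float]] = {}
    n_no_hit = 0
    for prsm in accepted_ref:
        segment = prsm.segment(ref_db)
        hit = mp.local_search(
            segment, hom_db, evalue_cutoff=cfg.evalue_cutoff,
            gap_open=go_l, gap_extend=ge_l,
        )
        if hit is None:
            n_no_hit += 1
            continue
        subject_id, e = hit
        aln = mp.global_local_align(
            segment,
            hom_db.sequence(subject_id),
            gap_open=go_g,
            gap_extend=ge_g,
            query_id=prsm.spectrum_id,
            subject_id=subject_id,
        )
        out[prsm.spectrum_id] = (aln, e)
    log.info("mapping: %d mapped, %d without homolog hit", len(out), n_no_hit)
    return out


def evaluate_stage(
    accepted_ref: Sequence[PrSM],
    mappings: dict[str, tuple[AlignmentResult, float]],
    hom_prsms: Sequence[PrSM],
    hom_db: ProteomeDB,
    truth: dict[str, Proteoform],
    cfg: PipelineConfig,
) -> list[EvalRecord]:
    """Build the per-spectrum correctness records.

    The group (perfect vs mass-shift) is read from the reference PrSM's
    unknown-shift mass; the mutation count from the mapped alignment; the
    correctness calls from the homolog-database PrSM of the same spectrum.
    Localization is assessed on correct-segment PrSMs: the reported shift
    interval must cover every mutation position and, for the mass-shift
    group, the planted modification site projected through the alignment.
    """
    hom_by_id = {p.spectrum_id: p for p in hom_prsms if p.accepted}
    records: list[EvalRecord] = []
    for prsm in accepted_ref:
        pair = mappings.get(prsm.spectrum_id)
        if pair is None:
            continue  # excluded: no homolog mapping (already logged)
        aln, _ = pair
        group = "mass_shift" if prsm.delta != 0.0 else "perfect"
        kmut = aln.mutation_count
        hom_prsm = hom_by_id.get(prsm.spectrum_id)
        if hom_prsm is None:
            cp, cs = False, False
        else:
            cp, cs = ev.assess_identification(
                hom_prsm.protein_id, hom_prsm.segment(hom_db), aln
            )
        rec = EvalRecord(
            spectrum_id=prsm.spectrum_id,
            group=group,
            mutation_count=kmut,
            correct_protein=cp,
            correct_segment=cs,
        )
        if cs and (kmut >= 1 or group == "mass_shift"):
            rec.localization_assessed = True
            required = [
                p - aln.subject_start + 1 for p in aln.mutation_positions
            ]
            projectable = True
            if group == "mass_shift":
                pf = truth.get(prsm.spectrum_id)
                site = None
                if pf is not None and pf.modification is not None:
                    qpos = pf.modification.site - prsm.start + 1
                    site = mp.query_to_subject_map(aln).get(qpos)
                if site is None:
                    projectable = False
                else:
                    required.append(site - aln.subject_start + 1)
            rec.localization_correct = projectable and ev.assess_localization(
                hom_prsm.shift_interval if hom_prsm else None, required
            )
        records.append(rec)
    return records


def _localization_accuracy(records: Sequence[EvalRecord], group: str) -> tuple[int, int]:
    """(#correct, #assessed) over subgroups with >= 1 mutation of a group."""
    sel = [
        r
        for r in records
        if r.group == group and r.localization_assessed and 1 <= r.mutation_count <= 4
    ]
    return sum(r.localization_correct for r in sel), len(sel)


@dataclass
class RunSummary:
    """What one experiment produced, with the paths of its artifacts."""

    rates: pd.DataFrame
    records: list[EvalRecord]
    identity_histogram: pd.DataFrame
    n_spectra: int
    n_ref_accepted: int
    n_hom_accepted: int
    n_mapped: int
    ref_fdr: "object"
    hom_fdr: "object"
    loc_perfect: tuple[int, int] = (0, 0)
    loc_mass_shift: tuple[int, int] = (0, 0)
    paths: dict[str, Path] = field(default_factory=dict)


def run_experiment(cfg: PipelineConfig, outdir: str | Path) -> RunSummary:
    """Run the full benchmark and write all artifacts into ``outdir``.

    Emits: reference.fasta, homolog.fasta, spectra.ms, truth.tsv,
    prsm_reference.tsv, prsm_homolog.tsv, mapping.tsv, eval.tsv, rates.tsv,
    identity_histogram.tsv, config.yaml and run.log.  Rerunning with the
    same config is bit-identical.  On failure, partial outputs are removed
    and the exception propagates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        name: outdir / fname
        for name, fname in [
            ("reference", "reference.fasta"),
            ("homolog", "homolog.fasta"),
            ("spectra", "spectra.ms"),
            ("truth", "truth.tsv"),
            ("prsm_reference", "prsm_reference.tsv"),
            ("prsm_homolog", "prsm_homolog.tsv"),
            ("mapping", "mapping.tsv"),
            ("eval", "eval.tsv"),
            ("rates", "rates.tsv"),
            ("identity_histogram", "identity_histogram.tsv"),
            ("config", "config.yaml"),
            ("log", "run.log"),
        ]
    }
    handler = logging.FileHandler(paths["log"], mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        cfg.to_yaml(paths["config"])
        ref, hom, _events, spectra = simulate_stage(cfg)
        log.info(
            "simulate: %d reference proteins, %d homolog proteins, %d spectra",
            len(ref), len(hom), len(spectra),
        )
        write_fasta(ref, paths["reference"])
        write_fasta(hom, paths["homolog"])
        write_spectra(spectra, paths["spectra"])
        write_truth(spectra, paths["truth"])
        truth = {sp.spectrum_id: sp.truth for sp in spectra if sp.truth is not None}

        ref_prsms, ref_accepted, ref_stats = search_stage(
            spectra, ref, cfg, child_seed(cfg.seed, "decoy:reference")
        )
        log.info(
            "reference search: %d/%d accepted at FDR %.2g (tau=%s, decoys over tau=%d)",
            len(ref_accepted), len(spectra), cfg.fdr_level,
            ref_stats.threshold, ref_stats.n_decoy,
        )
        write_prsms(ref_prsms, paths["prsm_reference"])

        hom_prsms, hom_accepted, hom_stats = search_stage(
            spectra, hom, cfg, child_seed(cfg.seed, "decoy:homolog")
        )
        log.info(
            "homolog search: %d/%d accepted at FDR %.2g (tau=%s, decoys over tau=%d)",
            len(hom_accepted), len(spectra), cfg.fdr_level,
            hom_stats.threshold, hom_stats.n_decoy,
        )
        write_prsms(hom_prsms, paths["prsm_homolog"])

        mappings = map_stage(ref_accepted, ref, hom, cfg)
        _write_mapping_tsv(ref_accepted, mappings, paths["mapping"])

        records = evaluate_stage(
            ref_accepted, mappings, hom_prsms, hom, truth, cfg
        )
        n_excluded = sum(
            1 for r in records if ev.assign_subgroup(r.group, r.mutation_count) == "excluded"
        )
        log.info(
            "evaluate: %d records, %d excluded (more than 4 mutations)",
            len(records), n_excluded,
        )
        _write_eval_tsv(records, paths["eval"])
        rates = ev.compute_rates(records)
        rates.to_csv(paths["rates"], sep="\t", index=False, float_format="%.2f")

        identities = _protein_identities(ref, hom, cfg)
        hist = ev.identity_histogram(identities, cfg.hist_bin_width)
        hist.to_csv(paths["identity_histogram"], sep="\t", index=False, float_format="%.1f")

        loc_g = _localization_accuracy(records, "perfect")
        loc_h = _localization_accuracy(records, "mass_shift")
        log.info(
            "localization: perfect %d/%d, mass shift %d/%d",
            loc_g[0], loc_g[1], loc_h[0], loc_h[1],
        )
        return RunSummary(
            rates=rates,
            records=records,
            identity_histogram=hist,
            n_spectra=len(spectra),
            n_ref_accepted=len(ref_accepted),
            n_hom_accepted=len(hom_accepted),
            n_mapped=len(mappings),
            ref_fdr=ref_stats,
            hom_fdr=hom_stats,
            loc_perfect=loc_g,
            loc_mass_shift=loc_h,
            paths=paths,
        )
    except Exception:
        for p in paths.values():
            if p != paths["log"] and p.exists():
                p.unlink()
        raise
    finally:
        log.removeHandler(handler)
        handler.close()


def _protein_identities(
    ref: ProteomeDB, hom: ProteomeDB, cfg: PipelineConfig
) -> list[float]:
    """Reference-protein-to-homolog sequence identities (one per mapped
    reference protein), for the identity histogram."""
    go_l, ge_l = cfg.local_gap
    go_g, ge_g = cfg.global_local_gap
    out = []
    for rec in ref:
        hit = mp.local_search(
            rec.sequence, hom, evalue_cutoff=cfg.evalue_cutoff,
            gap_open=go_l, gap_extend=ge_l,
        )
        if hit is None:
            continue
        aln = mp.global_local_align(
            rec.sequence, hom.sequence(hit[0]), gap_open=go_g, gap_extend=ge_g
        )
        out.append(aln.identity_pct)
    return out


def _write_mapping_tsv(accepted_ref, mappings, path: Path) -> None:
    ref_by_id = {p.spectrum_id: p for p in accepted_ref}
    rows = []
    for sid in sorted(mappings):
        aln, e = mappings[sid]
        rows.append(
            {
                "spectrum_id": sid,
                "ref_protein_id": ref_by_id[sid].protein_id,
                "homolog_protein_id": aln.subject_id,
                "homolog_start": aln.subject_start,
                "homolog_end": aln.subject_end,
                "homolog_segment": aln.subject_segment,
                "identity_pct": round(aln.identity_pct, 1),
                "mutation_count": aln.mutation_count,
                "mutation_positions": ",".join(map(str, aln.mutation_positions)),
                "evalue": f"{e:.1e}",
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "spectrum_id", "ref_protein_id", "homolog_protein_id",
            "homolog_start", "homolog_end", "homolog_segment",
            "identity_pct", "mutation_count", "mutation_positions", "evalue",
        ],
    ).to_csv(path, sep="\t", index=False)


def _write_eval_tsv(records: Sequence[EvalRecord], path: Path) -> None:
    rows = [
        {
            "spectrum_id": r.spectrum_id,
            "group": r.group,
            "subgroup": ev.assign_subgroup(r.group, r.mutation_count),
            "mutation_count": r.mutation_count,
            "correct_protein": int(r.correct_protein),
            "correct_segment": int(r.correct_segment),
            "localization_assessed": int(r.localization_assessed),
            "localization_correct": int(r.localization_correct),
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=[
            "spectrum_id", "group", "subgroup", "mutation_count",
            "correct_protein", "correct_segment",
            "localization_assessed", "localization_correct",
        ],
    ).to_csv(path, sep="\t", index=False)
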