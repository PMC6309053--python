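"""Identify a modified proteoform from a spectrum with one unknown shift.

Simulates a small proteome, produces the deconvoluted spectrum of a
phosphorylated, truncated proteoform, and searches it against the proteome
plus shuffled decoys.  The search does not know the modification: it
reports the best segment, the unexplained mass delta, and the residue
interval the shift could occupy.
"""

from homospec import (
    PHOSPHO,
    SearchConfig,
    build_decoy_db,
    generate_reference_proteome,
    sample_proteoforms,
    search_database,
    simulate_spectrum,
)

db = generate_reference_proteome(10, (60, 120), seed=8)
pf = sample_proteoforms(
    db, 1, truncation_model=(0.1, 0.1),
    ptm_menu=[("phospho", PHOSPHO)], ptm_probability=1.0, seed=5,
)[0]
print(f"truth:  {pf.protein_id} [{pf.start}, {pf.end}], "
      f"phospho at {pf.modification.site} (+{pf.modification.mass_shift:.5f} Da)")

spectrum = simulate_spectrum(pf, db, peak_keep_probability=0.8, seed=3)
print(f"spectrum: precursor {spectrum.precursor_mass:.3f} Da, "
      f"{spectrum.fragment_masses.size} fragment masses")

combined = db.concat(build_decoy_db(db, seed=1))
prsm = search_database(spectrum, combined, SearchConfig())
print(f"found:  {prsm.protein_id} [{prsm.start}, {prsm.end}], "
      f"score {prsm.score}, delta {prsm.delta:.5f} Da, "
      f"shift localized to segment positions {prsm.shift_interval}")
print("The delta recovers the planted phospho mass and the interval "
      "brackets the true site.")
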