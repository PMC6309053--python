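"""Map a reference protein segment onto its homolog and count mutations.

Derives a homologous proteome by planting three mutations in a reference
protein, then runs the two-step mapping: a BLOSUM62 local search with an
E-value cutoff to find the homologous protein, followed by a global-local
alignment (gap open 10, extend 4) whose aligned subject slice is the
homologous segment.  Mutation count and sequence identity come straight
off the alignment columns.
"""

from homospec import (
    generate_reference_proteome,
    global_local_align,
    local_search,
    mutate_proteome,
)

ref = generate_reference_proteome(5, (80, 120), seed=21)
hom, events = mutate_proteome(ref, 3, indel_fraction=0.3, seed=22)
query = ref.records[0]
print("planted on", query.protein_id, ":",
      [(e.kind, e.ref_pos) for e in events[query.protein_id]])

segment = query.sequence[9:70]  # a truncated proteoform segment
hit = local_search(segment, hom, evalue_cutoff=0.01)
print(f"local search: best homolog {hit[0]}, E = {hit[1]:.2e}")

aln = global_local_align(segment, hom.sequence(hit[0]))
print(f"global-local: subject span [{aln.subject_start}, {aln.subject_end}], "
      f"identity {aln.identity_pct:.1f}%, "
      f"{aln.mutation_count} mutation(s) at {aln.mutation_positions}")
print(aln.aligned_query)
print("".join("|" if a == b else " " for a, b in zip(aln.aligned_query, aln.aligned_subject)))
print(aln.aligned_subject)
print("Mutations planted inside the segment are recovered as substitution "
      "or gap columns; those outside the segment do not appear.")
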