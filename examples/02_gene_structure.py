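"""Intron phases and the diagnostic phase-0 intron of IQD genes.

Generates a small synthetic family, extracts each IQD gene's structure
and verifies the phase-0 intron between IQ67-domain codons 16 and 17 —
the second hallmark of the family besides the motif grammar.
"""

from iqdfam.domains import call_iq67_domains
from iqdfam.io import extract_cds, translate_cds
from iqdfam.simulate import FamilySpec, generate_family_genome
from iqdfam.structure import (
    compare_pair_structures,
    has_conserved_iq67_intron,
    intron_phases,
)

genome, annotation, truth = generate_family_genome(FamilySpec(seed=4))
chroms = {r.id: r for r in genome}

for gid in sorted(truth.domain_locations):
    gene = annotation.by_id(gid)
    protein = translate_cds(extract_cds(gene, chroms[gene.chromosome]))
    domain = call_iq67_domains(protein)[0]
    phases = [r.phase for r in intron_phases(gene)]
    conserved = has_conserved_iq67_intron(gene, domain)
    print(f"{gid}: phases {phases}, IQ67 16/17 phase-0 intron: {conserved}")

(a, b), _ = next(iter(truth.pair_types.items()))
cmp = compare_pair_structures(annotation.by_id(a), annotation.by_id(b))
print(f"{a} vs {b}: {cmp.verdict} (phase vectors {cmp.phase_vectors})")
# 'conserved' means identical intron phases — the usual outcome for young
# duplicates; a single-intron difference would flag a gain/loss candidate.
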