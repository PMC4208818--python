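"""Intron-phase analysis and paralog structure comparison.

Intron phase is defined on the coding sequence only: phase 0 falls exactly
between two codons, phase 1 after the first nucleotide of a codon, phase 2
after the second.  The diagnostic feature of IQD genes is a phase-0 intron
interrupting codons 16 and 17 of the IQ67 domain.
"""

from __future__ import annotations

from dataclasses import dataclass

from .domains import IQ67Domain
from .io import GeneModel


@dataclass(frozen=True)
class IntronRecord:
    """An intron between consecutive CDS segments, in transcription order."""

    index: int
    cds_offset: int  # nt of coding sequence upstream of the intron
    phase: int

    @property
    def interrupted_codon(self) -> int:
        """Codon the intron falls after (phase 0) or within (phase 1/2)."""
        if self.phase == 0:
            return self.cds_offset // 3
        return -(-self.cds_offset // 3)  # ceil


@dataclass
class StructureComparison:
    gene_a: str
    gene_b: str
    exon_counts: tuple[int, int]
    phase_vectors: tuple[tuple[int, ...], tuple[int, ...]]
    verdict: str  # conserved | gain_loss_candidate | divergent


def intron_phases(gene: GeneModel) -> list[IntronRecord]:
    """Phase of every intron separating consecutive CDS segments.

    Phases are computed from cumulative coding length walked in
    transcription order, so the result is strand-invariant.
    """
    if not gene.cds_segments:
        raise ValueError(f"gene {gene.gene_id} has no CDS segments")
    if gene.cds_length % 3:
        raise ValueError(
            f"gene {gene.gene_id}: CDS length {gene.cds_length} not divisible by 3"
        )
    segments = gene.cds_segments
    if gene.strand == "-":
        segments = segments[::-1]
    records = []
    offset = 0
    for i, (s, e) in enumerate(segments[:-1]):
        offset += e - s
        records.append(IntronRecord(index=i, cds_offset=offset, phase=offset % 3))
    return records


def has_conserved_iq67_intron(gene: GeneModel, domain: IQ67Domain) -> bool:
    """True iff a phase-0 intron falls exactly between domain codons 16/17.

    ``domain`` must have been called on the gene's translated CDS; the
    required coding offset is 3*(domain_start_codon - 1 + 16).
    """
    n_codons = gene.cds_length // 3
    if domain.end > n_codons:
        raise ValueError(
            f"domain ({domain.start},{domain.end}) outside the translation of "
            f"{gene.gene_id} ({n_codons} codons incl. stop)"
        )
    required = 3 * (domain.start - 1 + 16)
    return any(
        r.phase == 0 and r.cds_offset == required for r in intron_phases(gene)
    )


def _edit_distance_one(a: tuple[int, ...], b: tuple[int, ...]) -> bool:
    """True when b equals a with a single element inserted or deleted."""
    if abs(len(a) - len(b)) != 1:
        return False
    longer, shorter = (a, b) if len(a) > len(b) else (b, a)
    for i in range(len(longer)):
        if longer[:i] + longer[i + 1 :] == shorter:
            return True
    return False


def compare_pair_structures(a: GeneModel, b: GeneModel) -> StructureComparison:
    """Compare two paralogs' exon/intron architectures.

    conserved: identical phase vectors (hence equal exon counts);
    gain_loss_candidate: one vector is the other with one intron inserted or
    deleted; divergent: anything else.
    """
    pa = tuple(r.phase for r in intron_phases(a))
    pb = tuple(r.phase for r in intron_phases(b))
    if pa == pb:
        verdict = "conserved"
    elif _edit_distance_one(pa, pb):
        verdict = "gain_loss_candidate"
    else:
        verdict = "divergent"
    return StructureComparison(
        gene_a=a.gene_id,
        gene_b=b.gene_id,
        exon_counts=(len(a.cds_segments), len(b.cds_segments)),
        phase_vectors=(pa, pb),
        verdict=verdict,
    )
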