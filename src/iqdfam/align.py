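"""Thin pairwise-alignment helpers over Bio.Align.

Multiple alignment is deliberately not implemented here: pipelines should
feed externally computed alignments.  These helpers cover the pairwise
needs of the Ka/Ks and synteny stages and the synthetic test fixtures.
"""

from __future__ import annotations

from Bio import Align
from Bio.Align import substitution_matrices

from .io import SeqRecord


def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def global_protein_alignment(a: SeqRecord, b: SeqRecord) -> tuple[str, str]:
    """Needleman–Wunsch global alignment (BLOSUM62, affine gaps)."""
    aln = _aligner("global").align(a.sequence, b.sequence)[0]
    rows = str(aln).splitlines()
    # Biopython's formatted alignment: target / match / query rows; use
    # the indices API instead to stay robust across formats.
    seq_a, seq_b = aln[0], aln[1]
    return str(seq_a), str(seq_b)


def local_alignment_score(a: SeqRecord, b: SeqRecord) -> float:
    """Smith–Waterman local alignment score (BLOSUM62, affine gaps)."""
    return float(_aligner("local").score(a.sequence, b.sequence))
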