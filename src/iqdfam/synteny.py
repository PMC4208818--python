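"""Microsynteny detection around anchor gene pairs.

A synteny block is a pair of chromosomal segments (100-kb flanks around
two anchor genes) sharing three or more conserved homolog pairs, the
anchor pair included by default.  Homology is gated by a Smith–Waterman
score threshold (BLOSUM62, affine gaps) standing in for a BLASTP E-value
cutoff; the default threshold is calibrated on a random-protein null so
unrelated proteins essentially never pass.  A block is flagged as arising
from a large-scale duplication when five or more flanking (non-anchor)
protein-coding gene pairs are reciprocal best non-self matches.

Synteny quality of a block is 100 * 2P / (Ga + Gb), where P is the number
of conserved pairs and Ga, Gb the gene counts of the two segments after
excluding retroelements/transposons and collapsing tandem arrays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import local_alignment_score
from .duplication import is_tandem_pair
from .io import Annotation, GeneModel, SeqRecord

logger = logging.getLogger("iqdfam")

#: Default homology score gate; calibrated on a seeded random-protein null
#: (200-aa random pairs score well below this; see docs/methods.md).
DEFAULT_SCORE_THRESHOLD = 60.0
DEFAULT_WINDOW_BP = 100_000
MIN_CONSERVED_PAIRS = 3
LARGE_SCALE_MIN_FLANKING = 5


@dataclass(frozen=True)
class HomologMatch:
    gene_a: str
    gene_b: str
    score: float
    is_best_non_self: bool  # reciprocal best non-self match


@dataclass
class SyntenyBlock:
    anchor_pair: tuple[str, str]
    segment_a: tuple[str, int, int]
    segment_b: tuple[str, int, int]
    genes_a: list[str]
    genes_b: list[str]
    conserved_pairs: list[HomologMatch]
    orientation: str  # same | inverted
    large_scale: bool = False
    quality_pct: float = 0.0


def match_homologs(
    genes_a: dict[str, SeqRecord],
    genes_b: dict[str, SeqRecord],
    threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> list[HomologMatch]:
    """Best non-self partner in B for every gene in A.

    A match is reported when the local-alignment score reaches the
    threshold; ``is_best_non_self`` marks reciprocal consistency (A's best
    in B also picks A back).  Genes sharing an id are never matched to
    themselves.
    """
    if not genes_a or not genes_b:
        logger.warning("match_homologs called with an empty gene set")
        return []
    scores: dict[tuple[str, str], float] = {}
    for ida, prot_a in genes_a.items():
        for idb, prot_b in genes_b.items():
            if ida == idb:
                continue
            scores[(ida, idb)] = local_alignment_score(prot_a, prot_b)

    def best_partner(idx: str, forward: bool) -> str | None:
        pool = [
            (s, pair[1] if forward else pair[0])
            for pair, s in scores.items()
            if (pair[0] if forward else pair[1]) == idx
        ]
        if not pool:
            return None
        # highest score, ties to the alphabetically first partner
        return min(pool, key=lambda t: (-t[0], t[1]))[1]

    matches = []
    for ida in sorted(genes_a):
        idb = best_partner(ida, forward=True)
        if idb is None:
            continue
        score = scores[(ida, idb)]
        if score < threshold:
            continue
        reciprocal = best_partner(idb, forward=False) == ida
        matches.append(HomologMatch(ida, idb, score, reciprocal))
    return matches


def segment_genes(
    anchor: GeneModel,
    annotation: Annotation,
    window: int = DEFAULT_WINDOW_BP,
    collapse_threshold: float = DEFAULT_SCORE_THRESHOLD,
    proteome: dict[str, SeqRecord] | None = None,
) -> tuple[tuple[str, int, int], list[str]]:
    """The 100-kb flank segment around an anchor and its cleaned gene list.

    Retroelements and transposons (per ``annotation.gene_class_tags``) are
    excluded.  Tandem arrays — neighbors satisfying the tandem rule whose
    proteins align above the homology gate — are collapsed to their
    5'-most representative.
    """
    start = max(0, anchor.start - window)
    end = anchor.end + window
    chrom_len = annotation.chromosome_lengths.get(anchor.chromosome)
    if chrom_len is not None:
        end = min(end, chrom_len)
    segment = (anchor.chromosome, start, end)
    genes = [
        g
        for g in annotation.on_chromosome(anchor.chromosome)
        if g.start >= start and g.end <= end
        and annotation.gene_class_tags.get(g.gene_id, "protein_coding")
        == "protein_coding"
    ]
    kept: list[GeneModel] = []
    for g in genes:
        if kept and proteome is not None:
            prev = kept[-1]
            if (
                g.gene_id in proteome
                and prev.gene_id in proteome
                and is_tandem_pair(prev, g, annotation)
                and local_alignment_score(proteome[prev.gene_id], proteome[g.gene_id])
                >= collapse_threshold
            ):
                continue  # same tandem array; keep the 5'-most member
        kept.append(g)
    return segment, [g.gene_id for g in kept]


def _orientation(
    matches: list[HomologMatch], order_a: list[str], order_b: list[str]
) -> str:
    """Same-direction vs inverted collinearity of the matched genes."""
    pos_a = {g: i for i, g in enumerate(order_a)}
    pos_b = {g: i for i, g in enumerate(order_b)}
    pairs = sorted(
        (pos_a[m.gene_a], pos_b[m.gene_b])
        for m in matches
        if m.gene_a in pos_a and m.gene_b in pos_b
    )
    if len(pairs) < 2:
        return "same"
    concordant = discordant = 0
    for i in range(len(pairs) - 1):
        for j in range(i + 1, len(pairs)):
            diff = (pairs[j][0] - pairs[i][0]) * (pairs[j][1] - pairs[i][1])
            if diff > 0:
                concordant += 1
            elif diff < 0:
                discordant += 1
    return "same" if concordant >= discordant else "inverted"


def detect_block(
    anchor_a: GeneModel,
    anchor_b: GeneModel,
    annotation_a: Annotation,
    annotation_b: Annotation,
    proteome_a: dict[str, SeqRecord],
    proteome_b: dict[str, SeqRecord],
    window: int = DEFAULT_WINDOW_BP,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    count_anchor: bool = True,
) -> SyntenyBlock | None:
    """Detect a microsynteny block around an anchor gene pair.

    Returns a block when at least three conserved homolog pairs (reciprocal
    best non-self matches; anchor included when ``count_anchor``) fall
    within the two 100-kb windows, else None.
    """
    segment_a, ids_a = segment_genes(anchor_a, annotation_a, window, threshold, proteome_a)
    segment_b, ids_b = segment_genes(anchor_b, annotation_b, window, threshold, proteome_b)
    pool_a = {i: proteome_a[i] for i in ids_a if i in proteome_a}
    pool_b = {i: proteome_b[i] for i in ids_b if i in proteome_b}
    matches = [
        m for m in match_homologs(pool_a, pool_b, threshold) if m.is_best_non_self
    ]
    n_conserved = len(matches) if count_anchor else len(
        [m for m in matches if m.gene_a != anchor_a.gene_id]
    )
    if n_conserved < MIN_CONSERVED_PAIRS:
        return None
    block = SyntenyBlock(
        anchor_pair=(anchor_a.gene_id, anchor_b.gene_id),
        segment_a=segment_a,
        segment_b=segment_b,
        genes_a=ids_a,
        genes_b=ids_b,
        conserved_pairs=matches,
        orientation=_orientation(matches, ids_a, ids_b),
    )
    block.large_scale = is_large_scale_duplication(block)
    block.quality_pct = synteny_quality(block)
    return block


def is_large_scale_duplication(block: SyntenyBlock) -> bool:
    """True iff >= 5 flanking (non-anchor) gene pairs are reciprocal best
    non-self matches."""
    anchor_a, anchor_b = block.anchor_pair
    flanking = [
        m
        for m in block.conserved_pairs
        if m.is_best_non_self and m.gene_a != anchor_a and m.gene_b != anchor_b
    ]
    return len(flanking) >= LARGE_SCALE_MIN_FLANKING


def synteny_quality(block: SyntenyBlock) -> float:
    """Conserved fraction of the two segments: 100 * 2P / (Ga + Gb)."""
    if not block.genes_a or not block.genes_b:
        raise ValueError("synteny_quality on a block with an empty segment")
    p = len(block.conserved_pairs)
    return 100.0 * 2.0 * p / (len(block.genes_a) + len(block.genes_b))
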