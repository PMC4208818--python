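"""Tandem/segmental duplicate classification.

Tandem duplicates are paralogs separated by at most ``max_intervening``
annotated genes within a ``window`` (default 100 kb) on one chromosome.
Segmental duplicates sit on the two halves of a duplicated chromosomal
block.  Everything else (e.g. retrotransposition products) is typed "O".
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import Annotation, GeneModel

DEFAULT_MAX_INTERVENING = 5
DEFAULT_WINDOW_BP = 100_000


@dataclass(frozen=True)
class BlockInterval:
    chromosome: str
    start: int
    end: int

    def contains(self, gene: GeneModel) -> bool:
        return (
            gene.chromosome == self.chromosome
            and gene.start >= self.start
            and gene.end <= self.end
        )


@dataclass(frozen=True)
class DuplicatedBlock:
    block_id: str
    interval_a: BlockInterval
    interval_b: BlockInterval


@dataclass
class DuplicatedBlockSet:
    blocks: list[DuplicatedBlock]


@dataclass(frozen=True)
class PairClassification:
    pair: tuple[str, str]
    duplicate_type: str  # S | T | O


def is_tandem_pair(
    a: GeneModel,
    b: GeneModel,
    annotation: Annotation,
    max_intervening: int = DEFAULT_MAX_INTERVENING,
    window: int = DEFAULT_WINDOW_BP,
    protein_coding_only: bool = False,
) -> bool:
    """Tandem rule: same chromosome, <= max_intervening genes strictly
    between the pair, and the 5'-most start to 3'-most end span <= window.
    """
    if a.gene_id == b.gene_id:
        raise ValueError("is_tandem_pair requires two distinct genes")
    if a.chromosome != b.chromosome:
        return False
    left, right = (a, b) if a.start <= b.start else (b, a)
    if right.end - left.start > window:
        return False
    intervening = 0
    for g in annotation.on_chromosome(a.chromosome):
        if g.gene_id in (a.gene_id, b.gene_id):
            continue
        if protein_coding_only and annotation.gene_class_tags.get(
            g.gene_id, "protein_coding"
        ) != "protein_coding":
            continue
        if g.start >= left.end and g.end <= right.start:
            intervening += 1
    return intervening <= max_intervening


def assign_duplicate_type(
    a: GeneModel,
    b: GeneModel,
    blocks: DuplicatedBlockSet,
    annotation: Annotation,
    max_intervening: int = DEFAULT_MAX_INTERVENING,
    window: int = DEFAULT_WINDOW_BP,
) -> PairClassification:
    """Type a paralog pair: T (tandem, takes precedence), S (the two genes
    sit on partner intervals of a duplicated block) or O (other).
    """
    pair = (a.gene_id, b.gene_id)
    if is_tandem_pair(a, b, annotation, max_intervening, window):
        return PairClassification(pair, "T")
    for blk in blocks.blocks:
        if (blk.interval_a.contains(a) and blk.interval_b.contains(b)) or (
            blk.interval_a.contains(b) and blk.interval_b.contains(a)
        ):
            return PairClassification(pair, "S")
    return PairClassification(pair, "O")


def find_singletons_on_blocks(
    family_genes: list[GeneModel],
    blocks: DuplicatedBlockSet,
    annotation: Annotation,
) -> list[str]:
    """Family genes on a duplicated block whose partner interval holds no
    family gene — candidates for post-duplication sister loss.
    """
    singletons: list[str] = []
    for g in family_genes:
        for blk in blocks.blocks:
            for mine, partner in (
                (blk.interval_a, blk.interval_b),
                (blk.interval_b, blk.interval_a),
            ):
                if mine.contains(g) and not any(
                    partner.contains(other)
                    for other in family_genes
                    if other.gene_id != g.gene_id
                ):
                    singletons.append(g.gene_id)
                    break
            else:
                continue
            break
    return singletons
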