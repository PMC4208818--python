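"""Sequence and annotation I/O.

Internal convention: all genomic intervals are 0-based half-open.
Conversion from/to the 1-based inclusive coordinates of GFF3 happens only
here, at the I/O boundary, so that downstream window arithmetic (the 100-kb
rules of the duplication and synteny modules) never has to reason about
off-by-one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger("iqdfam")

# "-" is tolerated everywhere so aligned sequences remain SeqRecords
DNA_ALPHABET = set("ACGTN-")
DNA_AMBIGUOUS = DNA_ALPHABET | set("URYSWKMBDHV")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY-")
PROTEIN_AMBIGUOUS = PROTEIN_ALPHABET | set("BXZJUO*")


@dataclass
class SeqRecord:
    """A named sequence with a declared alphabet ('dna' or 'protein')."""

    id: str
    sequence: str
    alphabet_tag: str = "dna"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if self.alphabet_tag not in ("dna", "protein"):
            raise ValueError(f"unknown alphabet_tag {self.alphabet_tag!r}")
        seq = self.sequence.upper()
        strict = DNA_ALPHABET if self.alphabet_tag == "dna" else PROTEIN_ALPHABET
        loose = DNA_AMBIGUOUS if self.alphabet_tag == "dna" else PROTEIN_AMBIGUOUS
        bad = set(seq) - loose
        if bad:
            raise ValueError(
                f"record {self.id!r}: characters {sorted(bad)} outside the "
                f"{self.alphabet_tag} alphabet"
            )
        ambiguous = set(seq) - strict
        if ambiguous:
            logger.warning(
                "record %s contains ambiguity codes %s", self.id, sorted(ambiguous)
            )
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """One gene locus: strand, exon and CDS intervals (0-based half-open).

    Exons are kept sorted by genome coordinate regardless of strand;
    transcription order is derived from the strand when the CDS is
    extracted.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds_segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds_segments = sorted(tuple(c) for c in self.cds_segments)
        for s, e in self.exons + self.cds_segments:
            if s >= e:
                raise ValueError(f"gene {self.gene_id}: empty interval ({s},{e})")
        for i in range(1, len(self.exons)):
            if self.exons[i][0] < self.exons[i - 1][1]:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        for c in self.cds_segments:
            if not any(c[0] >= s and c[1] <= e for s, e in self.exons):
                raise ValueError(
                    f"gene {self.gene_id}: CDS segment {c} not contained in any exon"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)


@dataclass
class Annotation:
    """A gene set over named chromosomes, plus optional gene-class tags."""

    genes: list[GeneModel]
    chromosome_lengths: dict[str, int] = field(default_factory=dict)
    gene_class_tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene id {g.gene_id!r}")
            seen.add(g.gene_id)
            length = self.chromosome_lengths.get(g.chromosome)
            if length is not None and g.end > length:
                raise ValueError(
                    f"gene {g.gene_id} extends past the end of {g.chromosome}"
                )

    def by_id(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def on_chromosome(self, chromosome: str) -> list[GeneModel]:
        return sorted(
            (g for g in self.genes if g.chromosome == chromosome),
            key=lambda g: g.start,
        )


def read_fasta(path: str | Path, alphabet_tag: str = "dna") -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords, preserving order.

    Raises on an empty file and on duplicate record ids.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SeqRecord(rec.id, str(rec.seq), alphabet_tag))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_gff3(path: str | Path) -> Annotation:
    """Parse a GFF3 file of gene/mRNA/exon/CDS features into an Annotation.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    If a gene carries several mRNAs only the first is kept, with a warning.
    """
    genes: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    chromosome_lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    chromosome_lengths[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype not in ("gene", "mRNA", "exon", "CDS"):
                continue
            if strand not in ("+", "-"):
                raise ValueError(f"unknown strand symbol {strand!r} in {line!r}")
            iv = (int(start) - 1, int(end))  # 1-based inclusive -> 0-based half-open
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID")
                if gid is None:
                    raise ValueError(f"gene feature without ID: {line!r}")
                genes[gid] = {
                    "chromosome": seqid,
                    "strand": strand,
                    "mrna": None,
                    "exons": [],
                    "cds": [],
                }
            elif ftype == "mRNA":
                parent = attr.get("Parent")
                mid = attr.get("ID")
                if parent in genes:
                    if genes[parent]["mrna"] is None:
                        genes[parent]["mrna"] = mid
                        mrna_to_gene[mid] = parent
                    else:
                        logger.warning(
                            "gene %s has multiple mRNAs; keeping %s",
                            parent,
                            genes[parent]["mrna"],
                        )
            else:  # exon / CDS
                parent = attr.get("Parent")
                gid = mrna_to_gene.get(parent, parent if parent in genes else None)
                if gid is None:
                    continue  # feature of a discarded secondary transcript
                genes[gid]["exons" if ftype == "exon" else "cds"].append(iv)
    models = [
        GeneModel(gid, rec["chromosome"], rec["strand"], rec["exons"], rec["cds"])
        for gid, rec in genes.items()
    ]
    return Annotation(models, chromosome_lengths)


def write_gff3(annotation: Annotation, path: str | Path) -> None:
    """Write an Annotation back to GFF3 (round-trips with read_gff3)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in sorted(annotation.chromosome_lengths.items()):
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in annotation.genes:
            def row(ftype: str, s: int, e: int, attrs: str) -> str:
                return (
                    f"{g.chromosome}\tiqdfam\t{ftype}\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )

            fh.write(row("gene", g.start, g.end, f"ID={g.gene_id}"))
            mid = f"{g.gene_id}.t1"
            fh.write(row("mRNA", g.start, g.end, f"ID={mid};Parent={g.gene_id}"))
            for s, e in g.exons:
                fh.write(row("exon", s, e, f"Parent={mid}"))
            for s, e in g.cds_segments:
                fh.write(row("CDS", s, e, f"Parent={mid}"))


def extract_cds(gene: GeneModel, genome: SeqRecord) -> SeqRecord:
    """Concatenate a gene's CDS segments into the 5'->3' mRNA sequence.

    Minus-strand genes are reverse-complemented; the returned length always
    equals the sum of CDS segment lengths.
    """
    if gene.chromosome != genome.id:
        raise ValueError(
            f"gene {gene.gene_id} is on {gene.chromosome}, not {genome.id}"
        )
    parts = []
    for s, e in gene.cds_segments:
        if e > len(genome.sequence):
            raise ValueError(
                f"gene {gene.gene_id}: CDS segment ({s},{e}) beyond the end of "
                f"{genome.id} ({len(genome.sequence)} bp)"
            )
        parts.append(genome.sequence[s:e])
    seq = "".join(parts)
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return SeqRecord(gene.gene_id, seq, "dna")


def translate_cds(cds: SeqRecord, trim_stop: bool = True) -> SeqRecord:
    """Translate a CDS; trims a single trailing stop codon by default."""
    if len(cds.sequence) % 3:
        raise ValueError(f"CDS {cds.id} length not divisible by 3")
    prot = str(Seq(cds.sequence).translate())
    if trim_stop and prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise ValueError(f"CDS {cds.id} contains an internal stop codon")
    return SeqRecord(cds.id, prot, "protein")
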