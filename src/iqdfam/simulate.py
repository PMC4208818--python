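"""Synthetic gene-family genomes with known ground truth.

The generator emulates the structures a plant gene-family survey measures:
proteins carrying a canonical IQ67 domain (three strict IQ motifs at the
11/15 spacing, overlapping 1-5-10 and 1-8-14 copies), gene models with a
phase-0 intron between domain codons 16 and 17, tandem and segmental
duplicates with controlled Ka/Ks divergence and collinear flanking genes,
tissue expression count tables with designed preferences, and qPCR CT
tables encoding known fold changes.  Every generated entity has exactly
one entry in the returned TruthTable, so each downstream stage can be
scored against its implanted signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .duplication import BlockInterval, DuplicatedBlock, DuplicatedBlockSet
from .io import Annotation, GeneModel, SeqRecord
from .kaks import synonymous_sites

# Canonical 67-aa IQ67 domain template: strict IQ copies at positions 1-11,
# 23-33 and 49-59 (11 and 15 intervening residues), a 1-5-10 copy in the
# first spacer and a 1-8-14 copy in the second.
IQ_UNIT = "IQAAARGAAAR"
DOMAIN_TEMPLATE = (
    IQ_UNIT + "FAAAIAAAAWS" + IQ_UNIT + "LAAAAAAFAAAAAVS" + IQ_UNIT + "SAEESAEE"
)
assert len(DOMAIN_TEMPLATE) == 67

# Flank residues exclude Q so no spurious relaxed-IQ anchor can form, and
# exclude the bulky hydrophobics that would seed extra Ca-dependent motifs.
FLANK_ALPHABET = "ASTNDEGPHR"

# Average globular-protein residue frequencies; background genes draw from
# this so they are a realistic substrate for the scanner and a fair null
# for alignment scores.
_BG_AA = "ARNDCQEGHILKMFPSTWYV"
_BG_FREQ = np.array(
    [0.080, 0.050, 0.040, 0.050, 0.015, 0.040, 0.060, 0.070, 0.022, 0.055,
     0.090, 0.060, 0.023, 0.040, 0.050, 0.080, 0.055, 0.012, 0.030, 0.068]
)
_BG_FREQ = _BG_FREQ / _BG_FREQ.sum()

_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _AA_TO_CODONS.setdefault(aa, []).append(codon)
for codons in _AA_TO_CODONS.values():
    codons.sort()
_STOPS = sorted(standard_dna_table.stop_codons)

INTRON_LENGTH = 200
INTERGENIC_GAP = 12_000  # scattered genes: far apart, never tandem
TANDEM_GAP = 3_000  # within a tandem array: adjacent, well inside 100 kb
BLOCK_GAP = 2_000  # between collinear genes of a duplicated segment
BLOCK_FLANK_GENES = 3  # per side -> 6 flanking genes per block


@dataclass
class FamilySpec:
    """Study-condition knobs of the synthetic family genome."""

    n_chromosomes: int = 4
    chromosome_length: int = 600_000
    n_iqd_genes: int = 8
    n_background_genes: int = 40
    tandem_pairs: int = 1
    segmental_blocks: int = 2
    ka_target: float = 0.03
    ks_target: float = 0.12
    intron_plan: list[tuple[int, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes",
            "chromosome_length",
            "n_iqd_genes",
            "n_background_genes",
            "tandem_pairs",
            "segmental_blocks",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ks_target >= 0.7 or self.ka_target >= 0.7:
            raise ValueError("divergence targets must stay below 0.7")
        needed = 2 * (self.tandem_pairs + self.segmental_blocks)
        if self.n_iqd_genes < needed:
            raise ValueError(
                f"n_iqd_genes={self.n_iqd_genes} cannot host "
                f"{self.tandem_pairs} tandem pairs and "
                f"{self.segmental_blocks} segmental blocks ({needed} genes)"
            )
        if self.n_background_genes < BLOCK_FLANK_GENES * 2 * self.segmental_blocks:
            raise ValueError("not enough background genes for the block flanks")


@dataclass
class TruthTable:
    """Ground truth for every generated entity."""

    domain_locations: dict[str, tuple[int, int]] = field(default_factory=dict)
    pair_types: dict[tuple[str, str], str] = field(default_factory=dict)
    pair_divergence: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )
    block_layout: dict[str, tuple[list[str], list[str]]] = field(default_factory=dict)
    block_intervals: dict[str, tuple[BlockInterval, BlockInterval]] = field(
        default_factory=dict
    )
    expression_design: dict[str, tuple[str, float]] = field(default_factory=dict)
    qpcr_design: dict[str, dict[float, float]] = field(default_factory=dict)

    def block_set(self) -> DuplicatedBlockSet:
        return DuplicatedBlockSet(
            [
                DuplicatedBlock(bid, a, b)
                for bid, (a, b) in sorted(self.block_intervals.items())
            ]
        )


def _encode_protein(protein: str, rng: np.random.Generator) -> str:
    """CDS for a protein with rng-chosen synonymous codons plus a stop."""
    codons = [
        _AA_TO_CODONS[aa][rng.integers(len(_AA_TO_CODONS[aa]))] for aa in protein
    ]
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    return "".join(codons)


def _flank_protein(length: int, rng: np.random.Generator) -> str:
    body = "".join(
        FLANK_ALPHABET[i] for i in rng.integers(0, len(FLANK_ALPHABET), length - 1)
    )
    return "M" + body


def _random_protein(length: int, rng: np.random.Generator) -> str:
    body = "".join(rng.choice(list(_BG_AA), size=length - 1, p=_BG_FREQ))
    return "M" + body


def _random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


def mutate_codon_sequence(
    cds: SeqRecord,
    ka_target: float,
    ks_target: float,
    seed: int,
    protected_codons: set[int] | None = None,
) -> SeqRecord:
    """Substitute nucleotides so NG86 recovers the divergence targets.

    The targets are inverted through the Jukes-Cantor correction to
    expected proportions p = (3/4)(1 - exp(-4d/3)); synonymous and
    nonsynonymous single-nucleotide changes are then placed at distinct
    sites in a seeded random order.  No indels, no stop codons, protein
    length unchanged.  ``protected_codons`` (0-based indices) accept only
    synonymous changes — used to emulate purifying selection on a domain.
    """
    if len(cds.sequence) % 3:
        raise ValueError("CDS length not divisible by 3")
    if ks_target >= 0.7 or ka_target >= 0.7:
        raise ValueError("divergence target >= 0.7: JC correction undefined")
    if ks_target < 0 or ka_target < 0:
        raise ValueError("divergence targets must be non-negative")
    codons = [cds.sequence[i : i + 3] for i in range(0, len(cds.sequence), 3)]
    coding = codons[:-1] if codons[-1] in _STOPS else list(codons)
    if any(c in _STOPS for c in coding):
        raise ValueError(f"CDS {cds.id} contains an internal stop codon")
    if ka_target == 0 and ks_target == 0:
        return SeqRecord(cds.id, cds.sequence, "dna")
    rng = np.random.default_rng(seed)
    s_sites = sum(synonymous_sites(c) for c in coding)
    n_sites = 3 * len(coding) - s_sites
    p_s = 0.75 * (1.0 - math.exp(-4.0 * ks_target / 3.0))
    p_n = 0.75 * (1.0 - math.exp(-4.0 * ka_target / 3.0))
    n_syn = int(round(p_s * s_sites))
    n_non = int(round(p_n * n_sites))
    fwd = standard_dna_table.forward_table
    slots = [(i, p) for i in range(len(coding)) for p in range(3)]
    for idx in rng.permutation(len(slots)):
        if n_syn == 0 and n_non == 0:
            break
        i, p = slots[idx]
        codon = coding[i]
        aa = fwd[codon]
        syn_opts, non_opts = [], []
        for base in "ACGT":
            if base == codon[p]:
                continue
            mutant = codon[:p] + base + codon[p + 1 :]
            if mutant in _STOPS:
                continue
            (syn_opts if fwd[mutant] == aa else non_opts).append(base)
        if protected_codons and i in protected_codons:
            non_opts = []
        if n_syn > 0 and syn_opts:
            base = syn_opts[rng.integers(len(syn_opts))]
            coding[i] = codon[:p] + base + codon[p + 1 :]
            n_syn -= 1
        elif n_non > 0 and non_opts:
            base = non_opts[rng.integers(len(non_opts))]
            coding[i] = codon[:p] + base + codon[p + 1 :]
            n_non -= 1
    tail = [codons[-1]] if codons[-1] in _STOPS else []
    return SeqRecord(cds.id, "".join(coding + tail), "dna")


@dataclass
class _GenePlan:
    gene_id: str
    cds: str  # stop codon included
    strand: str
    intron_offsets: list[int]  # coding-nt offsets, transcription order
    domain_location: tuple[int, int] | None = None


def _iqd_protein(rng: np.random.Generator) -> tuple[str, int]:
    """An IQD protein and the 1-based start of its domain."""
    n_flank = _flank_protein(int(rng.integers(20, 60)), rng)
    c_flank = "".join(
        FLANK_ALPHABET[i] for i in rng.integers(0, len(FLANK_ALPHABET), int(rng.integers(30, 90)))
    )
    return n_flank + DOMAIN_TEMPLATE + c_flank, len(n_flank) + 1


def _plan_iqd_gene(
    gene_id: str, spec: FamilySpec, rng: np.random.Generator
) -> _GenePlan:
    protein, dom_start = _iqd_protein(rng)
    cds = _encode_protein(protein, rng)
    offsets = {3 * (dom_start - 1 + 16)}  # phase-0 intron between codons 16/17
    for codon, phase in spec.intron_plan:
        off = 3 * codon + phase
        if 0 < off < 3 * len(protein):
            offsets.add(off)
    return _GenePlan(
        gene_id,
        cds,
        "+" if rng.integers(2) else "-",
        sorted(offsets),
        (dom_start, dom_start + 66),
    )


def _plan_background_gene(gene_id: str, rng: np.random.Generator) -> _GenePlan:
    protein = _random_protein(int(rng.integers(120, 300)), rng)
    cds = _encode_protein(protein, rng)
    n_introns = int(rng.integers(0, 3))
    offsets = sorted(
        int(o)
        for o in rng.choice(
            np.arange(3, 3 * len(protein) - 3), size=n_introns, replace=False
        )
    ) if n_introns else []
    return _GenePlan(gene_id, cds, "+" if rng.integers(2) else "-", offsets)


def _mutated_copy(
    plan: _GenePlan, new_id: str, spec: FamilySpec, seed: int
) -> _GenePlan:
    # purifying selection on the IQ67 domain: its codons only change
    # synonymously, so the copy's domain stays detectable
    protected = None
    if plan.domain_location is not None:
        s, e = plan.domain_location
        protected = set(range(s - 1, e))
    mutated = mutate_codon_sequence(
        SeqRecord(plan.gene_id, plan.cds, "dna"),
        spec.ka_target,
        spec.ks_target,
        seed,
        protected_codons=protected,
    )
    return _GenePlan(
        new_id, mutated.sequence, plan.strand, list(plan.intron_offsets),
        plan.domain_location,
    )


def _realize_gene(
    plan: _GenePlan, offset: int, chromosome: str, rng: np.random.Generator
) -> tuple[str, GeneModel]:
    """Genomic sequence of one gene region and its GeneModel at ``offset``."""
    cuts = [0] + plan.intron_offsets + [len(plan.cds)]
    exon_seqs = [plan.cds[a:b] for a, b in zip(cuts[:-1], cuts[1:])]
    parts: list[str] = []
    exons_t: list[tuple[int, int]] = []  # transcript-orientation coordinates
    pos = 0
    for i, seq in enumerate(exon_seqs):
        if i:
            intron = "GT" + _random_dna(INTRON_LENGTH - 4, rng) + "AG"
            parts.append(intron)
            pos += INTRON_LENGTH
        exons_t.append((pos, pos + len(seq)))
        parts.append(seq)
        pos += len(seq)
    region = "".join(parts)
    length = len(region)
    if plan.strand == "-":
        region = str(Seq(region).reverse_complement())
        exons = [(offset + length - b, offset + length - a) for a, b in exons_t]
    else:
        exons = [(offset + a, offset + b) for a, b in exons_t]
    exons.sort()
    model = GeneModel(plan.gene_id, chromosome, plan.strand, exons, exons)
    return region, model


def generate_family_genome(
    spec: FamilySpec,
) -> tuple[list[SeqRecord], Annotation, TruthTable]:
    """Build a genome, its annotation and the ground truth for a spec.

    Deterministic for a fixed spec (byte-identical FASTA/GFF3 on rewrite).
    Raises when the planned genes do not fit on the chromosomes.
    """
    rng = np.random.default_rng(spec.seed)
    truth = TruthTable()

    iqd_ids = [f"IQD{i + 1:03d}" for i in range(spec.n_iqd_genes)]
    bg_ids = [f"BG{i + 1:03d}" for i in range(spec.n_background_genes)]
    iqd_queue = list(iqd_ids)
    bg_queue = list(bg_ids)

    # entity = (kind, [gene plans]) laid out contiguously on one chromosome
    entities: list[tuple[str, list[_GenePlan]]] = []
    dup_entities: list[tuple[int, list[_GenePlan]]] = []  # (source index, copies)

    for b in range(spec.segmental_blocks):
        flank_left = [
            _plan_background_gene(bg_queue.pop(0), rng)
            for _ in range(BLOCK_FLANK_GENES)
        ]
        anchor = _plan_iqd_gene(iqd_queue.pop(0), spec, rng)
        flank_right = [
            _plan_background_gene(bg_queue.pop(0), rng)
            for _ in range(BLOCK_FLANK_GENES)
        ]
        source = flank_left + [anchor] + flank_right
        anchor_copy_id = iqd_queue.pop(0)
        copies = []
        for j, src in enumerate(source):
            new_id = anchor_copy_id if src is anchor else f"{src.gene_id}d"
            copies.append(
                _mutated_copy(src, new_id, spec, int(rng.integers(2**31)))
            )
        entities.append(("block_src", source))
        dup_entities.append((len(entities) - 1, copies))
        truth.pair_types[(anchor.gene_id, anchor_copy_id)] = "segmental"
        truth.pair_divergence[(anchor.gene_id, anchor_copy_id)] = (
            spec.ka_target,
            spec.ks_target,
        )
        truth.block_layout[f"block{b + 1}"] = (
            [g.gene_id for g in source],
            [g.gene_id for g in copies],
        )

    for _ in range(spec.tandem_pairs):
        first = _plan_iqd_gene(iqd_queue.pop(0), spec, rng)
        second = _mutated_copy(
            first, iqd_queue.pop(0), spec, int(rng.integers(2**31))
        )
        entities.append(("tandem", [first, second]))
        truth.pair_types[(first.gene_id, second.gene_id)] = "tandem"
        truth.pair_divergence[(first.gene_id, second.gene_id)] = (
            spec.ka_target,
            spec.ks_target,
        )

    for gid in iqd_queue:
        entities.append(("single", [_plan_iqd_gene(gid, spec, rng)]))
    for gid in bg_queue:
        entities.append(("single", [_plan_background_gene(gid, rng)]))

    for plans in [e[1] for e in entities] + [c for _, c in dup_entities]:
        for p in plans:
            if p.domain_location is not None:
                truth.domain_locations[p.gene_id] = p.domain_location

    # round-robin placement; a block's duplicate goes on the next chromosome
    chroms = [f"chr{i + 1}" for i in range(max(spec.n_chromosomes, 1))]
    sequences: dict[str, list[str]] = {c: [] for c in chroms}
    cursors = {c: 0 for c in chroms}
    models: list[GeneModel] = []
    placed_spans: dict[int, tuple[str, int, int]] = {}

    def place(chrom: str, kind: str, plans: list[_GenePlan]) -> tuple[int, int]:
        gap_in = TANDEM_GAP if kind == "tandem" else BLOCK_GAP
        cursors[chrom] += INTERGENIC_GAP
        sequences[chrom].append(_random_dna(INTERGENIC_GAP, rng))
        span_start = cursors[chrom]
        for i, plan in enumerate(plans):
            if i:
                sequences[chrom].append(_random_dna(gap_in, rng))
                cursors[chrom] += gap_in
            region, model = _realize_gene(plan, cursors[chrom], chrom, rng)
            sequences[chrom].append(region)
            cursors[chrom] += len(region)
            models.append(model)
        span_end = cursors[chrom]
        if span_end > spec.chromosome_length:
            raise ValueError(
                f"genes do not fit on {chrom} "
                f"({span_end} > {spec.chromosome_length} bp)"
            )
        return span_start, span_end

    for idx, (kind, plans) in enumerate(entities):
        chrom = chroms[idx % len(chroms)]
        placed_spans[idx] = (chrom, *place(chrom, kind, plans))

    for b, (src_idx, copies) in enumerate(dup_entities):
        src_chrom, src_start, src_end = placed_spans[src_idx]
        dup_chrom = chroms[(chroms.index(src_chrom) + 1) % len(chroms)]
        dup_start, dup_end = place(dup_chrom, "block_src", copies)
        truth.block_intervals[f"block{b + 1}"] = (
            BlockInterval(src_chrom, src_start, src_end),
            BlockInterval(dup_chrom, dup_start, dup_end),
        )

    genome = []
    for chrom in chroms:
        pad = spec.chromosome_length - cursors[chrom]
        if pad > 0:
            sequences[chrom].append(_random_dna(pad, rng))
        genome.append(SeqRecord(chrom, "".join(sequences[chrom]), "dna"))
    annotation = Annotation(
        models,
        {c: spec.chromosome_length for c in chroms},
    )
    return genome, annotation, truth


def generate_expression_counts(
    design: dict[str, tuple[str, float]],
    library_sizes: dict[str, int],
    genes: list[str],
    seed: int = 0,
    baseline: float = 50.0,
    dispersion: float | None = 0.1,
) -> pd.DataFrame:
    """Gene x tissue read counts with designed tissue preferences.

    A gene designed ``(tissue, fold)`` has expected count baseline*fold in
    that tissue and baseline elsewhere, scaled by library size in millions.
    ``dispersion=None`` turns the negative-binomial noise off (counts equal
    their expectations exactly).
    """
    for tissue, total in library_sizes.items():
        if total <= 0:
            raise ValueError(f"library size for {tissue} must be positive")
    for gene, (tissue, fold) in design.items():
        if gene not in genes:
            raise ValueError(f"designed gene {gene!r} not in gene list")
        if tissue not in library_sizes:
            raise ValueError(f"designed tissue {tissue!r} not in library_sizes")
        if fold <= 0:
            raise ValueError(f"fold for {gene} must be positive")
    rng = np.random.default_rng(seed)
    tissues = list(library_sizes)
    rows = np.zeros((len(genes), len(tissues)))
    for gi, gene in enumerate(genes):
        pref, fold = design.get(gene, (None, 1.0))
        for ti, tissue in enumerate(tissues):
            mu = baseline * (fold if tissue == pref else 1.0)
            mu *= library_sizes[tissue] / 1e6
            if dispersion is None:
                rows[gi, ti] = mu
            else:
                size = 1.0 / dispersion
                rows[gi, ti] = rng.negative_binomial(size, size / (size + mu))
    return pd.DataFrame(rows, index=genes, columns=tissues)


REFERENCE_CT = 20.0
BASELINE_TARGET_CT = 25.0


def generate_qpcr_ct(
    design: dict[str, dict[float, float]],
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format CT table encoding known fold changes.

    A true fold F at timepoint t shifts the target CT by -log2(F) relative
    to the 0-h control; the reference CT stays constant.  Gaussian noise of
    sd ``noise_sd`` cycles is added to the target CTs.  Timepoint 0 (the
    control, fold 1) is always present.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for gene in sorted(design):
        folds = {0.0: 1.0, **design[gene]}
        for t in sorted(folds):
            fold = folds[t]
            if fold <= 0:
                raise ValueError(f"{gene} @ {t} h: fold must be positive")
            ct_true = BASELINE_TARGET_CT - math.log2(fold)
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                records.append(
                    {
                        "gene": gene,
                        "timepoint": t,
                        "replicate": rep,
                        "ct_target": ct_true + noise,
                        "ct_reference": REFERENCE_CT,
                    }
                )
    return pd.DataFrame.from_records(records)
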