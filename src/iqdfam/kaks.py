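"""Ka/Ks estimation (Nei–Gojobori 1986), divergence dating and selection
classification.

The estimator is the unweighted NG86 counting method: fractional synonymous
site counts averaged over both sequences, pathway-averaged difference
counts for codons differing at more than one position, and the
Jukes–Cantor correction d = -(3/4) ln(1 - 4p/3) applied to the proportions.
Single-nucleotide changes that would create a stop codon are counted as
nonsynonymous for site counting, and evolutionary pathways passing through
a stop codon are excluded from difference counting.

Divergence dates use the synonymous molecular clock for soybean,
lambda = 6.1e-9 synonymous substitutions per synonymous site per year:
T = Ks / (2 * lambda) * 1e-6 Mya.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table

from .align import global_protein_alignment
from .io import SeqRecord, translate_cds

#: Synonymous substitution rate per site per year (soybean clock).
SOYBEAN_SYNONYMOUS_RATE = 6.1e-9

_CODON_TO_AA = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"


@dataclass
class CodonAlignment:
    """A pair of gapped codon strings; gaps occur in whole-codon triplets."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences differ in length")
        if len(self.seq_a) % 3:
            raise ValueError("alignment length not divisible by 3")
        for codon in itertools.chain(self.codons_a, self.codons_b):
            if "-" in codon and codon != "---":
                raise ValueError(f"gap not in whole-codon triplets: {codon!r}")

    @property
    def codons_a(self) -> list[str]:
        return [self.seq_a[i : i + 3] for i in range(0, len(self.seq_a), 3)]

    @property
    def codons_b(self) -> list[str]:
        return [self.seq_b[i : i + 3] for i in range(0, len(self.seq_b), 3)]

    @property
    def n_codons(self) -> int:
        """Aligned codon columns with no gap in either sequence."""
        return sum(
            1
            for a, b in zip(self.codons_a, self.codons_b)
            if "-" not in a and "-" not in b
        )


@dataclass
class KaKsResult:
    pair: tuple[str, str]
    ka: float
    ks: float
    time_mya: float
    duplicate_type: str = "O"

    @property
    def ratio(self) -> float:
        if self.ks <= 0:
            raise ZeroDivisionError("Ka/Ks undefined for Ks = 0")
        return self.ka / self.ks

    @property
    def selection_class(self) -> str:
        return classify_selection(self.ratio)


def backthread_codon_alignment(
    protein_aln: tuple[str, str], cds_a: SeqRecord, cds_b: SeqRecord
) -> CodonAlignment:
    """Replace each aligned residue by its codon, each gap by ``---``.

    The ungapped proteins must equal the CDS translations (stop trimmed);
    the first discordant residue is named otherwise.
    """
    rows = []
    for aligned, cds in zip(protein_aln, (cds_a, cds_b)):
        protein = aligned.replace("-", "")
        translated = translate_cds(cds).sequence
        if protein != translated:
            for i, (p, t) in enumerate(
                itertools.zip_longest(protein, translated), start=1
            ):
                if p != t:
                    raise ValueError(
                        f"CDS {cds.id}: translation mismatch at residue {i} "
                        f"(alignment has {p!r}, CDS encodes {t!r})"
                    )
        codons = iter(
            cds.sequence[i : i + 3] for i in range(0, 3 * len(protein), 3)
        )
        rows.append("".join("---" if aa == "-" else next(codons) for aa in aligned))
    return CodonAlignment(rows[0], rows[1])


def synonymous_sites(codon: str) -> float:
    """Fractional synonymous site count of one codon (0..3).

    At each position, the fraction of the three single-nucleotide changes
    that preserve the amino acid; changes to stop codons count as
    nonsynonymous.
    """
    aa = _CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _CODON_TO_AA.get(mutant) == aa:
                s += 1.0 / 3.0
    return s


def _pathway_differences(a: str, b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons,
    averaged over all orderings of the differing positions; pathways through
    a stop codon are skipped unless every pathway is blocked."""
    diff_positions = [i for i in range(3) if a[i] != b[i]]
    if not diff_positions:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_positions):
        current = a
        sd = nd = 0
        through_stop = False
        for pos in order:
            mutant = current[:pos] + b[pos] + current[pos + 1 :]
            if mutant in _STOP_CODONS:
                through_stop = True
            if _CODON_TO_AA.get(current) == _CODON_TO_AA.get(mutant):
                sd += 1
            else:
                nd += 1
            current = mutant
        (blocked if through_stop else valid).append((sd, nd))
    pool = valid or blocked
    return (
        sum(p[0] for p in pool) / len(pool),
        sum(p[1] for p in pool) / len(pool),
    )


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""
    if p >= 0.75:
        raise ValueError(f"correction undefined for proportion {p:.4f} >= 3/4")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_kaks(aln: CodonAlignment) -> tuple[float, float]:
    """Nei–Gojobori (1986) Ka and Ks for a pairwise codon alignment.

    Codon columns containing a gap or a stop codon in either sequence are
    excluded from both site and difference counts, so S + N always equals
    three times the counted columns.
    """
    s_sites_a = s_sites_b = 0.0
    sd = nd = 0.0
    counted = 0
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        if "-" in ca or "-" in cb:
            continue
        if ca in _STOP_CODONS or cb in _STOP_CODONS:
            continue
        counted += 1
        s_sites_a += synonymous_sites(ca)
        s_sites_b += synonymous_sites(cb)
        dsd, dnd = _pathway_differences(ca, cb)
        sd += dsd
        nd += dnd
    if counted == 0:
        raise ValueError("no ungapped, stop-free codon columns to compare")
    s_sites = (s_sites_a + s_sites_b) / 2.0
    n_sites = 3.0 * counted - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    return jukes_cantor(pn), jukes_cantor(ps)


def divergence_time(ks: float, rate: float = SOYBEAN_SYNONYMOUS_RATE) -> float:
    """Divergence time in Mya: T = Ks / (2 * rate) * 1e-6."""
    if ks < 0:
        raise ValueError(f"negative Ks: {ks}")
    return ks / (2.0 * rate) * 1e-6


def classify_selection(ratio: float, tolerance: float = 1e-9) -> str:
    """purifying (<1), neutral (=1 within tolerance) or positive (>1)."""
    if ratio < 0:
        raise ValueError(f"negative Ka/Ks ratio: {ratio}")
    if abs(ratio - 1.0) <= tolerance:
        return "neutral"
    return "purifying" if ratio < 1.0 else "positive"


def pair_kaks(
    cds_a: SeqRecord,
    cds_b: SeqRecord,
    duplicate_type: str = "O",
) -> KaKsResult:
    """Convenience pipeline for one pair: translate, globally align the
    proteins, back-thread to codons and run NG86 + dating."""
    prot_a = translate_cds(cds_a)
    prot_b = translate_cds(cds_b)
    aln = global_protein_alignment(prot_a, prot_b)
    codon_aln = backthread_codon_alignment(aln, cds_a, cds_b)
    ka, ks = ng86_kaks(codon_aln)
    return KaKsResult(
        pair=(cds_a.id, cds_b.id),
        ka=ka,
        ks=ks,
        time_mya=divergence_time(ks),
        duplicate_type=duplicate_type,
    )
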