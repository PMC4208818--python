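"""IQ67-domain detection and protein descriptors.

The IQ67 domain of plant IQD proteins is a 67-residue calmodulin-binding
region built from three motif classes:

* the Ca2+-independent IQ motif, strict form ``IQxxxRGxxxR`` (11 aa) with a
  relaxed variant ``[ILV]QxxxR xxxx[RK]``;
* the Ca2+-dependent 1-5-10 motif ``[FILVW]x3[FILV]x4[FILVW]`` (10 aa);
* the Ca2+-dependent 1-8-14 motif ``[FILVW]x6[FAILVW]x5[FILVW]`` (14 aa).

A canonical domain carries 1-3 IQ copies separated by 11 and 15 intervening
residues, overlapping 1-4 copies of each Ca2+-dependent motif.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .io import SeqRecord, PROTEIN_ALPHABET

logger = logging.getLogger("iqdfam")

#: Window length of the full domain.
DOMAIN_LENGTH = 67

#: Canonical intervening-residue counts between successive IQ motif copies.
CANONICAL_SPACINGS = (11, 15)

# Overlap-tolerant patterns: each match is captured in a lookahead so that
# overlapping windows are all reported.
MOTIF_PATTERNS: dict[str, tuple[re.Pattern, int]] = {
    "IQ_strict": (re.compile(r"(?=(IQ.{3}RG.{3}R))"), 11),
    "IQ_relaxed": (re.compile(r"(?=([ILV]Q.{3}R.{4}[RK]))"), 11),
    "M_1_5_10": (re.compile(r"(?=([FILVW].{3}[FILV].{4}[FILVW]))"), 10),
    "M_1_8_14": (re.compile(r"(?=([FILVW].{6}[FAILVW].{5}[FILVW]))"), 14),
}


@dataclass(frozen=True)
class MotifHit:
    """One motif match; coordinates are 1-based inclusive on the protein."""

    motif_class: str
    start: int
    end: int
    matched_seq: str

    def __post_init__(self) -> None:
        expected = MOTIF_PATTERNS[self.motif_class][1]
        if self.end - self.start + 1 != expected:
            raise ValueError(
                f"{self.motif_class} hit has length {self.end - self.start + 1}, "
                f"expected {expected}"
            )


@dataclass
class IQ67Domain:
    """A called 67-residue domain and its constituent motif hits."""

    start: int
    end: int
    iq_hits: list[MotifHit]
    m1510_hits: list[MotifHit] = field(default_factory=list)
    m1814_hits: list[MotifHit] = field(default_factory=list)
    spacing_ok: bool = False

    @property
    def n_iq(self) -> int:
        return len(self.iq_hits)


@dataclass
class ProteinProperties:
    length: int
    molecular_weight_da: float
    isoelectric_point: float
    serine_fraction: float

    @property
    def molecular_weight_kda(self) -> float:
        return self.molecular_weight_da / 1000.0


def scan_motif(protein: SeqRecord, motif_class: str) -> list[MotifHit]:
    """All (possibly overlapping) windows of ``protein`` matching the class.

    Hits are sorted by start coordinate (1-based inclusive).
    """
    if protein.alphabet_tag != "protein":
        raise ValueError("scan_motif requires a protein-alphabet record")
    pattern, length = MOTIF_PATTERNS[motif_class]
    hits = []
    for m in pattern.finditer(protein.sequence):
        start = m.start() + 1
        hits.append(MotifHit(motif_class, start, start + length - 1, m.group(1)))
    return hits


def _select_nonoverlapping(hits: list[MotifHit]) -> list[MotifHit]:
    """Greedy left-to-right selection of non-overlapping hits."""
    chosen: list[MotifHit] = []
    for h in hits:
        if not chosen or h.start > chosen[-1].end:
            chosen.append(h)
    return chosen


def call_iq67_domains(
    protein: SeqRecord,
    spacing_tolerance: int = 2,
    min_iq_copies: int = 1,
) -> list[IQ67Domain]:
    """Call IQ67 domains on a protein.

    A 67-residue window is anchored at each relaxed-IQ hit whose window fits
    inside the protein and contains at least ``min_iq_copies`` strict IQ
    hits (a lone relaxed match in an arbitrary protein is an IQ motif, not
    evidence of the full domain).  Overlapping calls are merged keeping the
    leftmost.  ``iq_hits`` lists the non-overlapping relaxed copies (which
    subsume the strict ones); ``spacing_ok`` is set when three copies show
    the canonical 11 and 15 intervening residues (each within
    ``spacing_tolerance``).
    """
    if len(protein) < DOMAIN_LENGTH:
        logger.warning(
            "protein %s shorter than %d aa; no domain can be called",
            protein.id,
            DOMAIN_LENGTH,
        )
        return []
    relaxed = scan_motif(protein, "IQ_relaxed")
    strict = scan_motif(protein, "IQ_strict")
    m1510 = scan_motif(protein, "M_1_5_10")
    m1814 = scan_motif(protein, "M_1_8_14")
    domains: list[IQ67Domain] = []
    last_end = 0
    for anchor in relaxed:
        start = anchor.start
        end = start + DOMAIN_LENGTH - 1
        if end > len(protein):
            continue
        if start <= last_end:  # overlaps a previously kept call
            continue
        n_strict = sum(1 for h in strict if h.start >= start and h.end <= end)
        if n_strict < min_iq_copies:
            continue
        in_window = [h for h in relaxed if h.start >= start and h.end <= end]
        iq_hits = _select_nonoverlapping(in_window)[:3]
        gaps = [
            iq_hits[i + 1].start - iq_hits[i].end - 1
            for i in range(len(iq_hits) - 1)
        ]
        spacing_ok = len(iq_hits) == 3 and all(
            abs(g - c) <= spacing_tolerance
            for g, c in zip(gaps, CANONICAL_SPACINGS)
        )
        domains.append(
            IQ67Domain(
                start=start,
                end=end,
                iq_hits=iq_hits,
                m1510_hits=[h for h in m1510 if start <= h.start and h.end <= end][:4],
                m1814_hits=[h for h in m1814 if start <= h.start and h.end <= end][:4],
                spacing_ok=spacing_ok,
            )
        )
        last_end = end
    return domains


# ExPASy average residue masses (Da); MW = sum + one water.
RESIDUE_MASSES = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

# EMBOSS-style pKa values; overridable via protein_properties(pka_table=...).
DEFAULT_PKA = {
    "Nterm": 8.6, "Cterm": 3.6,
    "K": 10.8, "R": 12.5, "H": 6.5,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
}


def net_charge(sequence: str, ph: float, pka_table: dict[str, float] | None = None) -> float:
    """Net charge of a peptide at the given pH (Henderson–Hasselbalch)."""
    pka = pka_table or DEFAULT_PKA
    charge = 1.0 / (1.0 + 10 ** (ph - pka["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (pka["Cterm"] - ph))
    for aa, n in ((aa, sequence.count(aa)) for aa in "KRH"):
        charge += n / (1.0 + 10 ** (ph - pka[aa]))
    for aa, n in ((aa, sequence.count(aa)) for aa in "DECY"):
        charge -= n / (1.0 + 10 ** (pka[aa] - ph))
    return charge


def isoelectric_point(
    sequence: str,
    pka_table: dict[str, float] | None = None,
    tol: float = 1e-6,
) -> float:
    """pH at which the net charge vanishes, solved by bisection on (0, 14)."""
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(sequence, mid, pka_table) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def protein_properties(
    protein: SeqRecord, pka_table: dict[str, float] | None = None
) -> ProteinProperties:
    """Length, average molecular weight, pI and serine fraction.

    Only the standard 20-letter alphabet is accepted; the first offending
    position is named in the error.
    """
    seq = protein.sequence
    for i, aa in enumerate(seq, start=1):
        if aa not in PROTEIN_ALPHABET:
            raise ValueError(
                f"protein {protein.id}: non-standard residue {aa!r} at position {i}"
            )
    mw = sum(RESIDUE_MASSES[aa] for aa in seq) + WATER_MASS
    return ProteinProperties(
        length=len(seq),
        molecular_weight_da=mw,
        isoelectric_point=isoelectric_point(seq, pka_table),
        serine_fraction=seq.count("S") / len(seq),
    )


def orf_to_protein_length(orf_bp: int) -> int:
    """Protein length implied by an ORF that includes its stop codon.

    An ORF of 1263 bp encodes 420 aa (1263/3 - 1).
    """
    if orf_bp % 3:
        raise ValueError(f"ORF length {orf_bp} not divisible by 3")
    return orf_bp // 3 - 1
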