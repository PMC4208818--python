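# Methods

This note documents the models, conventions and design choices behind
`iqdfam`, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and formats

All genomic intervals are 0-based half-open internally; conversion to and
from the 1-based inclusive convention of GFF3 happens only at the I/O
boundary. This keeps the window arithmetic of the tandem and synteny rules
(both phrased over 100-kb regions) free of off-by-one ambiguity. When a
gene carries several mRNAs, the first listed transcript is kept with a
logged warning — the analyses here treat one model per locus. ORF lengths
are taken to include the stop codon, so protein length = ORF/3 − 1
(an ORF of 1263 bp encodes 420 aa); the shipped 67-gene soybean table is
consistent with this convention at every row.

## Domain model

The IQ67 domain is modelled as a 67-residue window containing 1–3 IQ
motifs (strict `IQxxxRGxxxR`; relaxed `[ILV]QxxxRxxxx[RK]`) separated by
11 and 15 intervening residues, overlapping 1–4 copies each of the
1-5-10 and 1-8-14 Ca²⁺-dependent motifs. Conventions:

- *Spacing* counts intervening residues between the last residue of one
  IQ copy and the first of the next; `spacing_ok` allows a configurable
  tolerance (default ±2) around (11, 15), since real members deviate from
  the canonical spacing.
- *Anchoring*: the domain window starts at the first residue of its first
  IQ copy — the simplest deterministic convention that places codons
  16/17 inside every member's domain.
- *Calling*: a window anchored at a relaxed-IQ hit is called a domain
  when it contains at least `min_iq_copies` (default 1) **strict** IQ
  hits. A lone relaxed match in an arbitrary protein is an IQ motif, not
  evidence of the full domain; requiring a strict copy keeps the
  false-call rate on shuffled realistic-composition proteins below 1%
  while every canonical domain (which carries strict copies) is still
  called. Overlapping windows are merged keeping the leftmost.
- *Overlap* of Ca²⁺-dependent motifs with IQ copies is reported but not
  required — it is a family hallmark, not a per-protein filter.

Molecular weight uses ExPASy average residue masses plus one water; pI is
the bisection root of the Henderson–Hasselbalch net-charge function under
an EMBOSS-style pKa table (shipped in code, overridable). Different pKa
tables shift pI by a few tenths of a unit; no published pI value is
treated as an exact target.

## Intron phases

Phase is defined on the coding sequence only (UTR exons are ignored),
walked in transcription order so it is strand-invariant: phase 0 falls
between codons, phase 1 after the first nucleotide, phase 2 after the
second. The diagnostic family intron satisfies
`cds_offset = 3 × (domain_start_codon − 1 + 16)` with phase 0. Paralog
structure comparison reduces each gene to its intron-phase vector:
identical vectors are *conserved*, vectors at edit distance 1 (one intron
inserted or deleted) are *gain/loss candidates*, anything else is
*divergent*. The edit-distance rule operationalizes qualitative
gain/loss calls reproducibly; inferring the direction of gain vs loss
requires outgroup species and is out of scope.

## Duplication typing

Tandem: same chromosome, at most 5 annotated genes strictly between the
pair (all genes by default; a protein-coding-only flag exists because the
counting universe is ambiguous in the field's usage), and the span from
the 5′-most gene start to the 3′-most gene end within 100 kb. The
"five or fewer" threshold is used because it is the operative protocol
value; a stricter "three or fewer" variant appears in some descriptions
and is reachable via `max_intervening=3`. Segmental: the two genes lie on
partner intervals of a supplied duplicated-block set. Tandem takes
precedence when both criteria fire — the mutually exclusive S/T/O typing
needs an order, and physical adjacency is the stronger signal. Pairs
matching neither rule are typed O (e.g. retrotransposition products).

## Ka/Ks and dating

The estimator is unweighted Nei–Gojobori (1986): fractional synonymous
site counts per codon (a change producing a stop counts as
nonsynonymous), averaged over both sequences; difference counts averaged
over all orderings of multi-position codon changes, skipping pathways
through stop codons unless all are blocked; Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3) applied to both proportions, raising an error at
p ≥ 3/4. Codon columns containing a gap or stop are excluded from both
site and difference counts, so S + N = 3 × counted columns exactly.
NG86 was chosen over a maximum-likelihood codon model because it is fully
specified, hand-checkable and symmetric; the published Ka/Ks point
estimates of the soybean pairs came from an ML fit and are treated as
inputs, not as values to reproduce from sequence. Dating applies the
soybean synonymous clock T = Ks/(2λ)×10⁻⁶ Mya with
λ = 6.1×10⁻⁹ substitutions/site/year; dates are reported to 2 decimals,
rates to 3–4. Selection classes: Ka/Ks < 1 purifying, = 1 (±10⁻⁹)
neutral, > 1 positive.

Protein alignment for back-threading is delegated to a pairwise global
aligner (BLOSUM62, affine gaps −11/−1); multiple alignment is expected to
come from an external aligner.

## Microsynteny

Segments are the 100-kb flanks around each anchor gene (clipped to the
chromosome), with retroelements/transposons excluded and tandem arrays
collapsed to their 5′-most member (neighbors are an array when they
satisfy the tandem rule *and* align above the homology gate — reusing the
only tandem definition in the pipeline). Homology between segments is a
Smith–Waterman score gate (BLOSUM62, affine gaps) standing in for a
BLASTP E-value cutoff: a full E-value statistics stack is out of scope
and the criterion is a binary gate. The default threshold (60) was
calibrated once on a seeded null of 1000 random protein pairs
(120–300 aa): maximum null score 56, so unrelated proteins pass at
< 0.1%. Conserved pairs are reciprocal best non-self matches; a block
requires ≥3 of them (anchor pair counted by default; flag provided since
either reading is defensible), and ≥5 flanking (non-anchor) pairs flag a
large-scale duplication origin. Quality is 100 × 2P/(Gₐ+G_b) — the
conserved fraction of the two cleaned gene lists; the formula is one
concrete reading of "sum of the total number of genes in both conserved
regions" as the denominator, and is stated here prominently because other
readings exist. Orientation (same vs inverted) is the majority sign of
pairwise order concordance among matched genes.

## Phylogenetics

Distances are p-distances over mutually ungapped columns — the simplest
defensible choice for full-length protein trees when no substitution
model is claimed; the distance input is pluggable. NJ is the Saitou–Nei
agglomeration with the standard Q criterion; ties are broken by the
lexicographically smallest leaf label of the candidate clusters, making
the topology independent of input order. On additive matrices NJ
recovers the generating topology and exact branch lengths (verified
against brute-force least-squares topology fitting and against an
independent NJ implementation). Bootstrap resamples alignment columns
with replacement (seeded NumPy generator); support of an internal
bipartition is the fraction of replicate trees containing it. Sister
pairs are cherries with support ≥ `min_support` (default 0.5 — "strong
support" has no canonical number; the threshold is configuration).

## Expression and qPCR

RPKM = count × 10⁹/(gene length in bp × library size). Clustering uses
d = 1 − Pearson r with complete linkage (scipy); a constant profile has
undefined correlation and is assigned distance 1 to everything, with a
warning, to keep the clustering total. Tissue preference is the argmax
condition (ties broken alphabetically for determinism), with a
single-tissue flag when the top condition exceeds the runner-up by a
dominance ratio (default 2×). ΔCT = mean target CT − mean reference CT
per sample, ΔΔCT = ΔCT(treatment) − ΔCT(control), fold = 2^−ΔΔCT, so the
control is exactly 1. Regulation calls: *down* if every fold < 0.5
(0.5 itself is not down), *up* if any fold > 2 and none below 0.5,
*unchanged* inside the band, *mixed* otherwise. The up threshold of 2 is
deliberately stricter than "any fold above 1": one-point folds barely
above unity are within assay noise. Amplification-efficiency correction
is not modelled.

## Synthetic data: what it emulates, and what it does not

`generate_family_genome` (defaults: 4 chromosomes × 600 kb, 8 IQD genes
of which 1 tandem pair and 2 segmental-block pairs, 40 background genes,
Ka/Ks targets 0.03/0.12) implants:

- a canonical 67-aa domain template — three strict IQ copies at the
  11/15 spacing, one 1-5-10 and one 1-8-14 copy in the spacers — inside
  Q-free flanks, so each IQD gene yields exactly one expected call;
- the phase-0 intron between domain codons 16/17 (plus any extra
  introns from `intron_plan`);
- tandem pairs placed adjacently and segmental blocks of one IQD gene
  with 3+3 collinear background flanks, duplicated onto another
  chromosome with divergence applied per gene;
- background genes with realistic average residue composition, serving
  as scanner nulls and alignment-score nulls.

The divergence targets (Ka 0.03, Ks 0.12) sit in the middle of the
published soybean range (Ka 0.017–0.067, Ks 0.078–0.219); the 8/40 gene
counts and 4×600 kb layout are a desk-scale rendering of the family
(the real survey spans 67 genes on 20 chromosomes) chosen so the full
ground-truth recovery suite runs in seconds.

`mutate_codon_sequence` inverts the targets through the Jukes–Cantor
correction to expected proportions p = (3/4)(1 − e^(−4d/3)), then places
that many synonymous and nonsynonymous single-nucleotide changes at
distinct sites in seeded random order (no indels, no stops; direct
placement rather than accept/reject sampling, which has the same
distribution of NG86-countable differences with fewer moving parts).
Domain codons of duplicate copies accept only synonymous changes,
emulating the purifying selection that keeps real members' domains
intact. Mean NG86 estimates recover the targets within a few percent at
450 codons.

Expression counts are negative-binomial (dispersion 0.1 by default,
`None` = noise off) around baseline × designed fold, scaled by library
size; qPCR tables encode fold F as a target-CT shift of −log₂F against a
constant reference CT, with Gaussian cycle noise.

What passing these tests does *not* show about real data: the generator
has no indels, no alternative transcripts, no UTRs, no pseudogenes, no
compositional heterogeneity along chromosomes, and its duplicates
diverge by a single homogeneous substitution process. Detection
thresholds tuned here (homology gate, spacing tolerance) are sensible
starting points, not validated calibrations for any particular genome.

## Numerical and degenerate-input conventions

Proteins shorter than 67 aa yield no domain calls (warning, not error).
Ka/Ks is undefined at Ks = 0 and raises; saturated proportions
(p ≥ 3/4) raise rather than returning infinities. NJ requires ≥3 taxa;
negative branch lengths are reported as computed (not clamped) so
additive matrices round-trip exactly. All randomness flows through
seeded `numpy.random.default_rng` generators; every generator function
is byte-deterministic for a fixed seed.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` use the desk-scale defaults
above: 31 published pairs for dating, 67 published genes for the ORF
convention, one synthetic family (8 IQD + 40 background genes) for
scanner/duplication/synteny recovery, 20 random 6-taxon additive
matrices for NJ, 50 seeds × 450 codons for Ka/Ks recovery, 100 shuffled
500-aa proteins for the scanner null, and 3-replicate qPCR tables.
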