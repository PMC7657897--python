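# Methods

## Degenerate motif scanning

Patterns are IUPAC nucleotide strings; a window matches within *k*
mismatches when its symbol-wise distance — the number of positions whose
base falls outside the symbol's allowed set — is at most *k*. Because
each symbol is evaluated independently, this equals the minimal Hamming
distance over all concrete sequences the pattern denotes; the test suite
checks that equivalence against a literal enumeration oracle. Matching
is substitution-only (no indels): the near-miss concept the pipeline
reports is "a point mutation away from functional", which is a
substitution by definition.

Policy choices:

- **Subject `N` matches nothing**, not even pattern `N`. An undetermined
  assembly base cannot confirm a motif; the alternative (N matches
  everything) inflates hit counts in low-quality regions.
- **Overlapping hits are all reported**; pairing requires non-overlap,
  since a cooperative pair needs two distinct sites.
- **Strand policy defaults to forward-only**, matching how the upstream
  regions are annotated; `--strands both` reports reverse-strand hits in
  forward coordinates. Whether the original survey considered the
  reverse strand is not stated anywhere we could anchor to, so the
  default stays conservative and the flag exists.
- Hits are sorted by (start, strand, pattern label); output is
  deterministic.

## Pairing and upstream coordinates

The gap between two hits counts bases strictly between their footprints:
under this convention the published paired E-box
(`CAGGTG…25 intervening…CAGGTG` in a 31-mer) has gap 19, consistent with
the "within 19 bases" phrasing, and 19 is the default `max_gap`. It is
the only convention that reconciles the printed fragment with the
printed distance, which is why it was adopted. Pairs where exactly one
member is a near-miss are a separate *presumptive* category rather than
being mixed with exact pairs.

A region's last base is taken to abut the transcription start site, so a
base at 1-based position *p* in a region of length *L* lies *L − p + 1*
bases upstream. Both edges (distal, proximal) are reported for every
feature because "X–Y bases upstream" in prose can refer to either edge;
for the published pair the composite spans 970 (distal) to 940
(proximal).

## CPS functional typing

Diagnostic positions — the Cys-His-Glu catalytic triad of the glutamine
amidotransferase domain plus the two glutamine-binding residues — are
supplied in a YAML `DiagnosticSpec`, not hard-coded: the source figures
mark them graphically without printing residue numbers, so the shipped
`diagnostic_spec_template.yaml` anchors placeholder positions inside the
residue 278–397 window of interest and is meant to be completed from an
annotated alignment. The classification logic is position-agnostic.

Positions are mapped through the alignment by reference-anchored
numbering: position *p* maps to the column holding the *p*-th non-gap
character of the anchor row. Each sequence's residue at a mapped column
is *match*, *divergent* or *gap*; `X` is divergent-with-flag (an unknown
residue cannot confirm a match). The decision table (README) is total
over the 3⁵ state space and exhaustively enumerated in tests. A gap at
any diagnostic position yields INDETERMINATE rather than a divergence
call: absence of evidence, not evidence of loss. Only the configured
positions are consulted — no weighting, no phylogenetic correction —
mirroring the qualitative rule the classification reproduces.

Unaligned queries are aligned to the anchor with a global affine-gap
aligner (Biopython's `PairwiseAligner`, BLOSUM62, a gap of length *L*
costing 11 + *L*·1 — common protein defaults, configurable). Tie-breaks
among co-optimal alignments follow the aligner's canonical enumeration
order; the tested contract is score optimality, verified against an
exhaustive enumeration oracle for short sequences. Column conservation
is the fraction of non-gap rows sharing the modal residue (all-gap
columns are NaN), with a default conserved threshold of 1.0.

## In-silico PCR

The forward primer anneals to the template as written; the reverse
primer's site on the template is its reverse complement, downstream.
The amplicon spans both footprints inclusively (the standard product
definition, under which the study pair yields 399 = 19 + 361 + 19 bp).
The 3′-terminal base of each primer must match even when internal
mismatches are allowed (polymerase extension requires a paired 3′ end);
default mismatch budget 0. All (forward, downstream-reverse) site
combinations are reported — determinism over heuristics.

## Synthetic data

`gen_promoter` draws background bases i.i.d. with P(G)=P(C)=gc/2
(default gc 0.41, a typical teleost genomic value; default length
3500 bp, the width of the surveyed upstream windows) and overwrites it
with the configured implants, emitting a truth list alongside. Chance
background occurrences of a motif are *not* suppressed — that would bias
the background — so recovery tests accept extra hits exactly where an
independent enumeration oracle confirms an occurrence. The i.i.d. model
has no dinucleotide structure, CpG effects or repeat content; passing
recovery tests therefore demonstrates scanner correctness, not
performance on real promoters.

`gen_protein_family` applies i.i.d. substitutions (default rate 0.05, a
moderate within-family divergence) to a reference at all non-diagnostic
sites and clamps diagnostic sites to the assigned functional class:
GLN_UTILIZING keeps every expected residue; the intermediate class
replaces one glutamine-binding residue; AMMONIA_OBLIGATE removes the
catalytic Cys (or, optionally, both glutamine-binding residues). Because
clamping is exact, class recovery is complete by construction at any
background rate — the tests verify the bookkeeping, not robustness to
diagnostic-site noise, which real data would add. Both generators use
one explicit NumPy `default_rng` stream per call and record the seed in
output headers; identical seeds give byte-identical output.

## Problem sizes and numerical notes

The suite runs enumeration oracles at deliberately small sizes —
sequences ≤ 50 nt with patterns ≤ 8 nt (1000 random instances),
alignment enumeration at lengths ≤ 6, promoters of 2–3.5 kb, families of
~30 sequences × 60–80 residues — sizes at which brute force is exact and
fast while the code paths are identical to full-scale use; the naive
scanner is adequate at the 3.5 kb scale the pipeline targets. All
coordinates are 1-based inclusive internally and in reports, converted
to 0-based half-open only at the BED boundary. Scores and fractions are
exact floating-point sums of matrix entries; no tolerance is needed in
comparisons.

## Known limitations

- The classifier's accuracy on real CPS sequences depends entirely on a
  correctly filled diagnostic spec; the shipped template's positions are
  placeholders.
- Near-miss reporting proposes the first allowed base alphabetically as
  the replacement; when a degenerate symbol admits several, others are
  equally valid.
- In-silico PCR models perfect-specificity annealing with a hard 3′
  anchor; no melting-temperature or secondary-structure modelling.
- The built-in global aligner is a single-pair tool; multiple alignments
  should come from a dedicated aligner and be supplied as input.
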