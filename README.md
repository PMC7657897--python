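# cpscan

Sequence-analysis toolkit for the two computational questions behind the
adaptation of carbamoyl-phosphate synthetase (CPS) in the extremophile
soda-lake cichlids *Alcolapia*:

1. **Promoter E-box scanning.** Does the upstream region of *CPS III*
   carry a *paired* MyoD-preferred E-box — the cooperative-binding unit
   that could redirect expression to skeletal muscle — and how does it
   compare across species? The scanner finds exact and degenerate E-boxes
   (generic consensus `CANNTG`; MyoD preference `CAG(G/C)TG`, IUPAC
   `CAGSTG`), near-miss windows one (or *k*) substitutions away, and
   assembles close-proximity pairs with TSS-relative coordinates.
2. **CPS functional typing.** Is a CPS protein glutamine-utilizing
   (fish-type CPS III), ammonia-obligate (tetrapod-type CPS I), or an
   intermediate that retains the Cys-His-Glu catalytic triad of the
   glutamine amidotransferase domain but has lost one of the two
   glutamine-binding residues — the *Alcolapia* configuration that shifts
   substrate preference toward ammonia? Classification reads diagnostic
   residue states off a protein alignment through reference-anchored
   position mapping.

It also predicts PCR amplicons for the study's *CPS III* primer pair
(the 399 bp product used for expression profiling) and ships synthetic
generators — promoters with implanted motifs, protein families with
clamped diagnostic residues — so every stage is testable without
downloads.

## The core rules

A window `w` of length *m* matches IUPAC pattern `p` within *k*
mismatches when

    d(w, p) = Σᵢ 1[wᵢ ∉ set(pᵢ)] ≤ k

(substitution-only Hamming distance; a subject `N` matches nothing).
Two hits on one strand form a **pair** when the gap — bases strictly
between their footprints — is ≤ 19, the separation of the published
paired E-box. A pair is *exact* when both members match exactly and
*presumptive* when exactly one is a near-miss.

Functional typing follows a deterministic decision table over the five
diagnostic residues (triad C/H/E + two glutamine-binding):

| triad        | gln-binding    | class                           |
|--------------|----------------|---------------------------------|
| all match    | both match     | GLN_UTILIZING                   |
| all match    | one divergent  | INTERMEDIATE_AMMONIA_PREFERRING |
| all match    | both divergent | AMMONIA_OBLIGATE                |
| any divergent| —              | AMMONIA_OBLIGATE                |
| any gap anywhere              || INDETERMINATE                   |

## Worked example

The two published 31-nt upstream fragments around the candidate
enhancer:

```
$ printf ">A_alcalica\nCAGGTGACTGTGATTATATAGTTCACAGGTG\n>O_niloticus\nCAGGTGACTGTGATTATATAGTTCACAGGTT\n" > frags.fasta
$ cpscan scan-promoter frags.fasta --out demo
    species   region_id  length  n_Ebox_generic  n_Ebox_MyoD  exact_pairs  presumptive_pairs
 A_alcalica  A_alcalica      31               2            2            1                  0
O_niloticus O_niloticus      31               1            1            0                  1
```

*A. alcalica* carries two exact MyoD E-boxes 19 bases apart — one exact
pair. *O. niloticus* differs by a single substitution: one exact motif
plus a `CAGGTT` near-miss at the same 19-base separation, reported as a
presumptive pair (one point mutation from functional). Per-species BED6
tracks land next to the table:

```
$ cat demo/A_alcalica.bed
# BED6: chrom	start	end	name	score(mismatches)	strand
A_alcalica	0	6	Ebox_MyoD	0	+
A_alcalica	0	6	Ebox_generic	0	+
A_alcalica	25	31	Ebox_MyoD	0	+
A_alcalica	25	31	Ebox_generic	0	+
```

`cpscan report` additionally verifies the primer pair
(`CAGTGGGAGGTCAGATTGC` / `CTCACAGCGAAGCACAGGG`) on a geometry-matched
template:

```
In-silico PCR on the geometry-matched template:
  product 1-399, length 399 bp
```

Other subcommands: `classify-cps` (alignment or query+reference, with a
diagnostic-position YAML; a template ships in `src/cpscan/data/`),
`insilico-pcr`, `simulate-promoter`, `simulate-proteins`.

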