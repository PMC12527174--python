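# Methods

## Model

`u1scan` treats U1:RNA recognition as a purely sequence-level pairing
problem. A U1 is reduced to its 11-nt binding sequence; a *target* is
any transcript substring that can form a duplex with it under one of
seven annealing registers, with strict Watson–Crick pairing and an
allowance for mismatches. No thermodynamics are computed: the only
stringency parameter is the MAB, the minimum number of canonical
Watson–Crick pairs the duplex must retain. G:U wobbles are counted as
mismatches (a `wobble`-style relaxation is deliberately not offered —
tolerance of wobbles across arbitrary modified U1s is unknown, and
counting them as unpaired gives a conservative, well-defined MAB).

### Register geometry

For a binding sequence of length n (base target = its reverse
complement in DNA):

| register | edit on target string | target length | annealed bases |
|---|---|---|---|
| COM | none | n | n |
| BS1 / BS2 | insert 1 / 2 nt at an internal junction | n+1 / n+2 | n |
| BA1 / BA2 | delete 1 / 2 internal adjacent bases | n−1 / n−2 | n−1 / n−2 |
| ALS | delete 1 internal base, insert 2 nt at the site | n+1 | n−1 |
| ALA | delete 2 internal adjacent bases, insert 1 nt | n−1 | n−2 |

Edits are internal only ("never the first or last position"): terminal
bulges would be frayed ends, not registers. Insertions take every
nucleotide combination (4 for 1 nt, 16 for 2 nt). Mismatches are then
introduced as substitutions at paired positions, at least 1 nt away
from any bulge/loop so the hypothesised structure is preserved, up to
k = (register's annealed count) − MAB substitutions. Mismatches *are*
allowed at the duplex-terminal positions; only bulge/loop adjacency is
restricted. This choice is configurable in spirit (the disallowed-set
logic is localised in one geometry function) but the default reflects
the stated adjacency rule and nothing more.

Identical strings arising from different derivations (e.g. deleting
either G of a GG, or an ALS insertion recreating a BS1 string) are
merged; a merged query's annealed-base count is the **maximum** over its
derivations, and its reported register follows the attribution priority
COM > BS1 > BS2 > BA1 > ALS > BA2 > ALA (most annealed bases first, then
fewest edited bases). `verify_annealing` provides an independent
recount: it rebuilds the pairing implied by a claimed (register, edit
site, mismatch set) and counts matches, and the test suite asserts it
reproduces every stored count.

### Search

Because every tolerated deviation is materialised as its own query
string, search is exact, full-length, plus-strand substring matching
(equivalent to BLASTn with `word_size` = query length, the
configuration the external-parity mode runs). Databases hold
transcript-oriented sequence, so minus-strand genes are handled by
construction and the minus strand is never searched. N matches nothing.

### Databases and coordinates

GFF3/GTF + FASTA are parsed with gffutils/pyfaidx into per-transcript
models; every annotated transcript variant is a distinct model, so a
junction shared by two variants is counted twice downstream — this is
intentional, since a hit affects each RNA molecule separately.
Organellar sequences (MT/chrM/Mt/Pt by default) are excluded; U1 acts
in the nucleus.

Coordinates are GFF3 1-based closed internally; positions along the
unspliced pre-mRNA run 5′→3′ from the transcript start. Splice-site
distances use the no-zero convention (donor: last exonic base −1, first
intronic base +1; acceptor mirrored). The convention matters: the
walking range −10…+25 only contains 35 positions, and the canonical
footprint −3…+8 only 11, without a zero.

Four record categories are extracted per transcript: exons, introns,
and donor/acceptor windows of 15 nt per side around each junction
(truncated, never padded, at transcript ends). 15 nt exceeds the
longest query (n+2 = 13), so every junction-spanning hit is
discoverable inside a window; flanks below 12 are rejected as a
configuration error. The annotation source for the original splice-site
window extents is not stated anywhere authoritative, so the 15/15
default is chosen for completeness and is configurable.

### Merging and classification

Raw hits collapse by (transcript, 5′-most base). The 5′-most base is
the reference position of a target regardless of whether it is
canonically paired. A merged target spanning a donor junction (covering
offsets −1 and +1) is a donor target; acceptor mirrored; otherwise
exonic/intronic by containment. A footprint spanning both junction
types is only possible for micro-introns shorter than the footprint;
it is assigned donor and logged. Positional histograms count *all*
merged targets near a junction regardless of category (a fully intronic
target at +17 is still a +17 entry), since distal positions well beyond
any junction-spanning footprint are biologically relevant.

Position frequency matrices align footprints at their 5′-most base.
Merged targets can have footprints of different lengths (registers
change length by ±2), so columns are truncated to the shortest
contributing footprint; this keeps the invariant that every column sums
to the number of sites.

### Variant survey

Filters, in order (each excluded record carries exactly one reason
code; the kept set is order-independent because the predicates are
independent): significance exactly "Pathogenic" (case-insensitive);
condition not matching the cancer keyword list (default: cancer,
carcinoma, tumor, neoplasm — "degenerative disorders" is
operationalised as *not cancer-related*, the only exclusion stated
explicitly, rather than inventing a disease ontology); single-nucleotide
substitutions only; offset of the nearest donor junction (minimum
|offset| over all transcript variants, ties to the lexicographically
smallest transcript id) within −3…+8; not +1/+2; wild-type base equal
to the canonical consensus at that offset (C A G | G T A A G T A T for
−3…+8), since a pre-mismatched position is unlikely to weaken
endogenous U1 binding further. Absolute tallies from public ClinVar
releases are release-dependent and are not reproduced here.

### Walking design

For a mutant donor context, one design per no-zero offset in −10…+25
(35 designs), each the reverse complement of the 11-nt mutant window —
including windows that do not cover the mutation (flagged
`mutation_in_window=False` rather than dropped, since the full walk is
informative). A 36th, endogenous-adapted design replaces the single
binding-sequence base pairing the mutated offset (antiparallel mapping:
target offsets −3…+8 ↔ binding positions 11…1) with the complement of
the mutant base; offsets +1/+2 are refused. Binding sequences beginning
UU, GA or GG are flagged as 5′-destabilised but kept — removal is a
user policy, not a property of the enumeration. Ranking is ascending by
(donor targets, acceptor targets, total targets) at a stated MAB, ties
keeping walking order; donor-target count leads because splice sites
mediate both the on-target and the dominant off-target mechanism. The
per-position aggregate reports median and maximum counts per category
across mutations.

### PSI

PSI(exon) = Σ TPM(transcripts carrying the exon) / Σ TPM(all
transcripts of the gene), after dropping transcripts with TPM < 0.5
(and any novel transcripts upstream of this package). Genes with zero
surviving TPM give NaN, reported as missing; replicate averaging is the
arithmetic mean over tables where the value is defined (missing
dropped, never zero-filled). Candidate off-target exons are those with
a target within −10…+25 of their donor junction and average PSI < 0.5.

## Synthetic data

The generator emulates what the pipeline actually consumes: multi-exon
gene models (optionally minus-strand, optionally with a skip-exon
transcript variant sharing junctions, optionally with an organellar
decoy contig), uniform-ACGT background, GT at donor +1/+2, the
canonical donor consensus emitted per base with probability 0.8 at
−3…+8, AG at acceptor ends, and planted sites whose strings are built
from a chosen register + mismatch count (collisions are an error). It
does **not** model realistic splice-signal strength distributions,
codon structure, GC heterogeneity, repeats, or expression noise — so
passing tests demonstrate correctness of the combinatorics, search,
coordinate arithmetic and filtering rules, not calibrated performance
on real genomes. Everything derives from one integer seed and is
byte-identical across runs and platforms (no locale- or
path-order-dependent output).

Problem sizes used by the automated checks: the search-vs-oracle
equivalence runs 20 seeded genomes of roughly 2–4 kb at MABs 9–11
(the independent oracle is a vectorised scan of every 9–13-nt window
against every register geometry, so its cost grows with genome size,
and a few kilobases per seed already exercises every code path);
planted-site recovery uses three seeds of a 4-gene fixture carrying one
site of each register; the design-arithmetic check builds all
839 × 36 = 30,204 designs.

## Numerical and degenerate-input choices

- MABs below 6 trigger a warning (combinatorial growth), not an error.
- A query's annealed count under merge is a maximum, so MAB sweeps are
  monotone by construction; summaries assert the category partition on
  every run.
- Windows at transcript ends truncate; a first exon shorter than the
  flank yields a shorter exonic side, never padding.
- Binding sequences must be ≥ 8 nt (register geometry degenerates
  below that); RNA and DNA spellings are interconverted on input.
- Ties in nearest-junction assignment prefer donors, then the smaller
  offset; ties in design ranking keep walking order.

## Known limitations

No duplex free energies (ranking within a MAB level is positional, not
thermodynamic); no chemical-modification modelling (2′-O-methyl,
pseudouridine); no read alignment or TPM quantification (TPM tables are
inputs); no trans-splicing or circular RNAs; genome-scale absolute
target counts depend on annotation releases and are out of scope for
the bundled fixtures.
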