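# u1scan

Transcriptome-wide binding-site ("targetome") prediction and design of
modified U1 snRNAs.

The 5′-terminal 11 nucleotides of U1 snRNA (5′-AUACUUACCUG-3′ in humans,
the *binding sequence*) base-pair with donor splice sites (5′-SSs) to
initiate splicing. Modified U1s whose binding sequence is adapted to a
mutant 5′-SS can rescue exon inclusion, which makes them attractive
therapeutic candidates — but the endogenous U1 is known to tolerate
bulges, asymmetric loops and mismatches, so a modified U1 may bind far
more places than its intended target. `u1scan` makes that off-target
space explicit:

- **Register enumeration** — a binding sequence is expanded into every
  target string realisable under seven annealing registers: perfect
  complementarity (COM), 1- and 2-nt bulges on the target strand
  (BS1/BS2), on the U1 strand (BA1/BA2), and asymmetric loops (ALS/ALA),
  plus Watson–Crick mismatches placed at least 1 nt away from any
  bulge/loop. G:U wobble pairs count as mismatches. Selectivity is
  controlled by the **MAB** — the minimum number of annealed
  (strict Watson–Crick) base pairs a target must retain; MAB 11 means a
  fully paired 11-mer, MAB 6 (≈55% complementarity) is the loosest level
  commonly considered functional.
- **Exact search** — each query string is searched, plus strand only,
  against exon, intron and splice-site-window databases built from a
  genome FASTA + GFF3/GTF in transcript orientation (BLASTn with
  `word_size` = query length reduces to exact matching; a parity mode
  shells out to BLAST+ for bit-level comparison).
- **Targetome assembly** — hits are merged (same transcript + same
  5′-most base = one target; different transcript variants = distinct
  targets) and classified as exonic, intronic, donor (5′-SS) or acceptor
  (3′-SS) targets; splice-site categories require the footprint to span
  the junction. Splice-site distances use a no-zero offset convention:
  the last exonic base of a donor is −1, the first intronic base +1, and
  the canonical U1 footprint occupies −3…+8.
- **Variant survey** — ClinVar-style tables are filtered to pathogenic,
  non-cancer, single-nucleotide donor-site variants at offsets −3…+8
  (excluding +1/+2, which abolish splicing, and positions already
  mismatched to the endogenous U1).
- **Walking design** — for a mutation, 35 candidate U1s are designed by
  sliding the 11-nt target window across offsets −10…+25 plus one
  endogenous-adapted design ("E"); each design is flagged if its binding
  sequence starts with a destabilising UU/GA/GG dinucleotide, and
  designs are ranked by predicted splice-site off-target load.
- **PSI utilities** — per-exon percent-spliced-in from transcript-level
  TPM (transcripts with TPM < 0.5 dropped), and selection of candidate
  off-target exons (donor-proximal hit + average PSI < 0.5).
- **Synthetic fixtures** — a deterministic generator for toy genomes
  with consensus-biased donors, planted target sites of known
  register/mismatch structure, variant tables and TPM tables, each with
  a truth table.

## Worked example

```sh
u1scan simulate --seed 17 --out demo
printf 'U1-demo\tAUACUUACCUG\n' > demo/binding.txt
u1scan predict --binding demo/binding.txt \
    --gff demo/annotation.gff3 --fasta demo/genome.fa \
    --mab 9 --out demo/targets
```

stderr reports `U1-demo: 6 targets at MAB 9`, and
`demo/targets/U1-demo.summary.json` contains (abridged):

```json
"totals":      {"9": 6, "10": 5, "11": 3},
"by_category": {"9": {"donor": 6, "acceptor": 0, "exonic": 0, "intronic": 0}},
"by_register": {"9": {"COM": 3, "BS1": 1, "BS2": 1, "BA2": 1, ...}}
```

Read: at the loosest level (MAB 9, up to two mismatches from a fully
paired register) the endogenous binding sequence finds 6 targets in the
toy transcriptome, all spanning donor junctions — 3 perfectly
complementary, the rest via bulged registers — and tightening the
requirement to full pairing (MAB 11) leaves 3. The accompanying
`U1-demo.targets.tsv` lists each target with its transcript, genomic
span, category, register, annealed-base count and splice offset, e.g.

```
tx1.1  chr1  166  176  +  106  donor  COM  11  donor  -3  CAGGTAAGTAT
```

a perfectly complementary target whose 5′-most base sits at the
canonical −3 position of a donor site.

Other subcommands: `build-db`, `summarize`, `positions` (junction-offset
histograms), `variants`, `walk` (per-mutation design + ranking), `psi`,
`candidates`, `simulate`. Each documents its flags under `--help`.

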