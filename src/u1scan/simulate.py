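"""Deterministic synthetic genomes, variants and expression tables.

Generates toy multi-exon gene models (FASTA + GFF3) with consensus-biased
donor sites, deliberately planted U1 target sites of known register and
mismatch structure, synthetic ClinVar-style variant tables, and
transcript-level TPM tables -- each accompanied by a machine-readable
truth table, so every pipeline stage is testable without downloads.

Background sequence is drawn uniformly from ACGT (so chance-hit rates are
analytically ~L/4^n per position); donor junctions carry GT at +1/+2 and,
with configurable probability per base, the canonical target consensus at
the remaining -3..+8 positions.  The same seed and spec always produce
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import TranscriptModel, offset_to_position
from .registers import (
    REGISTERS,
    BindingSequence,
    RNU1_1,
    derive_base_target,
    _apply_register,
    _edit_sites,
    _geometry,
)
from .variants import CANONICAL_TARGET_CONSENSUS, DEFAULT_CANCER_KEYWORDS

__all__ = [
    "PlantedSite",
    "PlantedVariant",
    "FixtureSpec",
    "GenomeFixture",
    "generate_genome",
    "generate_variants",
    "generate_tpm",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
DONOR_CONSENSUS = "CAGGTAAGTAT"  # offsets -3..+8


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PlantedSite:
    """A target site to plant at a known place.

    ``anchor`` locates the 5'-most base: ``("donor", i, off)`` /
    ``("acceptor", i, off)`` place it at SpliceOffset ``off`` from the
    gene's i-th junction of that kind; ``("t", pos)`` places it at an
    absolute pre-mRNA coordinate.  The planted string is derived from the
    fixture's binding sequence under ``register`` with ``mismatches``
    substitutions (or taken verbatim from ``sequence``).
    """

    gene: int
    category: str  # expected classification
    anchor: tuple
    register: str = "COM"
    mismatches: int = 0
    sequence: str | None = None


@dataclass(frozen=True)
class PlantedVariant:
    gene: int
    intron_index: int
    offset: int  # SpliceOffset from the donor junction, no zero
    significance: str = "Pathogenic"
    condition: str = "synthetic degenerative disorder"
    alt: str | None = None  # transcript-oriented mutant base; random if None


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic fixture."""

    seed: int = 0
    n_genes: int = 2
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_length: tuple[int, int] = (40, 120)
    intron_length: tuple[int, int] = (60, 200)
    intergenic: int = 60
    donor_consensus_strength: float = 0.8
    minus_strand_genes: tuple[int, ...] = ()
    variants_per_gene: int = 1  # extra transcript variants share the junctions
    include_mt_decoy: bool = False
    binding: BindingSequence = RNU1_1
    planted_sites: tuple[PlantedSite, ...] = ()
    planted_variants: tuple[PlantedVariant, ...] = ()
    tpm_values: dict[str, float] | None = None


@dataclass
class GenomeFixture:
    fasta_path: Path
    gff_path: Path
    truth_path: Path
    models: list[TranscriptModel]
    premrna: dict[str, str]  # primary transcript id -> transcript-oriented sequence
    truth: list[dict]


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _site_string(
    site: PlantedSite, binding: BindingSequence, rng: np.random.Generator
) -> tuple[str, int]:
    """Planted string and its designed annealed-base count."""
    base = derive_base_target(binding)
    n = len(base)
    reg = REGISTERS[site.register]
    if site.sequence is not None:
        return site.sequence.upper(), reg.base_annealed(n) - site.mismatches
    sites = _edit_sites(site.register, n)
    edit = sites[int(rng.integers(len(sites)))] if site.register != "COM" else None
    insert_len = {"COM": 0, "BS1": 1, "BS2": 2, "BA1": 0, "BA2": 0, "ALS": 2, "ALA": 1}[
        site.register
    ]
    insert = _rand_seq(rng, insert_len)
    seq = _apply_register(base, site.register, edit, insert)
    if site.mismatches:
        _, _, disallowed = _geometry(site.register, edit, n)
        allowed = [p for p in range(1, len(seq) + 1) if p not in disallowed]
        picks = rng.choice(len(allowed), size=site.mismatches, replace=False)
        chars = list(seq)
        for pi in sorted(int(p) for p in picks):
            p = allowed[pi]
            options = [b for b in "ACGT" if b != chars[p - 1]]
            chars[p - 1] = options[int(rng.integers(3))]
        seq = "".join(chars)
    return seq, reg.base_annealed(n) - site.mismatches


def _gene_structure(spec: FixtureSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    n_exons = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
    lengths = []
    for i in range(n_exons):
        lengths.append(int(rng.integers(spec.exon_length[0], spec.exon_length[1] + 1)))
        if i < n_exons - 1:
            lengths.append(int(rng.integers(spec.intron_length[0], spec.intron_length[1] + 1)))
    # exon/intron intervals in pre-mRNA coordinates
    out, pos = [], 1
    for L in lengths:
        out.append((pos, pos + L - 1))
        pos += L
    return out


def generate_genome(spec: FixtureSpec, out_dir: str | Path) -> GenomeFixture:
    """Write FASTA + GFF3 + truth TSV for the spec; deterministic in seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    genes = []  # (gene_idx, intervals, premrna, strand)
    truth: list[dict] = []
    for g in range(spec.n_genes):
        intervals = _gene_structure(spec, rng)
        L = intervals[-1][1]
        pre = list(_rand_seq(rng, L))
        exon_iv = intervals[0::2]
        # donor/acceptor consensus biasing
        for (e_start, e_end), (i_start, i_end) in zip(exon_iv, intervals[1::2]):
            boundary = e_end
            offsets = [o for o in range(-3, 9) if o != 0]
            for off, base in zip(offsets, DONOR_CONSENSUS):
                pos = offset_to_position(off, boundary)
                if off in (1, 2) or rng.random() < spec.donor_consensus_strength:
                    pre[pos - 1] = base
            pre[i_end - 2] = "A"  # acceptor AG
            pre[i_end - 1] = "G"
        strand = "-" if g in spec.minus_strand_genes else "+"
        genes.append([g, intervals, pre, strand])

    # plant sites (after consensus biasing; planted content wins)
    planted_intervals: dict[int, list[tuple[int, int, PlantedSite]]] = {}
    for site in spec.planted_sites:
        g = site.gene
        _, intervals, pre, _ = genes[g]
        exon_iv = intervals[0::2]
        intron_iv = intervals[1::2]
        seq, designed = _site_string(site, spec.binding, rng)
        kind = site.anchor[0]
        if kind == "t":
            t5 = site.anchor[1]
            offset = None
        elif kind in ("donor", "acceptor"):
            idx, off = site.anchor[1], site.anchor[2]
            boundary = exon_iv[idx][1] if kind == "donor" else intron_iv[idx][1]
            t5 = offset_to_position(off, boundary)
            offset = off
        else:
            raise ValueError(f"unknown anchor {site.anchor!r}")
        t3 = t5 + len(seq) - 1
        if t5 < 1 or t3 > intervals[-1][1]:
            raise ValueError(f"planted site {site} outside transcript (t {t5}-{t3})")
        for a, b, other in planted_intervals.get(g, ()):
            if t5 <= b and a <= t3:
                raise ValueError(f"planted sites collide on gene {g}: {site} vs {other}")
        planted_intervals.setdefault(g, []).append((t5, t3, site))
        pre[t5 - 1 : t3] = list(seq)
        truth.append(
            {
                "site_id": f"site{len(truth) + 1}",
                "transcript_id": f"tx{g + 1}.1",
                "t5": t5,
                "length": len(seq),
                "category": site.category,
                "offset": offset if offset is not None else "",
                "register": site.register,
                "designed_annealed": designed,
                "sequence": seq,
            }
        )

    # assemble the contig and genomic exon coordinates
    contig_parts: list[str] = []
    gff_lines = ["##gff-version 3"]
    models: list[TranscriptModel] = []
    premrna: dict[str, str] = {}
    cursor = 0
    chrom = "chr1"
    for g, intervals, pre, strand in genes:
        contig_parts.append(_rand_seq(rng, spec.intergenic))
        cursor += spec.intergenic
        pre_s = "".join(pre)
        gstart, gend = cursor + 1, cursor + len(pre_s)
        contig_parts.append(pre_s if strand == "+" else _revcomp(pre_s))
        cursor = gend
        gene_id = f"gene{g + 1}"
        gff_lines.append(
            f"{chrom}\tu1scan\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\tID={gene_id}"
        )
        exon_iv = intervals[0::2]

        def g_interval(a: int, b: int) -> tuple[int, int]:
            if strand == "+":
                return gstart + a - 1, gstart + b - 1
            return gend - b + 1, gend - a + 1

        variant_exon_sets = [exon_iv]
        if spec.variants_per_gene >= 2 and len(exon_iv) >= 3:
            # second variant skips the second exon, sharing remaining junctions
            variant_exon_sets.append(exon_iv[:1] + exon_iv[2:])
        for v, ex_set in enumerate(variant_exon_sets):
            tid = f"tx{g + 1}.{v + 1}"
            tg = [g_interval(a, b) for a, b in ex_set]
            tstart, tend = min(s for s, _ in tg), max(e for _, e in tg)
            gff_lines.append(
                f"{chrom}\tu1scan\tmRNA\t{tstart}\t{tend}\t.\t{strand}\t.\tID={tid};Parent={gene_id}"
            )
            for k, (s, e) in enumerate(sorted(tg)):
                gff_lines.append(
                    f"{chrom}\tu1scan\texon\t{s}\t{e}\t.\t{strand}\t.\tID={tid}.e{k + 1};Parent={tid}"
                )
            models.append(TranscriptModel(tid, gene_id, chrom, strand, tg))
            if v == 0:
                premrna[tid] = pre_s
    contig_parts.append(_rand_seq(rng, spec.intergenic))
    contig = "".join(contig_parts)

    fasta_path = out_dir / "genome.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(contig), 70):
            fh.write(contig[i : i + 70] + "\n")
        if spec.include_mt_decoy:
            decoy_rng = np.random.default_rng(spec.seed + 10_007)
            fh.write(">MT\n" + _rand_seq(decoy_rng, 300) + "\n")
    if spec.include_mt_decoy:
        gff_lines.append("MT\tu1scan\tgene\t10\t250\t.\t+\t.\tID=geneMT")
        gff_lines.append("MT\tu1scan\tmRNA\t10\t250\t.\t+\t.\tID=txMT.1;Parent=geneMT")
        gff_lines.append("MT\tu1scan\texon\t10\t250\t.\t+\t.\tID=txMT.1.e1;Parent=txMT.1")

    gff_path = out_dir / "annotation.gff3"
    gff_path.write_text("\n".join(gff_lines) + "\n")

    truth_path = out_dir / "truth_sites.tsv"
    cols = ["site_id", "transcript_id", "t5", "length", "category", "offset",
            "register", "designed_annealed", "sequence"]
    with open(truth_path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in truth:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")

    return GenomeFixture(fasta_path, gff_path, truth_path, models, premrna, truth)


def generate_variants(spec: FixtureSpec, fixture: GenomeFixture, out_dir: str | Path) -> tuple[Path, Path]:
    """Synthetic ClinVar-style table + truth of which rows survive the filter."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 20_011)
    by_tid = {m.transcript_id: m for m in fixture.models}
    rows, truth_rows = [], []
    for i, pv in enumerate(spec.planted_variants):
        if pv.offset == 0:
            raise ValueError("splice offsets have no zero")
        tid = f"tx{pv.gene + 1}.1"
        m = by_tid[tid]
        pre = fixture.premrna[tid]
        boundary = m.donor_junctions[pv.intron_index].boundary
        t = offset_to_position(pv.offset, boundary)
        g = m.t2g(t)
        wt = pre[t - 1]
        alt = pv.alt
        if alt is None:
            options = [b for b in "ACGT" if b != wt]
            alt = options[int(rng.integers(3))]
        ref_g = wt if m.strand == "+" else wt.translate(_COMPLEMENT)
        alt_g = alt if m.strand == "+" else alt.translate(_COMPLEMENT)
        survives = (
            pv.significance.strip().lower() == "pathogenic"
            and not any(k in pv.condition.lower() for k in DEFAULT_CANCER_KEYWORDS)
            and pv.offset in CANONICAL_TARGET_CONSENSUS
            and pv.offset not in (1, 2)
            and wt == CANONICAL_TARGET_CONSENSUS[pv.offset]
        )
        rows.append(
            {
                "variant_id": f"var{i + 1}",
                "chrom": m.chromosome,
                "pos": g,
                "ref": ref_g,
                "alt": alt_g,
                "significance": pv.significance,
                "condition": pv.condition,
            }
        )
        truth_rows.append({"variant_id": f"var{i + 1}", "offset": pv.offset,
                           "wild_type_base": wt, "survives": survives})
    var_path = out_dir / "variants.tsv"
    cols = ["variant_id", "chrom", "pos", "ref", "alt", "significance", "condition"]
    with open(var_path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in cols) + "\n")
    truth_path = out_dir / "truth_variants.tsv"
    with open(truth_path, "w") as fh:
        fh.write("variant_id\toffset\twild_type_base\tsurvives\n")
        for r in truth_rows:
            fh.write(f"{r['variant_id']}\t{r['offset']}\t{r['wild_type_base']}\t{r['survives']}\n")
    return var_path, truth_path


def generate_tpm(spec: FixtureSpec, fixture: GenomeFixture, out_dir: str | Path) -> tuple[Path, Path, Path]:
    """TPM table, exon-membership table and definitional truth PSI.

    Exons are identified by their genomic interval, so an exon shared by
    transcript variants appears once with all carrying transcripts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 30_011)
    tpm: dict[str, float] = {}
    gene_map: dict[str, str] = {}
    for m in fixture.models:
        gene_map[m.transcript_id] = m.gene_id
        if spec.tpm_values and m.transcript_id in spec.tpm_values:
            tpm[m.transcript_id] = spec.tpm_values[m.transcript_id]
        else:
            tpm[m.transcript_id] = round(float(rng.uniform(0.0, 10.0)), 3)
    exon_members: dict[str, set[str]] = {}
    exon_gene: dict[str, str] = {}
    for m in fixture.models:
        for s, e in m.exons:
            exon_id = f"{m.gene_id}:{m.chromosome}:{min(s, e)}-{max(s, e)}"
            exon_members.setdefault(exon_id, set()).add(m.transcript_id)
            exon_gene[exon_id] = m.gene_id

    tpm_path = out_dir / "tpm.tsv"
    with open(tpm_path, "w") as fh:
        fh.write("transcript_id\tgene_id\ttpm\n")
        for t in sorted(tpm):
            fh.write(f"{t}\t{gene_map[t]}\t{tpm[t]}\n")
    members_path = out_dir / "exon_membership.tsv"
    with open(members_path, "w") as fh:
        fh.write("exon_id\ttranscript_id\n")
        for exon_id in sorted(exon_members):
            for t in sorted(exon_members[exon_id]):
                fh.write(f"{exon_id}\t{t}\n")

    # definitional truth PSI (TPM floor 0.5)
    surviving = {t: v for t, v in tpm.items() if v >= 0.5}
    gene_tot: dict[str, float] = {}
    for t, v in surviving.items():
        gene_tot[gene_map[t]] = gene_tot.get(gene_map[t], 0.0) + v
    truth_path = out_dir / "truth_psi.tsv"
    with open(truth_path, "w") as fh:
        fh.write("exon_id\tpsi\n")
        for exon_id in sorted(exon_members):
            denom = gene_tot.get(exon_gene[exon_id], 0.0)
            if denom == 0.0:
                fh.write(f"{exon_id}\tNA\n")
                continue
            num = sum(surviving.get(t, 0.0) for t in exon_members[exon_id])
            fh.write(f"{exon_id}\t{num / denom:.6f}\n")
    return tpm_path, members_path, truth_path
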