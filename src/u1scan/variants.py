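"""Survey of pathogenic donor-splice-site variants amenable to U1 rescue.

From a ClinVar-summary-style table (or VCF), keep single-nucleotide
variants that are (1) annotated "Pathogenic" and not cancer-related,
(2) located within the canonical U1 binding site, offsets -3..+8 of their
nearest annotated donor junction, excluding +1/+2 (those abolish splicing
altogether), and (3) not already mismatched to the endogenous U1 at the
wild-type base (such variants are unlikely to diminish U1 binding).
Every excluded record carries exactly one machine-readable reason code.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace

from pyfaidx import Fasta

from .annotation import TranscriptModel, splice_offset

log = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "CANONICAL_TARGET_CONSENSUS",
    "DEFAULT_CANCER_KEYWORDS",
    "DEFAULT_COLUMN_MAP",
    "parse_variants",
    "parse_variants_vcf",
    "annotate_offsets",
    "filter_pathogenic",
    "select_rescuable",
    "survey",
    "SurveyResult",
]

#: The canonical donor target (reverse complement of 5'-AUACUUACCUG-3')
#: aligned to offsets -3..+8 of the exon-intron boundary.
CANONICAL_TARGET_CONSENSUS: dict[int, str] = {
    -3: "C", -2: "A", -1: "G",
    1: "G", 2: "T", 3: "A", 4: "A", 5: "G", 6: "T", 7: "A", 8: "T",
}

RESCUABLE_OFFSETS = frozenset(o for o in CANONICAL_TARGET_CONSENSUS if o not in (1, 2))

DEFAULT_CANCER_KEYWORDS = ("cancer", "carcinoma", "tumor", "neoplasm")

DEFAULT_COLUMN_MAP = {
    "id": "variant_id",
    "chrom": "chrom",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
    "significance": "significance",
    "condition": "condition",
}


@dataclass(frozen=True)
class VariantRecord:
    """One parsed variant, optionally annotated with its donor offset."""

    variant_id: str
    chrom: str
    pos: int  # genomic, 1-based
    ref: str
    alt: str
    significance: str
    condition: str
    transcript_id: str | None = None
    offset: int | None = None  # SpliceOffset from nearest donor junction
    wild_type_base: str | None = None  # transcript-oriented base at the offset
    reason: str | None = None  # exclusion reason code, None while kept


def parse_variants(path: str, column_map: dict[str, str] | None = None) -> list[VariantRecord]:
    """Read a tab-delimited ClinVar-summary-like table.

    ``column_map`` maps the logical fields (id, chrom, pos, ref, alt,
    significance, condition) to the table's column names.  Rows without a
    usable position are dropped and the count logged.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    records: list[VariantRecord] = []
    dropped = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in cmap.values() if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"variant table lacks required columns: {missing}")
        for row in reader:
            pos_text = (row[cmap["pos"]] or "").strip()
            chrom = (row[cmap["chrom"]] or "").strip()
            if not pos_text or not chrom or not pos_text.lstrip("-").isdigit():
                dropped += 1
                continue
            records.append(
                VariantRecord(
                    variant_id=row[cmap["id"]].strip(),
                    chrom=chrom,
                    pos=int(pos_text),
                    ref=row[cmap["ref"]].strip().upper(),
                    alt=row[cmap["alt"]].strip().upper(),
                    significance=row[cmap["significance"]].strip(),
                    condition=row[cmap["condition"]].strip(),
                )
            )
    if dropped:
        log.info("dropped %d variant rows lacking genomic coordinates", dropped)
    return records


def parse_variants_vcf(path: str, sig_key: str = "CLNSIG", cond_key: str = "CLNDN") -> list[VariantRecord]:
    """Read variants from a (plain-text) VCF with ClinVar-style INFO keys."""
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    dropped = 0
    for v in VCF(path):
        if v.POS is None or not v.ALT:
            dropped += 1
            continue
        sig = v.INFO.get(sig_key) or ""
        cond = v.INFO.get(cond_key) or ""
        records.append(
            VariantRecord(
                variant_id=v.ID or f"{v.CHROM}:{v.POS}",
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF.upper(),
                alt=v.ALT[0].upper(),
                significance=str(sig).replace("_", " "),
                condition=str(cond).replace("_", " "),
            )
        )
    if dropped:
        log.info("dropped %d VCF records lacking coordinates or alleles", dropped)
    return records


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def annotate_offsets(
    variants: list[VariantRecord],
    models: list[TranscriptModel],
    fasta: Fasta | str | None = None,
) -> list[VariantRecord]:
    """Attach each variant's nearest donor junction, offset and wild-type base.

    The nearest donor is the junction minimising |offset| over all
    transcript variants; ties break toward the lexicographically smallest
    transcript id (logged).  The wild-type base is read in transcript
    orientation.  When a genome is supplied, a mismatch between the table's
    ref allele and the genome raises.
    """
    if isinstance(fasta, str):
        fasta = Fasta(fasta)
    out: list[VariantRecord] = []
    for v in variants:
        best_key = None
        best: tuple[str, int, TranscriptModel] | None = None
        tie = False
        for m in sorted(models, key=lambda m: m.transcript_id):
            if m.chromosome != v.chrom:
                continue
            s, e = m.span
            if not s <= v.pos <= e:
                continue
            t = m.g2t(v.pos)
            for j in m.donor_junctions:
                off = splice_offset(t, j.boundary)
                key = (abs(off), m.transcript_id)
                if best_key is None or key < best_key:
                    tie = best_key is not None and key[0] == best_key[0]
                    best_key, best = key, (m.transcript_id, off, m)
        if best is None:
            out.append(replace(v, reason="no_donor_window"))
            continue
        tid, off, m = best
        if tie:
            log.info("variant %s: |offset| tie broken toward transcript %s", v.variant_id, tid)
        wt = None
        if fasta is not None:
            base = str(fasta[v.chrom][v.pos - 1]).upper()
            if len(v.ref) == 1 and v.ref in "ACGT" and base != v.ref:
                raise ValueError(
                    f"variant {v.variant_id}: ref allele {v.ref} does not match genome base {base}"
                )
            wt = base if m.strand == "+" else base.translate(_COMPLEMENT)
        out.append(replace(v, transcript_id=tid, offset=off, wild_type_base=wt))
    return out


def _is_cancer(condition: str, keywords: tuple[str, ...]) -> bool:
    c = condition.lower()
    return any(k.lower() in c for k in keywords)


def filter_pathogenic(
    variants: list[VariantRecord],
    cancer_keywords: tuple[str, ...] = DEFAULT_CANCER_KEYWORDS,
) -> list[VariantRecord]:
    """Keep "Pathogenic" (exactly, case-insensitive) non-cancer variants.

    "Likely pathogenic", "Likely benign", "Benign" and blank significance
    are dropped, as are variants whose condition matches the cancer
    keyword list.  Excluded records are returned too, carrying a reason
    code; callers filter on ``reason is None``.
    """
    out: list[VariantRecord] = []
    for v in variants:
        if v.reason is not None:
            out.append(v)
        elif v.significance.strip().lower() != "pathogenic":
            out.append(replace(v, reason="not_pathogenic"))
        elif _is_cancer(v.condition, cancer_keywords):
            out.append(replace(v, reason="cancer_related"))
        else:
            out.append(v)
    return out


def select_rescuable(
    variants: list[VariantRecord],
    consensus: dict[int, str] = CANONICAL_TARGET_CONSENSUS,
) -> list[VariantRecord]:
    """Keep single-nucleotide variants within -3..+8, excluding +1/+2 and
    positions already mismatched to the endogenous U1."""
    out: list[VariantRecord] = []
    for v in variants:
        if v.reason is not None:
            out.append(v)
        elif len(v.ref) != 1 or len(v.alt) != 1 or v.ref not in "ACGT" or v.alt not in "ACGT":
            out.append(replace(v, reason="not_single_nucleotide"))
        elif v.offset is None:
            out.append(replace(v, reason="no_donor_window"))
        elif v.offset in (1, 2):
            out.append(replace(v, reason="position_plus1_plus2"))
        elif v.offset not in consensus:
            out.append(replace(v, reason="outside_canonical_window"))
        elif v.wild_type_base is not None and v.wild_type_base != consensus[v.offset]:
            out.append(replace(v, reason="pre_mismatched"))
        else:
            out.append(v)
    return out


@dataclass
class SurveyResult:
    """Kept and excluded variants plus unique variant/exon/gene tallies."""

    kept: list[VariantRecord]
    excluded: list[VariantRecord]
    n_variants: int
    n_exons: int
    n_genes: int

    def summary(self) -> dict[str, int]:
        return {
            "unique_variants": self.n_variants,
            "distinct_exons": self.n_exons,
            "distinct_genes": self.n_genes,
            "excluded": len(self.excluded),
        }


def survey(
    variants: list[VariantRecord],
    models: list[TranscriptModel],
    fasta: Fasta | str | None = None,
    cancer_keywords: tuple[str, ...] = DEFAULT_CANCER_KEYWORDS,
) -> SurveyResult:
    """Full variant filter: annotate offsets, then apply both filters.

    Exons are tallied by the genomic boundary of the affected donor
    junction (so the same physical exon shared by transcript variants
    counts once); genes by the transcript's gene id.
    """
    annotated = annotate_offsets(variants, models, fasta)
    filtered = select_rescuable(filter_pathogenic(annotated, cancer_keywords))
    kept = [v for v in filtered if v.reason is None]
    excluded = [v for v in filtered if v.reason is not None]
    by_tid = {m.transcript_id: m for m in models}
    exons, genes = set(), set()
    for v in kept:
        m = by_tid[v.transcript_id]
        genes.add(m.gene_id)
        donor_g = next(
            (j.genomic_boundary for j in m.donor_junctions
             if splice_offset(m.g2t(v.pos), j.boundary) == v.offset),
            None,
        )
        exons.add((v.chrom, donor_g))
    return SurveyResult(
        kept, excluded,
        n_variants=len({(v.chrom, v.pos, v.ref, v.alt) for v in kept}),
        n_exons=len(exons),
        n_genes=len(genes),
    )
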