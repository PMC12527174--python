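"""Transcript models and sequence databases from genome FASTA + GFF3/GTF.

All sequence is handled in *transcript orientation*: minus-strand
transcripts are reverse complemented, so downstream search is plus-strand
only.  Positions along the unspliced pre-mRNA use a 1-based coordinate
running 5'->3' from the transcript start.  Distances from splice junctions
use a signed offset with no zero: at a donor (exon->intron) junction the
last exonic base is -1 and the first intronic base is +1; at an acceptor
(intron->exon) junction the last intronic base is -1 and the first exonic
base is +1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import gffutils
from pyfaidx import Fasta

log = logging.getLogger(__name__)

__all__ = [
    "AnnotationError",
    "ConfigurationError",
    "Junction",
    "TranscriptModel",
    "DbRecord",
    "SequenceDatabase",
    "splice_offset",
    "offset_to_position",
    "load_annotation",
    "build_databases",
    "DEFAULT_EXCLUDE_SEQIDS",
]

#: Organellar sequences excluded by default (U1 acts in the nucleus).
DEFAULT_EXCLUDE_SEQIDS = ("MT", "chrM", "Mt", "Pt", "chrMT", "ChrM", "ChrC", "Pltd")

#: Window flanks must exceed the longest query minus one (13-nt BS2 queries)
#: or junction-crossing hits could be missed.
MIN_FLANK = 12

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AnnotationError(RuntimeError):
    """Inconsistency between annotation and genome."""


class ConfigurationError(ValueError):
    """Invalid database-construction parameters."""


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def splice_offset(position: int, boundary: int) -> int:
    """Signed no-zero offset of a pre-mRNA position from a junction.

    ``boundary`` is the pre-mRNA coordinate of the last base on the 5' side
    of the junction (last exonic base for donors, last intronic base for
    acceptors).  Bases at or before the boundary get negative offsets,
    bases after it positive ones; there is no offset 0.
    """
    return position - boundary if position > boundary else position - boundary - 1


def offset_to_position(offset: int, boundary: int) -> int:
    """Inverse of :func:`splice_offset`."""
    if offset == 0:
        raise ValueError("splice offsets have no zero")
    return boundary + offset if offset > 0 else boundary + offset + 1


@dataclass(frozen=True)
class Junction:
    """A splice junction in one transcript.

    ``boundary`` is the pre-mRNA coordinate of the base at offset -1;
    ``genomic_boundary`` the corresponding genomic (chromosome) coordinate.
    """

    kind: str  # "donor" or "acceptor"
    transcript_id: str
    intron_index: int  # 0-based intron this junction belongs to
    boundary: int
    genomic_boundary: int


@dataclass
class TranscriptModel:
    """Exon/intron structure of one annotated transcript variant."""

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]  # genomic 1-based closed, transcript order

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: no exons")
        # transcript order: ascending start on +, descending on -
        self.exons = sorted(self.exons, reverse=(self.strand == "-"))
        starts = sorted(s for s, _ in self.exons)
        ends = sorted(e for _, e in self.exons)
        for (s1, e1), s2 in zip(zip(starts, ends), starts[1:]):
            if s2 <= e1:
                raise AnnotationError(f"{self.transcript_id}: overlapping exons")

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span (min start, max end) of the unspliced transcript."""
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))

    def __len__(self) -> int:
        s, e = self.span
        return e - s + 1

    def g2t(self, g: int) -> int:
        """Genomic coordinate -> pre-mRNA coordinate (transcript oriented)."""
        s, e = self.span
        if not s <= g <= e:
            raise ValueError(f"{self.transcript_id}: genomic {g} outside span {s}-{e}")
        return g - s + 1 if self.strand == "+" else e - g + 1

    def t2g(self, t: int) -> int:
        """Pre-mRNA coordinate -> genomic coordinate."""
        s, e = self.span
        if not 1 <= t <= len(self):
            raise ValueError(f"{self.transcript_id}: pre-mRNA position {t} outside 1-{len(self)}")
        return s + t - 1 if self.strand == "+" else e - t + 1

    def exons_t(self) -> list[tuple[int, int]]:
        """Exon intervals in pre-mRNA coordinates, 5'->3'."""
        out = []
        for s, e in self.exons:
            a, b = self.g2t(s), self.g2t(e)
            out.append((min(a, b), max(a, b)))
        return out

    def introns_t(self) -> list[tuple[int, int]]:
        ex = self.exons_t()
        return [(e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(ex, ex[1:])]

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Intron intervals in genomic coordinates (transcript order)."""
        return [
            (min(self.t2g(a), self.t2g(b)), max(self.t2g(a), self.t2g(b)))
            for a, b in self.introns_t()
        ]

    @property
    def donor_junctions(self) -> list[Junction]:
        ex = self.exons_t()
        return [
            Junction("donor", self.transcript_id, i, e1, self.t2g(e1))
            for i, (_, e1) in enumerate(ex[:-1])
        ]

    @property
    def acceptor_junctions(self) -> list[Junction]:
        ex = self.exons_t()
        return [
            Junction("acceptor", self.transcript_id, i, s2 - 1, self.t2g(s2 - 1))
            for i, (s2, _) in enumerate(ex[1:])
        ]


@dataclass
class DbRecord:
    """One searchable transcript-oriented sequence.

    ``t_start`` anchors the record on its transcript's pre-mRNA axis, so a
    1-based offset within the record maps back to pre-mRNA (and genomic)
    coordinates.  Window records additionally carry their junction.
    """

    record_id: str
    transcript_id: str
    category: str  # exon | intron | donor_window | acceptor_window
    sequence: str
    t_start: int
    junction: Junction | None = None
    index: int | None = None  # ordinal for exon/intron records

    def offset_to_t(self, offset: int) -> int:
        """1-based in-record offset -> pre-mRNA coordinate."""
        if not 1 <= offset <= len(self.sequence):
            raise ValueError(f"offset {offset} outside record {self.record_id}")
        return self.t_start + offset - 1

    def t_to_offset(self, t: int) -> int:
        return t - self.t_start + 1

    def offset_to_splice(self, offset: int) -> int:
        """In-window offset -> signed splice offset (window records only)."""
        if self.junction is None:
            raise ValueError(f"record {self.record_id} has no junction")
        return splice_offset(self.offset_to_t(offset), self.junction.boundary)


@dataclass
class SequenceDatabase:
    """Exon/intron/splice-site-window sequences for a set of transcripts."""

    records: list[DbRecord]
    models: dict[str, TranscriptModel]
    donor_flank: tuple[int, int]
    acceptor_flank: tuple[int, int]

    def by_category(self, category: str) -> list[DbRecord]:
        return [r for r in self.records if r.category == category]

    def model(self, transcript_id: str) -> TranscriptModel:
        return self.models[transcript_id]


def _iter_transcripts(db: gffutils.FeatureDB):
    seen = set()
    for ftype in ("mRNA", "transcript"):
        for t in db.features_of_type(ftype):
            if t.id in seen:
                continue
            seen.add(t.id)
            yield t


def _gene_id_of(db: gffutils.FeatureDB, t) -> str:
    if "gene_id" in t.attributes:
        return t.attributes["gene_id"][0]
    parents = list(db.parents(t, featuretype="gene"))
    if parents:
        return parents[0].id
    if "Parent" in t.attributes:
        return t.attributes["Parent"][0]
    return t.id


def load_annotation(
    gff_path: str,
    fasta_path: str,
    exclusion_patterns: tuple[str, ...] = DEFAULT_EXCLUDE_SEQIDS,
) -> list[TranscriptModel]:
    """Parse GFF3/GTF + genome FASTA into per-transcript models.

    Every annotated transcript variant becomes a distinct model (shared
    junctions are counted separately downstream).  Transcripts on excluded
    seqids (mitochondrial/chloroplast by default) are dropped.  Transcripts
    with zero exons are skipped with a warning; exons referencing missing
    contigs or lying outside contig bounds are hard errors.
    """
    db = gffutils.create_db(
        gff_path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    fasta = Fasta(fasta_path)
    excluded = set(exclusion_patterns)
    models: list[TranscriptModel] = []
    for t in sorted(_iter_transcripts(db), key=lambda f: f.id):
        if t.seqid in excluded:
            log.info("excluding transcript %s on seqid %s", t.id, t.seqid)
            continue
        exons = [(e.start, e.end) for e in db.children(t, featuretype="exon")]
        if not exons:
            log.warning("transcript %s has zero exons; skipped", t.id)
            continue
        if t.seqid not in fasta:
            raise AnnotationError(f"seqid {t.seqid!r} (transcript {t.id}) missing from FASTA")
        contig_len = len(fasta[t.seqid])
        for s, e in exons:
            if s < 1 or e > contig_len:
                raise AnnotationError(
                    f"exon {s}-{e} of transcript {t.id} outside contig {t.seqid} (1-{contig_len})"
                )
        models.append(
            TranscriptModel(
                transcript_id=t.id,
                gene_id=_gene_id_of(db, t),
                chromosome=t.seqid,
                strand=t.strand,
                exons=exons,
            )
        )
    return models


def _premrna(model: TranscriptModel, fasta: Fasta) -> str:
    s, e = model.span
    seq = str(fasta[model.chromosome][s - 1 : e]).upper()
    return _revcomp(seq) if model.strand == "-" else seq


def build_databases(
    models: list[TranscriptModel],
    fasta_path: str | Fasta,
    donor_flank: tuple[int, int] = (15, 15),
    acceptor_flank: tuple[int, int] = (15, 15),
) -> SequenceDatabase:
    """Extract exon, intron and splice-site-window records for searching.

    Donor windows span ``donor_flank[0]`` exonic + ``donor_flank[1]``
    intronic nt around each exon->intron junction (acceptor windows
    mirrored), truncated -- never padded -- at transcript ends.  Flanks
    below 12 nt would allow junction-crossing hits of the longest queries
    to be missed and are rejected.
    """
    for name, (a, b) in (("donor", donor_flank), ("acceptor", acceptor_flank)):
        if a < MIN_FLANK or b < MIN_FLANK:
            raise ConfigurationError(
                f"{name} flank {a}/{b} below minimum {MIN_FLANK}: junction-crossing hits could be missed"
            )
    fasta = fasta_path if isinstance(fasta_path, Fasta) else Fasta(str(fasta_path))
    records: list[DbRecord] = []
    model_map: dict[str, TranscriptModel] = {}
    for m in sorted(models, key=lambda m: m.transcript_id):
        model_map[m.transcript_id] = m
        pre = _premrna(m, fasta)
        L = len(pre)
        for i, (a, b) in enumerate(m.exons_t()):
            records.append(
                DbRecord(f"{m.transcript_id}:exon:{i + 1}", m.transcript_id, "exon",
                         pre[a - 1 : b], a, index=i)
            )
        for i, (a, b) in enumerate(m.introns_t()):
            records.append(
                DbRecord(f"{m.transcript_id}:intron:{i + 1}", m.transcript_id, "intron",
                         pre[a - 1 : b], a, index=i)
            )
        for j in m.donor_junctions:
            a = max(1, j.boundary - donor_flank[0] + 1)
            b = min(L, j.boundary + donor_flank[1])
            records.append(
                DbRecord(f"{m.transcript_id}:donor:{j.intron_index + 1}", m.transcript_id,
                         "donor_window", pre[a - 1 : b], a, junction=j)
            )
        for j in m.acceptor_junctions:
            a = max(1, j.boundary - acceptor_flank[0] + 1)
            b = min(L, j.boundary + acceptor_flank[1])
            records.append(
                DbRecord(f"{m.transcript_id}:acceptor:{j.intron_index + 1}", m.transcript_id,
                         "acceptor_window", pre[a - 1 : b], a, junction=j)
            )
    return SequenceDatabase(records, model_map, donor_flank, acceptor_flank)
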