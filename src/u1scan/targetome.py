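"""Merging, classification and summarisation of raw hits into a targetome.

Counting rules: hits at the same genomic position on *different* transcript
variants are distinct targets (they affect different RNA molecules); hits
at the same 5'-most position of the *same* transcript, produced by
different registers or found in different database records, are merged
into one target.  Each merged target is classified as exonic, intronic,
donor (5'-SS) or acceptor (3'-SS): splice-site categories require the
footprint to span the junction (cover both offsets -1 and +1).  A target's
reference position is always the 5'-most nucleotide of its footprint,
whether or not that base is canonically paired.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, replace

import numpy as np

from .annotation import SequenceDatabase, TranscriptModel, splice_offset
from .registers import BindingSequence, QueryCandidate, generate_queries, REGISTER_PRIORITY, _PRIORITY_RANK
from .search import DatabaseIndex, RawHit, search

log = logging.getLogger(__name__)

__all__ = [
    "TargetHit",
    "TargetomeSummary",
    "merge_hits",
    "classify_hits",
    "summarize",
    "positional_distribution",
    "position_frequency_matrix",
    "compute_psi",
    "select_candidate_offtarget_exons",
    "predict_targetome",
]

CATEGORIES = ("exonic", "intronic", "donor", "acceptor")


@dataclass(frozen=True)
class TargetHit:
    """A merged (and, after classification, categorised) target site."""

    transcript_id: str
    t5: int  # pre-mRNA coordinate of the 5'-most footprint base
    length: int
    sequence: str
    annealed_bases: int
    register: str
    category: str | None = None
    junction_kind: str | None = None  # nearest junction, when within range
    junction_offset: int | None = None

    @property
    def t3(self) -> int:
        return self.t5 + self.length - 1


def merge_hits(raw: list[RawHit]) -> list[TargetHit]:
    """Collapse raw hits by (transcript, 5'-most position).

    The merged target keeps the maximum annealed-base count over members
    and the register of highest attribution priority (most annealed bases
    first, then fewest edited bases: COM > BS1 > BS2 > BA1 > ALS > BA2 >
    ALA); footprint length and sequence follow the priority member.
    Cross-database duplicates (the same position found in an exon record
    and again in a window record) collapse as well.  Idempotent.
    """
    groups: dict[tuple[str, int], list[RawHit]] = defaultdict(list)
    for h in raw:
        groups[(h.transcript_id, h.t5)].append(h)
    merged: list[TargetHit] = []
    for (tid, t5), members in sorted(groups.items()):
        best_annealed = max(m.annealed_bases for m in members)
        rep = min(members, key=lambda m: (_PRIORITY_RANK[m.register], m.length, m.query))
        merged.append(
            TargetHit(
                transcript_id=tid,
                t5=t5,
                length=rep.length,
                sequence=rep.query,
                annealed_bases=best_annealed,
                register=rep.register,
            )
        )
    return merged


def _nearest_junction(model: TranscriptModel, t5: int) -> tuple[str, int] | None:
    best_key = None
    best = None
    for j in (*model.donor_junctions, *model.acceptor_junctions):
        off = splice_offset(t5, j.boundary)
        key = (abs(off), 0 if j.kind == "donor" else 1, off)
        if best_key is None or key < best_key:
            best_key, best = key, (j.kind, off)
    return best


def classify_hits(
    hits: list[TargetHit], models: dict[str, TranscriptModel] | list[TranscriptModel]
) -> list[TargetHit]:
    """Assign each merged hit its positional category.

    A footprint spanning an exon->intron boundary (covering offsets -1 and
    +1) is a donor target; spanning an intron->exon boundary, an acceptor
    target; otherwise it lies fully within an exon or an intron.  A
    footprint spanning both (micro-intron shorter than the footprint) is
    assigned donor and logged.  Footprints outside the transcript span
    indicate a database-construction bug and raise.
    """
    if isinstance(models, list):
        models = {m.transcript_id: m for m in models}
    out: list[TargetHit] = []
    for h in hits:
        m = models[h.transcript_id]
        if h.t5 < 1 or h.t3 > len(m):
            raise RuntimeError(
                f"footprint {h.t5}-{h.t3} outside transcript {h.transcript_id} (1-{len(m)})"
            )
        spans_donor = any(h.t5 <= j.boundary and h.t3 >= j.boundary + 1
                          for j in m.donor_junctions)
        spans_acceptor = any(h.t5 <= j.boundary and h.t3 >= j.boundary + 1
                             for j in m.acceptor_junctions)
        if spans_donor and spans_acceptor:
            log.info("hit %s:%d spans both a donor and an acceptor; assigned donor",
                     h.transcript_id, h.t5)
        if spans_donor:
            cat = "donor"
        elif spans_acceptor:
            cat = "acceptor"
        elif any(a <= h.t5 and h.t3 <= b for a, b in m.exons_t()):
            cat = "exonic"
        elif any(a <= h.t5 and h.t3 <= b for a, b in m.introns_t()):
            cat = "intronic"
        else:  # pragma: no cover - unreachable given span checks above
            raise RuntimeError(f"unclassifiable footprint {h.t5}-{h.t3} on {h.transcript_id}")
        nearest = _nearest_junction(m, h.t5)
        kind, off = nearest if nearest else (None, None)
        out.append(replace(h, category=cat, junction_kind=kind, junction_offset=off))
    return out


@dataclass
class TargetomeSummary:
    """Per-MAB target counts, broken down by category and register."""

    u1_id: str
    totals: dict[int, int]
    by_category: dict[int, dict[str, int]]
    by_register: dict[int, dict[str, int]]

    def check_partition(self) -> None:
        for m, total in self.totals.items():
            assert total == sum(self.by_category[m].values()), (
                f"category partition violated at MAB {m}"
            )


def summarize(hits: list[TargetHit], mab_levels: list[int], u1_id: str = "") -> TargetomeSummary:
    """Counts of targets with annealed_bases >= m for each MAB level m."""
    totals: dict[int, int] = {}
    by_cat: dict[int, dict[str, int]] = {}
    by_reg: dict[int, dict[str, int]] = {}
    for m in sorted(mab_levels, reverse=True):
        kept = [h for h in hits if h.annealed_bases >= m]
        totals[m] = len(kept)
        by_cat[m] = {c: sum(1 for h in kept if h.category == c) for c in CATEGORIES}
        by_reg[m] = {r: sum(1 for h in kept if h.register == r) for r in REGISTER_PRIORITY}
    s = TargetomeSummary(u1_id, totals, by_cat, by_reg)
    s.check_partition()
    return s


def positional_distribution(
    hits: list[TargetHit],
    models: dict[str, TranscriptModel] | list[TranscriptModel],
    junction_type: str,
    offset_range: tuple[int, int] = (-15, 10),
) -> dict[int, int]:
    """Histogram of hit 5'-most positions relative to junctions of a type.

    Counts every merged hit (any category) whose 5'-most base lies at each
    no-zero offset in ``offset_range`` from any junction of the requested
    type; fully-intronic hits downstream of a donor are counted when in
    range.
    """
    lo, hi = offset_range
    if lo == 0 or hi == 0 or lo > hi:
        raise ValueError(f"invalid offset range {offset_range} (offsets have no zero)")
    if junction_type not in ("donor", "acceptor"):
        raise ValueError(f"junction_type must be donor or acceptor, got {junction_type!r}")
    if isinstance(models, list):
        models = {m.transcript_id: m for m in models}
    offsets = [o for o in range(lo, hi + 1) if o != 0]
    counts = {o: 0 for o in offsets}
    by_tid: dict[str, list[TargetHit]] = defaultdict(list)
    for h in hits:
        by_tid[h.transcript_id].append(h)
    for tid, model in models.items():
        junctions = model.donor_junctions if junction_type == "donor" else model.acceptor_junctions
        for j in junctions:
            for h in by_tid.get(tid, ()):
                off = splice_offset(h.t5, j.boundary)
                if lo <= off <= hi:
                    counts[off] += 1
    return counts


def position_frequency_matrix(hits: list[TargetHit]) -> tuple[np.ndarray, str]:
    """Column-wise A/C/G/T counts over aligned footprint sequences.

    Footprints are aligned at their 5'-most base; columns are truncated to
    the shortest contributing footprint so every column sums to the number
    of sites.  Returns (4 x L count matrix, row order "ACGT").
    """
    if not hits:
        raise ValueError("position frequency matrix requires at least one site")
    L = min(h.length for h in hits)
    mat = np.zeros((4, L), dtype=int)
    order = "ACGT"
    for h in hits:
        for col, base in enumerate(h.sequence[:L]):
            mat[order.index(base), col] += 1
    return mat, order


def compute_psi(
    tpm_table: dict[str, float],
    exon_membership: dict[str, set[str]],
    gene_map: dict[str, str],
    min_tpm: float = 0.5,
) -> dict[str, float]:
    """Percent-spliced-in per exon from transcript-level TPM.

    PSI(exon) = sum of TPM over transcripts carrying the exon / sum of TPM
    over all transcripts of the same gene, after dropping transcripts with
    TPM below ``min_tpm``.  Genes with zero surviving TPM yield NaN.
    """
    surviving = {t: v for t, v in tpm_table.items() if v >= min_tpm}
    gene_tpm: dict[str, float] = defaultdict(float)
    for t, v in surviving.items():
        gene_tpm[gene_map[t]] += v
    psi: dict[str, float] = {}
    for exon, transcripts in exon_membership.items():
        genes = {gene_map[t] for t in transcripts if t in gene_map}
        if len(genes) != 1:
            raise ValueError(f"exon {exon!r} maps to transcripts of {len(genes)} genes")
        gene = genes.pop()
        denom = gene_tpm.get(gene, 0.0)
        if denom == 0.0:
            psi[exon] = math.nan
            continue
        num = sum(surviving.get(t, 0.0) for t in transcripts)
        value = num / denom
        assert 0.0 <= value <= 1.0 + 1e-12
        psi[exon] = min(value, 1.0)
    return psi


def select_candidate_offtarget_exons(
    hits: list[TargetHit],
    psi_tables: list[dict[str, float]],
    exon_donors: dict[str, list[tuple[str, int]]],
    models: dict[str, TranscriptModel] | list[TranscriptModel],
    psi_threshold: float = 0.5,
    window: tuple[int, int] = (-10, 25),
) -> list[str]:
    """Exons with a donor-proximal hit and average PSI below threshold.

    ``exon_donors`` maps an exon identifier to the (transcript_id,
    exon_index) placements whose 3'-end donor junction should be checked;
    a hit counts when its 5'-most base lies within ``window`` of that
    junction.  PSI is averaged arithmetically over tables where the exon
    has a defined value (missing values dropped, not zero-filled).
    """
    if isinstance(models, list):
        models = {m.transcript_id: m for m in models}
    lo, hi = window
    by_tid: dict[str, list[TargetHit]] = defaultdict(list)
    for h in hits:
        by_tid[h.transcript_id].append(h)
    selected: list[str] = []
    for exon in sorted(exon_donors):
        values = [t[exon] for t in psi_tables if exon in t and not math.isnan(t[exon])]
        if not values:
            continue
        avg = sum(values) / len(values)
        if avg >= psi_threshold:
            continue
        has_hit = False
        for tid, exon_index in exon_donors[exon]:
            model = models.get(tid)
            if model is None:
                continue
            donors = [j for j in model.donor_junctions if j.intron_index == exon_index]
            for j in donors:
                for h in by_tid.get(tid, ()):
                    if lo <= splice_offset(h.t5, j.boundary) <= hi:
                        has_hit = True
        if has_hit:
            selected.append(exon)
    return selected


def predict_targetome(
    binding: BindingSequence,
    db: SequenceDatabase,
    mab: int,
    registers: tuple[str, ...] = REGISTER_PRIORITY,
    index: DatabaseIndex | None = None,
    queries: list[QueryCandidate] | None = None,
) -> list[TargetHit]:
    """End-to-end prediction: enumerate queries, search, merge, classify."""
    if queries is None:
        queries = generate_queries(binding, mab, registers)
    if index is None:
        index = DatabaseIndex(db)
    raw = search(queries, index)
    merged = merge_hits(raw)
    return classify_hits(merged, db.models)
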