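"""Exact, full-length, plus-strand search of query strings in a database.

All base-pairing tolerance lives in query generation, so the search step
reduces to exact substring matching: a BLASTn run with ``word_size`` equal
to the full query length can only seed (and therefore report) perfect
full-length matches.  The built-in engine scans each record once per query
length class with a hash-set membership test; an optional parity mode runs
the external BLAST+ binaries with the equivalent flags for bit-level
comparison.

Records are transcript-oriented sense sequences, so only the plus strand
is ever searched.  ``N`` bases match nothing.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

from .annotation import DbRecord, SequenceDatabase
from .registers import QueryCandidate, ValidationError

log = logging.getLogger(__name__)

__all__ = ["RawHit", "DatabaseIndex", "search", "blast_parity_run", "BlastUnavailable"]


@dataclass(frozen=True)
class RawHit:
    """One exact occurrence of a query in a database record."""

    query: str
    record_id: str
    transcript_id: str
    category: str
    offset: int  # 1-based start within the record
    t5: int  # transcript-oriented pre-mRNA coordinate of the 5'-most base
    length: int
    annealed_bases: int
    register: str

    @property
    def t3(self) -> int:
        return self.t5 + self.length - 1


class DatabaseIndex:
    """Exact-lookup index over all fixed-length substrings of a database.

    Length classes are indexed lazily: positions for a query length are
    collected on first use.  Iteration order is deterministic (record_id,
    offset ascending).
    """

    def __init__(self, db: SequenceDatabase):
        self.db = db
        self.records: list[DbRecord] = sorted(db.records, key=lambda r: r.record_id)
        self._by_length: dict[int, dict[str, list[tuple[int, int]]]] = {}

    def _index_length(self, k: int) -> dict[str, list[tuple[int, int]]]:
        idx = self._by_length.get(k)
        if idx is None:
            idx = {}
            for ri, rec in enumerate(self.records):
                seq = rec.sequence
                for off in range(len(seq) - k + 1):
                    word = seq[off : off + k]
                    if "N" in word:
                        continue
                    idx.setdefault(word, []).append((ri, off + 1))
            self._by_length[k] = idx
        return idx

    def lookup(self, word: str) -> list[tuple[DbRecord, int]]:
        """All (record, 1-based offset) occurrences of an exact word."""
        idx = self._index_length(len(word))
        return [(self.records[ri], off) for ri, off in idx.get(word, [])]

    def positions_indexed(self, k: int) -> int:
        """Number of indexed substring positions of length k."""
        return sum(len(v) for v in self._index_length(k).values())


def search(queries: list[QueryCandidate], index: DatabaseIndex) -> list[RawHit]:
    """Every exact occurrence of every query, plus strand only.

    Scans each record once per query length class, testing window
    membership in the query set; overlapping occurrences are all reported.
    """
    by_len: dict[int, dict[str, QueryCandidate]] = {}
    for q in queries:
        if "N" in q.sequence:
            raise ValidationError(f"query contains N: {q.sequence}")
        by_len.setdefault(len(q.sequence), {})[q.sequence] = q
    hits: list[RawHit] = []
    for rec in index.records:
        seq = rec.sequence
        for k, qmap in sorted(by_len.items()):
            for off in range(len(seq) - k + 1):
                q = qmap.get(seq[off : off + k])
                if q is None:
                    continue
                hits.append(
                    RawHit(
                        query=q.sequence,
                        record_id=rec.record_id,
                        transcript_id=rec.transcript_id,
                        category=rec.category,
                        offset=off + 1,
                        t5=rec.offset_to_t(off + 1),
                        length=k,
                        annealed_bases=q.annealed_bases,
                        register=q.register,
                    )
                )
    hits.sort(key=lambda h: (h.record_id, h.offset, h.length, h.query))
    return hits


class BlastUnavailable(RuntimeError):
    """External BLAST+ binaries are not on PATH; parity mode disabled."""


def blast_parity_run(
    queries: list[QueryCandidate],
    db: SequenceDatabase,
    blastn: str = "blastn",
    makeblastdb: str = "makeblastdb",
) -> list[RawHit]:
    """Run external BLAST+ with the short-query exact-match settings.

    Uses ``-task blastn-short``, ``-word_size`` equal to each query length,
    ``-strand plus``, ``-evalue 1000000000`` and ``-max_target_seqs
    1000000000``, then keeps full-length 100%-identity hits.  Agrees with
    the built-in engine on those hits; never required by the pipeline.
    """
    if shutil.which(blastn) is None or shutil.which(makeblastdb) is None:
        raise BlastUnavailable(
            "BLAST+ binaries not found; parity mode unavailable, use the built-in engine"
        )
    if not queries:
        return []
    recmap = {r.record_id: r for r in db.records}
    hits: list[RawHit] = []
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        dbfa = tmp / "db.fa"
        with open(dbfa, "w") as fh:
            for r in sorted(db.records, key=lambda r: r.record_id):
                fh.write(f">{r.record_id}\n{r.sequence}\n")
        subprocess.run(
            [makeblastdb, "-in", str(dbfa), "-dbtype", "nucl"],
            check=True, capture_output=True,
        )
        for k in sorted({len(q.sequence) for q in queries}):
            qfa = tmp / f"q{k}.fa"
            qmap = {}
            with open(qfa, "w") as fh:
                for i, q in enumerate(sorted((q for q in queries if len(q.sequence) == k),
                                             key=lambda q: q.sequence)):
                    qid = f"q{k}_{i}"
                    qmap[qid] = q
                    fh.write(f">{qid}\n{q.sequence}\n")
            out = subprocess.run(
                [
                    "blastn" if blastn == "blastn" else blastn,
                    "-task", "blastn-short",
                    "-word_size", str(k),
                    "-strand", "plus",
                    "-evalue", "1000000000",
                    "-max_target_seqs", "1000000000",
                    "-query", str(qfa),
                    "-db", str(dbfa),
                    "-outfmt", "6 qseqid sseqid pident length sstart send",
                ],
                check=True, capture_output=True, text=True,
            )
            for line in out.stdout.splitlines():
                qid, sid, pident, length, sstart, send = line.split("\t")
                if int(length) != k or float(pident) < 100.0 or int(send) < int(sstart):
                    continue
                q = qmap[qid]
                rec = recmap[sid]
                off = int(sstart)
                hits.append(
                    RawHit(
                        query=q.sequence,
                        record_id=rec.record_id,
                        transcript_id=rec.transcript_id,
                        category=rec.category,
                        offset=off,
                        t5=rec.offset_to_t(off),
                        length=k,
                        annealed_bases=q.annealed_bases,
                        register=q.register,
                    )
                )
    hits.sort(key=lambda h: (h.record_id, h.offset, h.length, h.query))
    return hits
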