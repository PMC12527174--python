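"""Tabular writers and provenance stamping for pipeline outputs.

Every text output begins with comment headers recording the tool version
and a hash of the run configuration, so re-runs on identical inputs are
byte-identical and auditable.  Targets are written both as BED6 and TSV;
query sets as FASTA with provenance-encoding headers compatible with the
external-BLAST parity mode.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from . import __version__
from .annotation import SequenceDatabase, TranscriptModel
from .registers import QueryCandidate
from .targetome import TargetHit, TargetomeSummary


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(config: dict | None = None, comment: str = "#") -> list[str]:
    lines = [f"{comment} u1scan v{__version__}"]
    if config is not None:
        lines.append(f"{comment} config_hash={config_hash(config)}")
    return lines


def write_query_fasta(queries: list[QueryCandidate], path: str | Path) -> None:
    """Query FASTA; headers encode register, edit site, mismatches, annealed."""
    with open(path, "w") as fh:
        for i, q in enumerate(sorted(queries, key=lambda q: q.sequence)):
            p = q.best_provenance()
            mm = ",".join(map(str, p.mismatches)) or "-"
            fh.write(
                f">q{i}|{p.register}|site={p.edit_site if p.edit_site is not None else '-'}"
                f"|mm={mm}|annealed={q.annealed_bases}\n{q.sequence}\n"
            )


def write_database_manifest(db: SequenceDatabase, path: str | Path, config: dict | None = None) -> None:
    with open(path, "w") as fh:
        for line in provenance_header(config):
            fh.write(line + "\n")
        fh.write("record_id\tcategory\ttranscript_id\tchrom\tstart\tend\tstrand\tlength\n")
        for r in sorted(db.records, key=lambda r: r.record_id):
            m = db.models[r.transcript_id]
            g1 = m.t2g(r.t_start)
            g2 = m.t2g(r.t_start + len(r.sequence) - 1)
            fh.write(
                f"{r.record_id}\t{r.category}\t{r.transcript_id}\t{m.chromosome}"
                f"\t{min(g1, g2)}\t{max(g1, g2)}\t{m.strand}\t{len(r.sequence)}\n"
            )


def write_database_fasta(db: SequenceDatabase, category: str, path: str | Path) -> None:
    """FASTA dump of one database category for external BLASTn parity runs."""
    with open(path, "w") as fh:
        for r in sorted(db.by_category(category), key=lambda r: r.record_id):
            fh.write(f">{r.record_id}\n{r.sequence}\n")


def write_targets_tsv(
    hits: list[TargetHit],
    models: dict[str, TranscriptModel],
    path: str | Path,
    config: dict | None = None,
) -> None:
    with open(path, "w") as fh:
        for line in provenance_header(config):
            fh.write(line + "\n")
        fh.write(
            "transcript_id\tchrom\tstart\tend\tstrand\tt5\tcategory\tregister"
            "\tannealed_bases\tjunction_kind\tjunction_offset\tsequence\n"
        )
        for h in sorted(hits, key=lambda h: (h.transcript_id, h.t5)):
            m = models[h.transcript_id]
            g1, g2 = m.t2g(h.t5), m.t2g(h.t3)
            fh.write(
                f"{h.transcript_id}\t{m.chromosome}\t{min(g1, g2)}\t{max(g1, g2)}\t{m.strand}"
                f"\t{h.t5}\t{h.category}\t{h.register}\t{h.annealed_bases}"
                f"\t{h.junction_kind or ''}\t{h.junction_offset if h.junction_offset is not None else ''}"
                f"\t{h.sequence}\n"
            )


def write_targets_bed(
    hits: list[TargetHit], models: dict[str, TranscriptModel], path: str | Path
) -> None:
    """BED6: name = transcript|register|annealed, score = annealed bases."""
    with open(path, "w") as fh:
        for h in sorted(hits, key=lambda h: (h.transcript_id, h.t5)):
            m = models[h.transcript_id]
            g1, g2 = m.t2g(h.t5), m.t2g(h.t3)
            fh.write(
                f"{m.chromosome}\t{min(g1, g2) - 1}\t{max(g1, g2)}"
                f"\t{h.transcript_id}|{h.register}|{h.annealed_bases}"
                f"\t{h.annealed_bases}\t{m.strand}\n"
            )


def write_summary_json(summary: TargetomeSummary, path: str | Path, config: dict | None = None) -> None:
    doc = {
        "tool": f"u1scan v{__version__}",
        "u1_id": summary.u1_id,
        "totals": summary.totals,
        "by_category": summary.by_category,
        "by_register": summary.by_register,
    }
    if config is not None:
        doc["config_hash"] = config_hash(config)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def write_histogram_tsv(counts: dict[int, int], path: str | Path, config: dict | None = None) -> None:
    with open(path, "w") as fh:
        for line in provenance_header(config):
            fh.write(line + "\n")
        fh.write("offset\tcount\n")
        for off in sorted(counts):
            fh.write(f"{off}\t{counts[off]}\n")


def write_pfm_tsv(matrix, order: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("base\t" + "\t".join(str(i + 1) for i in range(matrix.shape[1])) + "\n")
        for b, row in zip(order, matrix):
            fh.write(b + "\t" + "\t".join(map(str, row)) + "\n")
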