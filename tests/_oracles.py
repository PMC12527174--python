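"""Independent brute-force oracles used by the test suite.

These re-derive expected results from first principles -- duplex geometry
arithmetic and naive window scanning -- without touching the package's
query-enumeration or search code paths.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "U": "A", "T": "A"}


def revcomp_rna_to_dna(binding: str) -> str:
    """Reverse complement of an RNA binding sequence, in DNA letters."""
    return "".join(_COMPLEMENT[b] for b in reversed(binding.upper()))


def geometries(n: int):
    """All register geometries for an n-nt base target.

    Yields (label, qlen, q_idx, t_idx, allowed_mismatch_mask, paired) where
    q_idx/t_idx are 0-based paired positions in query and base target, and
    allowed_mismatch_mask marks query positions where a mismatch may sit
    (paired, and >= 1 nt away from any bulge/loop).
    """
    out = []

    def add(label, qlen, pairs, disallowed):
        q_idx = np.array([q for q, _ in pairs])
        t_idx = np.array([t for _, t in pairs])
        allowed = np.ones(qlen, dtype=bool)
        for d in disallowed:
            if 0 <= d < qlen:
                allowed[d] = False
        out.append((label, qlen, q_idx, t_idx, allowed, len(pairs)))

    # COM: 1:1 pairing
    add("COM", n, [(i, i) for i in range(n)], [])
    # BS1/BS2: insert 1 or 2 nt between target bases j and j+1 (1-based j)
    for w, label in ((1, "BS1"), (2, "BS2")):
        for j in range(1, n):
            pairs = [(i, i) for i in range(j)] + [(i + w, i) for i in range(j, n)]
            disallowed = list(range(j, j + w)) + [j - 1, j + w]
            add(label, n + w, pairs, disallowed)
    # BA1/BA2: delete target base(s) d.. (1-based d, internal)
    for w, label in ((1, "BA1"), (2, "BA2")):
        for d in range(2, n - w + 1):
            pairs = [(i, i) for i in range(d - 1)] + [(i - w, i) for i in range(d + w - 1, n)]
            disallowed = [d - 2, d - 1]
            add(label, n - w, pairs, disallowed)
    # ALS: delete 1, insert 2 at the site
    for d in range(2, n):
        pairs = [(i, i) for i in range(d - 1)] + [(i + 1, i) for i in range(d, n)]
        disallowed = [d - 1, d, d - 2, d + 1]
        add("ALS", n + 1, pairs, disallowed)
    # ALA: delete 2, insert 1
    for d in range(2, n - 1):
        pairs = [(i, i) for i in range(d - 1)] + [(i - 1, i) for i in range(d + 1, n)]
        disallowed = [d - 2, d - 1, d]
        add("ALA", n - 1, pairs, disallowed)
    return out


def best_annealing_per_window(record_seq: str, binding: str) -> dict[tuple[int, int], int]:
    """Best register-constrained annealed-base count for every window.

    Returns {(1-based offset, window length): best annealed} over all
    windows of lengths n-2..n+2 and all register geometries; windows
    containing N are skipped, as are geometry derivations that would need
    a mismatch adjacent to a bulge/loop.
    """
    base = revcomp_rna_to_dna(binding)
    n = len(base)
    enc = np.frombuffer(record_seq.encode(), dtype=np.uint8)
    base_enc = np.frombuffer(base.encode(), dtype=np.uint8)
    has_n = enc == ord("N")
    best: dict[tuple[int, int], int] = {}
    geoms = geometries(n)
    for qlen in range(n - 2, n + 3):
        if len(enc) < qlen:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(enc, qlen)
        n_ok = ~np.lib.stride_tricks.sliding_window_view(has_n, qlen).any(axis=1)
        score = np.full(windows.shape[0], -1, dtype=int)
        for label, gl, q_idx, t_idx, allowed, paired in geoms:
            if gl != qlen:
                continue
            mism = windows[:, q_idx] != base_enc[t_idx]
            bad = (mism & ~allowed[q_idx]).any(axis=1)
            annealed = paired - mism.sum(axis=1)
            annealed[bad] = -1
            score = np.maximum(score, annealed)
        score[~n_ok] = -1
        for off in np.nonzero(score >= 0)[0]:
            best[(int(off) + 1, qlen)] = int(score[off])
    return best


def naive_substring_scan(record_seq: str, queries: list[str]) -> list[tuple[str, int]]:
    """All (query, 1-based offset) exact occurrences, overlapping included."""
    hits = []
    for q in queries:
        start = 0
        while True:
            i = record_seq.find(q, start)
            if i < 0:
                break
            if "N" not in record_seq[i : i + len(q)]:
                hits.append((q, i + 1))
            start = i + 1
    return sorted(hits)
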