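"""Enumeration of U1:target annealing registers and mismatch expansion.

The 5'-terminal 11 nt of U1 snRNA (the *binding sequence*) anneal
antiparallel to donor splice sites.  Besides the perfectly complementary
duplex (register ``COM``), the endogenous U1 tolerates single- and
double-nucleotide bulges on the target strand (``BS1``/``BS2``), bulges on
the U1 strand (``BA1``/``BA2``), asymmetric loops with the larger loop on
either strand (``ALS``/``ALA``), and Watson-Crick mismatches at positions
at least one nucleotide away from any bulge or loop.  G:U wobble pairs are
counted as mismatches by default.

This module turns a binding sequence into the complete, deduplicated set
of DNA query strings realisable under those geometries, each annotated
with its provenance and the number of annealed (strict Watson-Crick)
base pairs.  Selectivity is controlled by the MAB parameter: the minimum
number of annealed bases a query must retain.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

from Bio.Seq import Seq

__all__ = [
    "BindingSequence",
    "Register",
    "REGISTERS",
    "REGISTER_PRIORITY",
    "QueryCandidate",
    "Provenance",
    "ValidationError",
    "derive_base_target",
    "enumerate_register_variants",
    "expand_mismatches",
    "generate_queries",
    "verify_annealing",
]

DNA_BASES = "ACGT"
_RNA_ALPHABET = frozenset("ACGU")

MISMATCH_FLOOR_DEFAULT = 6


class ValidationError(ValueError):
    """Raised on malformed binding sequences, queries or register requests."""


@dataclass(frozen=True)
class BindingSequence:
    """A U1 binding sequence: RNA, 5'->3', at least 8 nt (11 for natural U1s)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        if set(seq) - _RNA_ALPHABET:
            bad = sorted(set(seq) - _RNA_ALPHABET)
            raise ValidationError(f"binding sequence {self.id!r}: non-RNA characters {bad}")
        if len(seq) < 8:
            raise ValidationError(
                f"binding sequence {self.id!r}: length {len(seq)} < 8 not supported"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


#: The human endogenous U1 (RNU1-1) binding sequence.
RNU1_1 = BindingSequence("RNU1-1", "AUACUUACCUG")


@dataclass(frozen=True)
class Register:
    """One annealing-register geometry.

    ``target_length_delta`` is the change in target-string length relative
    to the binding-sequence length n; ``annealed_delta`` the loss of paired
    bases relative to n (U1-strand bulges leave U1 bases unpaired).
    """

    label: str
    target_length_delta: int
    annealed_delta: int

    def base_annealed(self, n: int) -> int:
        return n + self.annealed_delta


REGISTERS: dict[str, Register] = {
    "COM": Register("COM", 0, 0),
    "BS1": Register("BS1", +1, 0),
    "BS2": Register("BS2", +2, 0),
    "BA1": Register("BA1", -1, -1),
    "BA2": Register("BA2", -2, -2),
    "ALS": Register("ALS", +1, -1),
    "ALA": Register("ALA", -1, -2),
}

#: Reporting priority when hits from several registers merge:
#: most annealed bases first, then fewest edited bases.
REGISTER_PRIORITY = ("COM", "BS1", "BS2", "BA1", "ALS", "BA2", "ALA")
_PRIORITY_RANK = {label: i for i, label in enumerate(REGISTER_PRIORITY)}


@dataclass(frozen=True)
class Provenance:
    """One derivation of a query string.

    ``edit_site`` is the insertion junction (between base-target positions
    ``edit_site`` and ``edit_site+1``) for BS1/BS2, or the first deleted
    base-target position for BA1/BA2/ALS/ALA; ``None`` for COM.
    ``mismatches`` are 1-based positions *in the query string*.
    """

    register: str
    edit_site: int | None
    mismatches: tuple[int, ...] = ()

    def sort_key(self) -> tuple:
        return (_PRIORITY_RANK[self.register], len(self.mismatches), self.edit_site or 0)


@dataclass
class QueryCandidate:
    """A deduplicated target query string with all known derivations."""

    sequence: str
    provenance: tuple[Provenance, ...]
    annealed_bases: int

    def best_provenance(self) -> Provenance:
        return min(self.provenance, key=Provenance.sort_key)

    @property
    def register(self) -> str:
        """Reporting register under the attribution priority."""
        return self.best_provenance().register


def derive_base_target(b: BindingSequence) -> str:
    """Reverse complement of the binding sequence in DNA alphabet.

    The target strand anneals antiparallel, so the perfectly complementary
    target read 5'->3' is the reverse complement (U -> T for searching
    DNA-encoded transcript databases).
    """
    return str(Seq(b.sequence).back_transcribe().reverse_complement())


def _geometry(register: str, edit_site: int | None, n: int) -> tuple[list[tuple[int, int]], tuple[int, ...], frozenset[int]]:
    """Pairing geometry of a register applied to an n-nt base target.

    Returns ``(pairs, loop_positions, disallowed)`` where ``pairs`` is a
    list of (query_pos, base_target_pos) 1-based pairings, ``loop_positions``
    the inserted (unpaired) query positions, and ``disallowed`` the query
    positions where mismatches may not be introduced (loops plus positions
    within 1 nt of an edit site).
    """
    if register == "COM":
        pairs = [(i, i) for i in range(1, n + 1)]
        return pairs, (), frozenset()
    if register in ("BS1", "BS2"):
        j = edit_site  # insertion between target positions j and j+1
        w = 1 if register == "BS1" else 2
        loops = tuple(range(j + 1, j + 1 + w))
        pairs = [(i, i) for i in range(1, j + 1)]
        pairs += [(i + w, i) for i in range(j + 1, n + 1)]
        disallowed = frozenset(loops) | {j, j + w + 1}
        return pairs, loops, disallowed
    if register in ("BA1", "BA2"):
        d = edit_site  # first deleted base-target position
        w = 1 if register == "BA1" else 2
        pairs = [(i, i) for i in range(1, d)]
        pairs += [(i - w, i) for i in range(d + w, n + 1)]
        # deletion junction lies between query positions d-1 and d
        disallowed = frozenset({d - 1, d})
        return pairs, (), disallowed
    if register == "ALS":
        d = edit_site  # delete target base d, insert 2 nt at the site
        loops = (d, d + 1)
        pairs = [(i, i) for i in range(1, d)]
        pairs += [(i + 1, i) for i in range(d + 1, n + 1)]
        disallowed = frozenset(loops) | {d - 1, d + 2}
        return pairs, loops, disallowed
    if register == "ALA":
        d = edit_site  # delete target bases d,d+1, insert 1 nt
        loops = (d,)
        pairs = [(i, i) for i in range(1, d)]
        pairs += [(i - 1, i) for i in range(d + 2, n + 1)]
        disallowed = frozenset(loops) | {d - 1, d + 1}
        return pairs, loops, disallowed
    raise ValidationError(f"unknown register {register!r}")


def _edit_sites(register: str, n: int) -> list[int | None]:
    """All internal edit sites for a register (never the first/last position)."""
    if register == "COM":
        return [None]
    if register in ("BS1", "BS2"):
        return list(range(1, n))  # junctions between base i and i+1
    if register in ("BA1", "ALS"):
        return list(range(2, n))  # delete single internal base
    if register in ("BA2", "ALA"):
        return list(range(2, n - 1))  # delete internal adjacent pair
    raise ValidationError(f"unknown register {register!r}")


def _apply_register(base: str, register: str, edit_site: int | None, insert: str = "") -> str:
    """Build the register-transformed string from the base target."""
    if register == "COM":
        return base
    j = edit_site
    if register == "BS1" or register == "BS2":
        return base[:j] + insert + base[j:]
    if register == "BA1":
        return base[: j - 1] + base[j:]
    if register == "BA2":
        return base[: j - 1] + base[j + 1 :]
    if register == "ALS":
        return base[: j - 1] + insert + base[j:]
    if register == "ALA":
        return base[: j - 1] + insert + base[j + 1 :]
    raise ValidationError(f"unknown register {register!r}")


def enumerate_register_variants(
    base_target: str,
    registers: tuple[str, ...] | list[str] = REGISTER_PRIORITY,
) -> list[QueryCandidate]:
    """All zero-mismatch query strings of the requested registers.

    Insertions (BS1/BS2/ALS) take every nucleotide combination; deletions
    remove every internal base or pair.  Identical strings arising from
    different edits are merged into one candidate with multi-entry
    provenance; the annealed-base count of a merged candidate is the
    maximum over its derivations.
    """
    if not registers:
        raise ValidationError("empty register subset")
    unknown = set(registers) - set(REGISTERS)
    if unknown:
        raise ValidationError(f"unknown registers: {sorted(unknown)}")
    n = len(base_target)
    if n < 8:
        raise ValidationError(f"base target length {n} < 8")

    by_string: dict[str, tuple[list[Provenance], int]] = {}

    def emit(seq: str, prov: Provenance, annealed: int) -> None:
        if seq in by_string:
            provs, best = by_string[seq]
            provs.append(prov)
            by_string[seq] = (provs, max(best, annealed))
        else:
            by_string[seq] = ([prov], annealed)

    for label in REGISTER_PRIORITY:  # deterministic order
        if label not in registers:
            continue
        reg = REGISTERS[label]
        annealed = reg.base_annealed(n)
        insert_len = {"COM": 0, "BS1": 1, "BS2": 2, "BA1": 0, "BA2": 0, "ALS": 2, "ALA": 1}[label]
        for site in _edit_sites(label, n):
            if insert_len:
                for combo in itertools.product(DNA_BASES, repeat=insert_len):
                    seq = _apply_register(base_target, label, site, "".join(combo))
                    emit(seq, Provenance(label, site), annealed)
            else:
                seq = _apply_register(base_target, label, site)
                emit(seq, Provenance(label, site), annealed)

    return [
        QueryCandidate(seq, tuple(provs), best)
        for seq, (provs, best) in by_string.items()
    ]


def expand_mismatches(
    candidates: list[QueryCandidate],
    mab: int,
    *,
    mismatch_floor: int = MISMATCH_FLOOR_DEFAULT,
) -> list[QueryCandidate]:
    """Add every mismatch combination keeping at least ``mab`` annealed bases.

    Mismatches are substitutions at paired query positions, excluding
    inserted loop bases and positions within 1 nt of any edit site (the
    bulge/loop structure must be preserved).  Terminal duplex positions are
    allowed.  Output is deduplicated by string; the annealed-base count of
    a string is the maximum over all of its derivations.
    """
    if not candidates:
        return []
    n = max(len(c.sequence) - REGISTERS[p.register].target_length_delta
            for c in candidates for p in c.provenance)
    if mab > n:
        raise ValidationError(f"MAB {mab} exceeds binding-sequence length {n}")
    if mab <= 0:
        raise ValidationError("MAB must be positive")
    if mab < mismatch_floor:
        warnings.warn(
            f"MAB {mab} below floor {mismatch_floor}: query set grows combinatorially",
            stacklevel=2,
        )

    by_string: dict[str, tuple[list[Provenance], int]] = {}
    for cand in candidates:
        for prov in cand.provenance:
            provs, best = by_string.setdefault(cand.sequence, ([], 0))
            provs.append(prov)
            by_string[cand.sequence] = (provs, max(best, cand.annealed_bases))

    for cand in candidates:
        for prov in cand.provenance:
            reg = REGISTERS[prov.register]
            a = reg.base_annealed(n)
            max_k = a - mab
            if max_k <= 0:
                continue
            _, _, disallowed = _geometry(prov.register, prov.edit_site, n)
            allowed = [p for p in range(1, len(cand.sequence) + 1) if p not in disallowed]
            seq = cand.sequence
            for k in range(1, min(max_k, len(allowed)) + 1):
                annealed = a - k
                for positions in itertools.combinations(allowed, k):
                    originals = [seq[p - 1] for p in positions]
                    for repl in itertools.product(DNA_BASES, repeat=k):
                        if any(r == o for r, o in zip(repl, originals)):
                            continue
                        chars = list(seq)
                        for p, r in zip(positions, repl):
                            chars[p - 1] = r
                        new = "".join(chars)
                        new_prov = Provenance(prov.register, prov.edit_site, positions)
                        if new in by_string:
                            provs, best = by_string[new]
                            provs.append(new_prov)
                            by_string[new] = (provs, max(best, annealed))
                        else:
                            by_string[new] = ([new_prov], annealed)

    out = [
        QueryCandidate(s, tuple(pr), ann)
        for s, (pr, ann) in by_string.items()
        if ann >= mab
    ]
    return out


def generate_queries(
    b: BindingSequence,
    mab: int,
    registers: tuple[str, ...] | list[str] = REGISTER_PRIORITY,
    *,
    mismatch_floor: int = MISMATCH_FLOOR_DEFAULT,
) -> list[QueryCandidate]:
    """Binding sequence -> full deduplicated query set at the given MAB."""
    base = derive_base_target(b)
    variants = enumerate_register_variants(base, registers)
    expanded = expand_mismatches(variants, mab, mismatch_floor=mismatch_floor)
    expanded.sort(key=lambda c: c.sequence)
    return expanded


def verify_annealing(
    query: str,
    b: BindingSequence,
    claimed: tuple[str, int | None, tuple[int, ...]],
) -> int:
    """Independently recount annealed bases for a claimed derivation.

    Reconstructs the duplex pairing implied by the claimed register
    geometry and counts strict Watson-Crick pairs (G:T/G:U count as
    unpaired).  Raises if the query length is inconsistent with the
    geometry, or if the query differs from the register-transformed base
    target anywhere outside the claimed mismatch positions or loop bases.
    """
    register, edit_site, mismatches = claimed
    if register not in REGISTERS:
        raise ValidationError(f"unknown register {register!r}")
    base = derive_base_target(b)
    n = len(base)
    expected_len = n + REGISTERS[register].target_length_delta
    if len(query) != expected_len:
        raise ValidationError(
            f"query length {len(query)} inconsistent with register {register} (expect {expected_len})"
        )
    pairs, loops, _ = _geometry(register, edit_site, n)
    mismatch_set = set(mismatches)
    count = 0
    for qp, tp in pairs:
        if query[qp - 1] == base[tp - 1]:
            count += 1
        elif qp not in mismatch_set:
            raise ValidationError(
                f"query differs from register-transformed target at unclaimed position {qp}"
            )
    # loop positions are unconstrained (any base), contribute no pairing
    del loops
    return count
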