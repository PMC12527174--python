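"""Design of candidate modified-U1 binding sequences for a 5'-SS mutation.

For each mutation, 35 *walking* designs slide an 11-nt target window at
1-nt resolution across offsets -10..+25 (no zero) around the mutant donor
junction; the binding sequence of each design is the reverse complement of
its mutant target window.  A 36th design ("E") adapts the endogenous U1 by
a single base change complementary to the mutant allele.  Designs whose
binding sequence starts with the dinucleotide UU, GA or GG are flagged as
destabilised at the 5' end.  Designs are ranked by predicted off-target
load, splice-site targets first.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

from Bio.Seq import Seq

from .registers import BindingSequence, RNU1_1, ValidationError
from .targetome import TargetomeSummary

__all__ = [
    "DesignedU1",
    "DonorContext",
    "WALK_RANGE",
    "UNSTABLE_5PRIME",
    "design_walking",
    "design_endogenous_adapted",
    "flag_unstable_5prime",
    "rank_designs",
    "walk_offsets",
]

#: Default walking range: 10 nt upstream to 25 nt downstream of the junction.
WALK_RANGE = (-10, 25)

#: 5'-end dinucleotides that destabilise a U1 binding sequence.
UNSTABLE_5PRIME = frozenset({"UU", "GA", "GG"})

BINDING_LENGTH = 11

#: Offsets of the canonical binding site footprint (5'-most base at -3).
CANONICAL_OFFSETS = tuple(o for o in range(-3, 9) if o != 0)


def walk_offsets(walk_range: tuple[int, int] = WALK_RANGE) -> list[int]:
    """All no-zero 5'-most offsets in the walking range."""
    lo, hi = walk_range
    if lo == 0 or hi == 0 or lo > hi:
        raise ValidationError(f"invalid walking range {walk_range}")
    return [o for o in range(lo, hi + 1) if o != 0]


@dataclass(frozen=True)
class DesignedU1:
    """A candidate binding sequence for one mutation.

    ``position`` is the SpliceOffset of the 5'-most target base, or "E"
    for the endogenous-adapted design.
    """

    mutation_id: str
    position: int | str
    binding_sequence: str  # RNA 5'->3'
    unstable_5prime: bool
    target_window: str  # mutant target window (DNA, transcript orientation)
    mutation_in_window: bool


@dataclass(frozen=True)
class DonorContext:
    """Mutant pre-mRNA sequence around one donor junction.

    ``sequence`` is transcript-oriented DNA with the mutation already
    applied; ``boundary_index`` is the 0-based index of the last exonic
    base (offset -1), so offset o maps to index ``boundary_index + o + 1``
    for o < 0 and ``boundary_index + o`` for o > 0.
    """

    mutation_id: str
    sequence: str
    boundary_index: int
    mutation_offset: int | None = None

    def offset_index(self, offset: int) -> int:
        if offset == 0:
            raise ValidationError("splice offsets have no zero")
        return self.boundary_index + offset + (1 if offset < 0 else 0)


def flag_unstable_5prime(seq: str) -> bool:
    """True iff the binding sequence starts with UU, GA or GG."""
    if len(seq) < 2:
        raise ValidationError("binding sequence shorter than 2 nt")
    head = seq[:2].upper().replace("T", "U")
    return head in UNSTABLE_5PRIME


def _binding_from_window(window: str) -> str:
    return str(Seq(window).reverse_complement().transcribe())


def design_walking(
    context: DonorContext,
    walk_range: tuple[int, int] = WALK_RANGE,
    length: int = BINDING_LENGTH,
) -> list[DesignedU1]:
    """One design per walking offset; 35 for the default -10..+25 range."""
    designs: list[DesignedU1] = []
    for off in walk_offsets(walk_range):
        i = context.offset_index(off)
        if i < 0 or i + length > len(context.sequence):
            raise ValidationError(
                f"{context.mutation_id}: context does not cover the {length}-nt window "
                f"at offset {off:+d} (need indices {i}..{i + length - 1}, "
                f"have 0..{len(context.sequence) - 1})"
            )
        window = context.sequence[i : i + length]
        binding = _binding_from_window(window)
        in_window = False
        if context.mutation_offset is not None:
            mi = context.offset_index(context.mutation_offset)
            in_window = i <= mi < i + length
        designs.append(
            DesignedU1(
                mutation_id=context.mutation_id,
                position=off,
                binding_sequence=binding,
                unstable_5prime=flag_unstable_5prime(binding),
                target_window=window,
                mutation_in_window=in_window,
            )
        )
    return designs


def design_endogenous_adapted(
    mutation: tuple[int, str],
    endogenous: BindingSequence = RNU1_1,
    mutation_id: str = "",
) -> DesignedU1:
    """The endogenous binding sequence with one base adapted to the mutant.

    The mutation is (SpliceOffset within the canonical -3..+8 window
    excluding +1/+2, mutant base on the transcript strand).  Antiparallel
    index mapping: target offsets -3..+8 pair with binding positions
    11..1, so the adapted base sits at binding position
    ``11 - (canonical index of the offset) + 1``.
    """
    offset, mutant_base = mutation
    if offset in (1, 2):
        raise ValidationError(f"offset {offset:+d}: +1/+2 mutations abolish splicing and are not rescuable")
    if offset not in CANONICAL_OFFSETS:
        raise ValidationError(f"offset {offset:+d} outside the canonical -3..+8 window")
    mutant_base = mutant_base.upper().replace("U", "T")
    if mutant_base not in "ACGT":
        raise ValidationError(f"invalid mutant base {mutant_base!r}")
    idx = CANONICAL_OFFSETS.index(offset)  # 0-based position in the target window
    binding_pos = len(endogenous) - idx  # 1-based position in the binding sequence
    complement = str(Seq(mutant_base).complement_rna())
    chars = list(endogenous.sequence)
    chars[binding_pos - 1] = complement
    binding = "".join(chars)
    return DesignedU1(
        mutation_id=mutation_id,
        position="E",
        binding_sequence=binding,
        unstable_5prime=flag_unstable_5prime(binding),
        target_window=str(Seq(binding).back_transcribe().reverse_complement()),
        mutation_in_window=True,
    )


def rank_designs(
    designs: list[DesignedU1],
    summaries: dict[tuple[str, int | str], TargetomeSummary],
    mab: int,
) -> tuple[list[tuple[DesignedU1, dict[str, int]]], dict[int | str, dict[str, dict[str, float]]]]:
    """Order designs by off-target load and aggregate per position.

    Designs are sorted ascending by (donor-target count, acceptor-target
    count, total targets) at the stated MAB; ties keep walking-position
    order.  Returns the ranked list of (design, counts) and a per-position
    aggregate of median and max counts per category across mutations.
    """
    rows: list[tuple[DesignedU1, dict[str, int]]] = []
    for d in designs:
        key = (d.mutation_id, d.position)
        if key not in summaries:
            raise ValidationError(f"missing targetome summary for design {key}")
        s = summaries[key]
        if mab not in s.totals:
            raise ValidationError(f"summary for {key} lacks MAB {mab}")
        counts = {
            "donor": s.by_category[mab]["donor"],
            "acceptor": s.by_category[mab]["acceptor"],
            "exonic": s.by_category[mab]["exonic"],
            "intronic": s.by_category[mab]["intronic"],
            "total": s.totals[mab],
        }
        rows.append((d, counts))

    def pos_order(p: int | str) -> tuple[int, int]:
        return (1, 0) if p == "E" else (0, p)

    rows.sort(key=lambda r: (r[1]["donor"], r[1]["acceptor"], r[1]["total"],
                             pos_order(r[0].position)))

    by_pos: dict[int | str, list[dict[str, int]]] = {}
    for d, counts in rows:
        by_pos.setdefault(d.position, []).append(counts)
    aggregate: dict[int | str, dict[str, dict[str, float]]] = {}
    for pos, clist in by_pos.items():
        aggregate[pos] = {
            cat: {
                "median": float(statistics.median(c[cat] for c in clist)),
                "max": float(max(c[cat] for c in clist)),
            }
            for cat in ("donor", "acceptor", "exonic", "intronic", "total")
        }
    return rows, aggregate
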