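"""Domain types for the topology census: proteins, TMDs, loops/tails.

Coordinates are 1-based and inclusive on both ends (UniProt convention).
Membrane sides use ``"inside"`` (cytosolic) and ``"outside"`` (exoplasmic,
i.e. ER-lumenal). A protein's ``n_terminus_side`` says where the N terminus
of the mature chain faces; sides of successive extramembrane segments then
alternate, each TMD flipping the side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

INSIDE = "inside"
OUTSIDE = "outside"
SIDES = (INSIDE, OUTSIDE)

N_TAIL = "n_tail"
INTERNAL_LOOP = "internal_loop"
C_TAIL = "c_tail"

#: the 20 canonical amino acids; X is tolerated in sequences but not scorable
CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")
TOLERATED_AA = CANONICAL_AA | {"X"}


def opposite(side: str) -> str:
    if side == INSIDE:
        return OUTSIDE
    if side == OUTSIDE:
        return INSIDE
    raise ValueError(f"unknown membrane side: {side!r}")


@dataclass
class TmdSegment:
    """One transmembrane domain (1-based inclusive coordinates)."""

    index: int  # 1-based ordinal within the protein
    start: int
    end: int
    sequence: str
    dg_app: Optional[float] = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def unusual_length(self) -> bool:
        """Lengths ≤14 or ≥35 aa are permitted but flagged for inspection."""
        return self.length <= 14 or self.length >= 35


@dataclass
class LoopSegment:
    """A tail or inter-TMD loop.

    Ordinal 1 is the N-terminal tail, ordinal nTMD+1 the C-terminal tail.
    Zero-length segments (abutting TMDs) are encoded with end == start - 1;
    ``length`` is clamped at 0, never negative.
    """

    ordinal: int
    start: int
    end: int
    kind: str
    side: Optional[str] = None

    @property
    def length(self) -> int:
        return max(0, self.end - self.start + 1)

    def extract(self, protein_sequence: str) -> str:
        if self.length == 0:
            return ""
        return protein_sequence[self.start - 1 : self.end]


@dataclass
class Violation:
    field: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.field}: {self.rule} — {self.message}"


@dataclass
class ProteinRecord:
    """One curated protein with its ordered TMDs and orientation."""

    accession: str
    gene_name: str
    length: int
    sequence: str
    n_terminus_side: str
    signal_peptide: Optional[tuple[int, int]] = None
    tmds: list[TmdSegment] = field(default_factory=list)

    @property
    def n_tmds(self) -> int:
        return len(self.tmds)

    @property
    def is_single_pass(self) -> bool:
        return self.n_tmds == 1

    @property
    def has_signal(self) -> bool:
        return self.signal_peptide is not None

    def tmd_sequences_valid(self) -> bool:
        return all(
            self.sequence[t.start - 1 : t.end] == t.sequence for t in self.tmds
        )


def validate_record(record: ProteinRecord) -> list[Violation]:
    """Check every type invariant; violations are data, not exceptions."""
    v: list[Violation] = []
    if record.length != len(record.sequence):
        v.append(
            Violation(
                "length",
                "length == len(sequence)",
                f"declared {record.length}, sequence has {len(record.sequence)}",
            )
        )
    bad = set(record.sequence) - TOLERATED_AA
    if bad:
        v.append(
            Violation(
                "sequence",
                "canonical residues (X tolerated)",
                f"disallowed letters {sorted(bad)}",
            )
        )
    if record.n_terminus_side not in SIDES:
        v.append(
            Violation(
                "n_terminus_side", "inside|outside", repr(record.n_terminus_side)
            )
        )
    sig = record.signal_peptide
    if sig is not None:
        s, e = sig
        if s != 1:
            v.append(
                Violation("signal_peptide", "starts at residue 1", f"starts at {s}")
            )
        if not (1 <= e <= len(record.sequence)):
            v.append(
                Violation(
                    "signal_peptide", "within sequence", f"ends at {e}"
                )
            )
        if record.n_terminus_side != OUTSIDE:
            v.append(
                Violation(
                    "n_terminus_side",
                    "signal peptide forces outside",
                    "cleavable signal with n_terminus_side=inside is contradictory",
                )
            )
    if not record.tmds:
        v.append(Violation("tmds", "at least one TMD", "no TMDs"))
    prev_end = sig[1] if sig is not None else 0
    for i, t in enumerate(record.tmds, start=1):
        tag = f"TMD{i}"
        if t.index != i:
            v.append(Violation("tmds", "indices 1..n in order", f"{tag} has index {t.index}"))
        if t.start < 1 or t.end > record.length:
            v.append(
                Violation(
                    "tmds", "span within [1, length]", f"{tag} spans {t.start}-{t.end}"
                )
            )
        if t.end < t.start:
            v.append(Violation("tmds", "end >= start", f"{tag} spans {t.start}-{t.end}"))
        if t.start <= prev_end:
            what = "signal peptide" if (sig and i == 1 and t.start <= sig[1]) else f"TMD{i-1}"
            v.append(
                Violation(
                    "tmds",
                    "ordered, non-overlapping",
                    f"{tag} starts at {t.start}, overlapping/preceding {what}",
                )
            )
        if t.end - t.start + 1 != len(t.sequence):
            v.append(
                Violation(
                    "tmds",
                    "span length == sequence length",
                    f"{tag}: span {t.length} aa, sequence {len(t.sequence)} aa",
                )
            )
        prev_end = max(prev_end, t.end)
    # brute pairwise overlap check (redundant with the ordered walk above but
    # reports one violation per overlapping pair, as promised)
    for i in range(len(record.tmds)):
        for j in range(i + 1, len(record.tmds)):
            a, b = record.tmds[i], record.tmds[j]
            lo, hi = (a, b) if a.start <= b.start else (b, a)
            if hi.start <= lo.end:
                v.append(
                    Violation(
                        "tmds",
                        "pairwise disjoint",
                        f"TMD{a.index} and TMD{b.index} overlap",
                    )
                )
    if record.length == len(record.sequence) and not record.tmd_sequences_valid():
        v.append(
            Violation(
                "tmds",
                "TMD sequence matches coordinates",
                "recorded TMD sequence differs from the coordinate slice",
            )
        )
    return v


def deduce_segments(record: ProteinRecord) -> list[LoopSegment]:
    """Deduce the nTMD+1 tails/loops tiling the non-TMD, non-signal sequence.

    The N-terminal tail runs from residue 1 (or signal_end+1 when a signal
    peptide is present) to TMD1_start−1; internal loops run between successive
    TMDs; the C-terminal tail runs from TMDn_end+1 to the end of the protein.
    Abutting TMDs yield zero-length loops.
    """
    segs: list[LoopSegment] = []
    n = record.n_tmds
    first_start = record.signal_peptide[1] + 1 if record.has_signal else 1
    segs.append(
        LoopSegment(
            ordinal=1,
            start=first_start,
            end=record.tmds[0].start - 1,
            kind=N_TAIL,
        )
    )
    for i in range(n - 1):
        segs.append(
            LoopSegment(
                ordinal=i + 2,
                start=record.tmds[i].end + 1,
                end=record.tmds[i + 1].start - 1,
                kind=INTERNAL_LOOP,
            )
        )
    segs.append(
        LoopSegment(
            ordinal=n + 1,
            start=record.tmds[-1].end + 1,
            end=record.length,
            kind=C_TAIL,
        )
    )
    return segs


def assign_locations(
    record: ProteinRecord, segments: Iterable[LoopSegment]
) -> list[LoopSegment]:
    """Set the membrane side of each segment by alternation.

    Segment 1 (the N tail) sits on ``n_terminus_side``; each TMD crossing
    flips the side, so segment k sits on the N side iff k is odd.
    """
    out = list(segments)
    side = record.n_terminus_side
    for k, seg in enumerate(out, start=1):
        seg.side = side if k % 2 == 1 else opposite(side)
    return out


def segments_with_sides(record: ProteinRecord) -> list[LoopSegment]:
    """Convenience: :func:`deduce_segments` + :func:`assign_locations`."""
    return assign_locations(record, deduce_segments(record))


@dataclass
class ParseReport:
    source: str = ""
    rows_read: int = 0
    rows_accepted: int = 0
    rejected: list[tuple[str, str]] = field(default_factory=list)  # (row id, reason)
    column_mapping: dict[str, str] = field(default_factory=dict)
    loop_mismatches: list[str] = field(default_factory=list)

    @property
    def rows_rejected(self) -> int:
        return len(self.rejected)


@dataclass
class CensusTable:
    records: list[ProteinRecord]
    provenance: ParseReport = field(default_factory=ParseReport)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.accession in seen:
                raise ValueError(f"duplicate accession {r.accession}")
            seen.add(r.accession)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, accession: str) -> ProteinRecord:
        for r in self.records:
            if r.accession == accession:
                return r
        raise KeyError(accession)
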