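"""Topology classes, signal-anchor classes, TMD pairs, and insertion reactions.

Protein classes
---------------
Single-pass: SP-I (cleavable signal, N_exo), SP-II (N_cyt signal anchor, long
C tail), SP-III (N_exo signal anchor), SP-IV (tail-anchored: N_cyt with a
C tail ≤50 aa, posttranslationally inserted). Multipass: MP-SS (cleavable
signal), MP-Nexo / MP-Ncyt by N-terminus orientation.

TMD pairs
---------
A pair is two consecutive TMDs separated by a short (≤50 aa) exoplasmic loop,
treated as one insertion unit. Pairing is greedy left-to-right; because loop
sides alternate, an exoplasmic loop is always followed by a cytosolic one, so
greedy pairing can never orphan a TMD between two short exoplasmic loops.

Insertion reactions
-------------------
Each TMD gets one of six core membrane-insertion reactions: R1 (TMD after a
cleavable signal, through the Sec61 lateral gate), R2 (N_cyt signal anchor
with a long translocated loop, Sec61), R3 (N_exo signal anchor, insertase),
R4 (tail-anchored, posttranslational insertase), R5a/R5b (the two TMDs
flanking a long >100 aa exoplasmic loop, Sec61), R6a/R6b (first/second TMD of
a pair, insertase). TMDs fitting none of these (intermediate 51–100 aa
translocated domains, unpaired terminal TMDs) are labelled residual with a
sub-reason rather than forced into a reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .records import (
    INSIDE,
    OUTSIDE,
    LoopSegment,
    ProteinRecord,
    segments_with_sides,
)

SP_I = "SP-I"
SP_II = "SP-II"
SP_III = "SP-III"
SP_IV = "SP-IV"
MP_SS = "MP-SS"
MP_NEXO = "MP-Nexo"
MP_NCYT = "MP-Ncyt"
PROTEIN_CLASSES = (SP_I, SP_II, SP_III, SP_IV, MP_SS, MP_NEXO, MP_NCYT)
SP_CLASSES = (SP_I, SP_II, SP_III, SP_IV)
MP_CLASSES = (MP_SS, MP_NEXO, MP_NCYT)

NEXO_SA = "Nexo_SA"
NCYT_LONG_SA = "Ncyt_long_SA"
NCYT_PAIR_SA = "Ncyt_pair_SA"
SA_OTHER = "SA_other"

LOOP_SHORT = "short"  # ≤50 aa
LOOP_INTERMEDIATE = "intermediate"  # 51–100 aa
LOOP_LONG = "long"  # >100 aa

SHORT_MAX = 50
LONG_MIN = 101

FIRST_PAIR = "first_pair"
AFTER_SHORT_CYT = "internal_after_short_cyt"
AFTER_INTERMEDIATE_CYT = "after_intermediate_cyt"
AFTER_LONG_CYT = "after_long_cyt"


def classify_loop(length: int) -> str:
    """Loop-length class: ≤50 short, 51–100 intermediate, >100 long."""
    if length <= SHORT_MAX:
        return LOOP_SHORT
    if length < LONG_MIN:
        return LOOP_INTERMEDIATE
    return LOOP_LONG


@dataclass
class TmdPair:
    first: int  # 1-based TMD indices
    second: int
    exo_loop: LoopSegment
    context: str

    def __post_init__(self):
        if self.exo_loop.side != OUTSIDE:
            raise ValueError("pair loop must be exoplasmic")
        if self.exo_loop.length > SHORT_MAX:
            raise ValueError("pair loop must be ≤50 aa")


@dataclass
class TopologyLabels:
    protein_class: str
    sa_class: Optional[str]
    pairs: list[TmdPair]
    loop_classes: list[str]  # per segment, ordinal order
    reactions: list[str]  # per TMD
    reaction_reasons: list[str]  # sub-reason for residual TMDs, "" otherwise
    contexts: list[frozenset] = field(default_factory=list)  # per-TMD strata tags


def classify_protein(record: ProteinRecord, segments: list[LoopSegment]) -> str:
    """Assign the single topology class of a protein."""
    if record.is_single_pass:
        if record.has_signal:
            return SP_I
        if record.n_terminus_side == OUTSIDE:
            return SP_III
        c_tail = segments[-1]
        return SP_IV if c_tail.length <= SHORT_MAX else SP_II
    if record.has_signal:
        return MP_SS
    return MP_NEXO if record.n_terminus_side == OUTSIDE else MP_NCYT


def find_tmd_pairs(
    record: ProteinRecord, segments: list[LoopSegment]
) -> list[TmdPair]:
    """Greedy left-to-right, non-overlapping pairing of TMDs across short
    exoplasmic loops. Single-pass records yield no pairs."""
    pairs: list[TmdPair] = []
    n = record.n_tmds
    if n < 2:
        return pairs
    paired_second: set[int] = set()
    for i in range(1, n):  # candidate pair (i, i+1); loop between is segment i+1
        loop = segments[i]
        if loop.side != OUTSIDE or loop.length > SHORT_MAX:
            continue
        if i in paired_second:
            continue
        if i == 1:
            context = FIRST_PAIR
        else:
            preceding = segments[i - 1]  # cytosolic flank before TMD i
            cls = classify_loop(preceding.length)
            context = {
                LOOP_SHORT: AFTER_SHORT_CYT,
                LOOP_INTERMEDIATE: AFTER_INTERMEDIATE_CYT,
                LOOP_LONG: AFTER_LONG_CYT,
            }[cls]
        pairs.append(TmdPair(first=i, second=i + 1, exo_loop=loop, context=context))
        paired_second.add(i + 1)
    return pairs


def classify_sa(
    record: ProteinRecord,
    segments: list[LoopSegment],
    pairs: list[TmdPair],
) -> str:
    """Class of a cotranslational signal anchor (first TMD, no cleavable
    signal). Tail-anchored proteins are posttranslational and excluded."""
    if record.has_signal:
        raise ValueError("classify_sa called on a signal-bearing protein")
    protein_class = classify_protein(record, segments)
    if protein_class == SP_IV:
        raise ValueError("classify_sa called on a tail-anchored protein")
    if record.n_terminus_side == OUTSIDE:
        return NEXO_SA
    if any(p.first == 1 for p in pairs):
        return NCYT_PAIR_SA
    downstream = segments[1]  # segment after TMD1, exoplasmic for N_cyt
    if downstream.length > 100:
        return NCYT_LONG_SA
    return SA_OTHER


# per-TMD context tags used as analysis strata
SS_FOLLOWING = "SS_following"
NCYT_LONG_FOLLOWING = "Ncyt_long_following"
PAIR_FIRST = "pair_first"
PAIR_SECOND = "pair_second"
LONG_EXO_FIRST = "long_exo_first"
LONG_EXO_SECOND = "long_exo_second"
FINAL_C_TERMINAL = "final_c_terminal"


def label_protein(
    record: ProteinRecord, segments: Optional[list[LoopSegment]] = None
) -> TopologyLabels:
    """Run the full per-protein classification: class, SA class, pairs,
    loop classes, per-TMD reactions and context tags."""
    if segments is None:
        segments = segments_with_sides(record)
    protein_class = classify_protein(record, segments)
    pairs = find_tmd_pairs(record, segments)
    loop_classes = [classify_loop(s.length) for s in segments]

    sa_class: Optional[str] = None
    if protein_class in (SP_II, SP_III, MP_NEXO, MP_NCYT):
        sa_class = classify_sa(record, segments, pairs)

    n = record.n_tmds
    reactions = [""] * n
    reasons = [""] * n
    contexts: list[set] = [set() for _ in range(n)]

    pair_of_first = {p.first: p for p in pairs}
    pair_of_second = {p.second: p for p in pairs}

    # first-TMD rules
    if protein_class == SP_IV:
        reactions[0] = "R4"
    elif record.has_signal:
        reactions[0] = "R1"
        contexts[0].add(SS_FOLLOWING)
    elif sa_class == NEXO_SA:
        reactions[0] = "R3"
    elif sa_class == NCYT_LONG_SA:
        reactions[0] = "R2"
    elif sa_class == NCYT_PAIR_SA:
        reactions[0] = "R6a"
    else:  # SA_other: intermediate translocated domain, route ambiguous
        reactions[0] = "residual"
        reasons[0] = "intermediate_translocated_domain"

    # pair rules
    for p in pairs:
        i, j = p.first - 1, p.second - 1
        if not reactions[i]:
            reactions[i] = "R6a"
        if not reactions[j]:
            reactions[j] = "R6b"
        contexts[i].add(PAIR_FIRST)
        contexts[j].add(PAIR_SECOND)
        contexts[i].add(f"pair_context:{p.context}")
        contexts[j].add(f"pair_context:{p.context}")

    # long exoplasmic inter-TMD loops: flanking TMDs go through Sec61
    for k in range(1, n):  # segment k+1 sits between TMD k and TMD k+1
        loop = segments[k]
        if loop.kind != "internal_loop" or loop.side != OUTSIDE:
            continue
        if loop.length > 100:
            if not reactions[k - 1]:
                reactions[k - 1] = "R5a"
            if not reactions[k]:
                reactions[k] = "R5b"
            contexts[k - 1].add(LONG_EXO_FIRST)
            contexts[k].add(LONG_EXO_SECOND)

    # the TMD downstream of an Ncyt-long SA's translocated loop inserts via
    # the Sec61 lateral gate; tag it as its own stratum
    if sa_class == NCYT_LONG_SA and n >= 2:
        contexts[1].add(NCYT_LONG_FOLLOWING)

    for k in range(n):
        if not reactions[k]:
            reactions[k] = "residual"
            nxt = segments[k + 1]
            if classify_loop(nxt.length) == LOOP_INTERMEDIATE and nxt.side == OUTSIDE:
                reasons[k] = "intermediate_exoplasmic_loop"
            elif k == n - 1:
                reasons[k] = "unpaired_terminal_TMD"
            else:
                reasons[k] = "unpaired_internal_TMD"
    if n >= 2:
        contexts[n - 1].add(FINAL_C_TERMINAL)

    return TopologyLabels(
        protein_class=protein_class,
        sa_class=sa_class,
        pairs=pairs,
        loop_classes=loop_classes,
        reactions=reactions,
        reaction_reasons=reasons,
        contexts=[frozenset(c) for c in contexts],
    )


def classify_reactions(
    record: ProteinRecord, segments: Optional[list[LoopSegment]] = None
) -> list[str]:
    """Per-TMD insertion-reaction labels (thin wrapper over label_protein)."""
    return label_protein(record, segments).reactions


def classify_tmd_context(
    record: ProteinRecord, segments: Optional[list[LoopSegment]] = None
) -> list[frozenset]:
    """Per-TMD analysis-strata tags (thin wrapper over label_protein)."""
    return label_protein(record, segments).contexts
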