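"""Aggregate census statistics: counts by class, length and ΔG_app
distributions, amino-acid frequencies, sequon census, and the full report.

Conventions: medians of even-sized samples are the mean of the two central
values; "short" domains are ≤50 aa and "long" >100 aa throughout; zero-length
loops are included in length statistics; reports are deterministic (fixed
ordering and float formatting) so identical inputs give byte-identical JSON.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import charges as _charges
from .classify import (
    MP_CLASSES,
    PROTEIN_CLASSES,
    SP_CLASSES,
    TopologyLabels,
    label_protein,
)
from .records import (
    INSIDE,
    OUTSIDE,
    CensusTable,
    LoopSegment,
    ProteinRecord,
    segments_with_sides,
)

AA_ORDER = tuple("ACDEFGHIKLMNPQRSTVWY")
HYDROPHOBIC_SET = tuple("LVIAFMW")

DEFAULT_SEQUON_DISTANCE = 12


def _stats(values: Iterable[float]) -> dict:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return {"n": 0}
    return {
        "n": int(arr.size),
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
    }


def length_summary(
    table: CensusTable, segments_by_acc: Optional[dict] = None
) -> pd.DataFrame:
    """Tail/loop length statistics per (membrane side × SP/MP × kind).

    Kinds are tails, loops, and both (pooled per segment); zero-length loops
    are included. Also emits "All/Both" rows pooling SP and MP.
    """
    rows = []
    for rec in table:
        segs = (
            segments_by_acc[rec.accession]
            if segments_by_acc
            else segments_with_sides(rec)
        )
        topo = "Single-pass" if rec.is_single_pass else "Multipass"
        for seg in segs:
            kind = "Tails" if seg.kind in ("n_tail", "c_tail") else "Loops"
            rows.append(
                {
                    "location": "Exoplasmic" if seg.side == OUTSIDE else "Cytosolic",
                    "topology": topo,
                    "type": kind,
                    "length": seg.length,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["location", "topology", "type", "n", "mean", "median"]
        )
    df = pd.DataFrame(rows)
    out = []
    for loc in ("Exoplasmic", "Cytosolic"):
        sub = df[df["location"] == loc]
        for topo in ("Single-pass", "Multipass"):
            tsub = sub[sub["topology"] == topo]
            kinds = ["Tails", "Loops", "Both"] if topo == "Multipass" else ["Tails"]
            for kind in kinds:
                ksub = tsub if kind == "Both" else tsub[tsub["type"] == kind]
                if len(ksub) == 0:
                    continue
                st = _stats(ksub["length"])
                out.append({"location": loc, "topology": topo, "type": kind, **st})
        if len(sub):
            st = _stats(sub["length"])
            out.append({"location": loc, "topology": "All", "type": "Both", **st})
    return pd.DataFrame(out)


def aa_frequency(table: CensusTable, labels_by_acc: dict) -> pd.DataFrame:
    """Amino-acid frequencies (%) over TMD residues for the all/SP/MP sets,
    plus per-aa log2(MP/SP) ratios (NaN where an aa is absent from a set)."""
    counts = {"all": {}, "SP": {}, "MP": {}}
    for rec in table:
        is_sp = labels_by_acc[rec.accession].protein_class in SP_CLASSES
        group = "SP" if is_sp else "MP"
        for tmd in rec.tmds:
            for aa in tmd.sequence:
                for g in ("all", group):
                    counts[g][aa] = counts[g].get(aa, 0) + 1
    if not counts["all"]:
        raise ValueError("no TMD residues to tabulate")
    rows = []
    totals = {g: sum(c.values()) for g, c in counts.items()}
    for aa in AA_ORDER:
        freq = {
            g: 100.0 * counts[g].get(aa, 0) / totals[g] if totals[g] else float("nan")
            for g in ("all", "SP", "MP")
        }
        sp, mp = freq["SP"], freq["MP"]
        ratio = float(np.log2(mp / sp)) if sp > 0 and mp > 0 else float("nan")
        rows.append(
            {
                "aa": aa,
                "all_pct": freq["all"],
                "sp_pct": sp,
                "mp_pct": mp,
                "log2_mp_sp": ratio,
            }
        )
    return pd.DataFrame(rows)


def dg_distribution(
    table: CensusTable, labels_by_acc: dict, strata: Optional[dict] = None
) -> pd.DataFrame:
    """ΔG_app mean/median and sign fractions per TMD stratum.

    Built-in strata: all, SP, MP, the SA classes, pair members, and per-TMD
    context tags. ``strata`` may map extra names to predicates
    ``(record, labels, tmd_index) -> bool``. Missing ΔG values are an error
    naming the TMDs.
    """
    missing = [
        f"{rec.accession}/TMD{t.index}"
        for rec in table
        for t in rec.tmds
        if t.dg_app is None
    ]
    if missing:
        raise ValueError(f"TMDs without ΔG_app: {', '.join(missing[:10])}"
                         + ("..." if len(missing) > 10 else ""))
    rows = []
    for rec in table:
        labels = labels_by_acc[rec.accession]
        is_sp = labels.protein_class in SP_CLASSES
        paired = {p.first for p in labels.pairs} | {p.second for p in labels.pairs}
        for tmd in rec.tmds:
            tags = {"all", "SP" if is_sp else "MP"}
            if tmd.index == 1 and labels.sa_class is not None:
                tags.add(f"SA:{labels.sa_class}")
            if tmd.index in paired:
                tags.add("pair_member")
            tags |= {f"ctx:{c}" for c in labels.contexts[tmd.index - 1]}
            tags.add(f"reaction:{labels.reactions[tmd.index - 1]}")
            if strata:
                for name, pred in strata.items():
                    if pred(rec, labels, tmd.index):
                        tags.add(name)
            for tag in tags:
                rows.append({"stratum": tag, "dg": tmd.dg_app})
    df = pd.DataFrame(rows)
    out = (
        df.groupby("stratum", sort=True)["dg"]
        .agg(
            n="size",
            mean="mean",
            median="median",
            pct_negative=lambda s: 100.0 * float((s < 0).mean()),
            pct_positive=lambda s: 100.0 * float((s > 0).mean()),
        )
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out


@dataclass(frozen=True)
class Sequon:
    position: int  # 1-based position of the N
    motif: str  # the three residues
    side: Optional[str]  # side of the containing segment; None inside a TMD
    min_tmd_distance: int
    usable: bool


def find_sequons(
    record: ProteinRecord,
    segments: Optional[list[LoopSegment]] = None,
    min_tmd_distance: int = DEFAULT_SEQUON_DISTANCE,
    exclude_proline: bool = True,
) -> list[Sequon]:
    """N-glycosylation sequons N-X-[S/T] (X ≠ P in the strict default form).

    A sequon is usable iff its N lies in an exoplasmic segment and at least
    ``min_tmd_distance`` residues from every TMD boundary.
    """
    if segments is None:
        segments = segments_with_sides(record)
    pattern = r"N(?=[^P][ST])" if exclude_proline else r"N(?=.[ST])"
    out = []
    for m in re.finditer(pattern, record.sequence):
        p = m.start() + 1
        side = None
        for seg in segments:
            if seg.length and seg.start <= p <= seg.end:
                side = seg.side
                break
        dist = min(
            (t.start - p if p < t.start else p - t.end if p > t.end else 0)
            for t in record.tmds
        )
        usable = side == OUTSIDE and dist >= min_tmd_distance
        out.append(
            Sequon(
                position=p,
                motif=record.sequence[p - 1 : p + 2],
                side=side,
                min_tmd_distance=dist,
                usable=usable,
            )
        )
    return out


@dataclass
class CensusSummary:
    """Aggregate census mirroring the published tables and figure panels."""

    n_proteins: int = 0
    n_tmds: int = 0
    class_counts: dict = field(default_factory=dict)
    tmd_counts_per_class: dict = field(default_factory=dict)
    sa_class_counts: dict = field(default_factory=dict)
    reaction_counts: dict = field(default_factory=dict)
    length_stats: list = field(default_factory=list)
    tmd_length: dict = field(default_factory=dict)
    dg_stats: list = field(default_factory=list)
    aa_freq: list = field(default_factory=list)
    loop_class_counts: dict = field(default_factory=dict)
    pair_counts: dict = field(default_factory=dict)
    flank_charge_means: list = field(default_factory=list)
    pair_bias: dict = field(default_factory=dict)
    sequon_counts: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        def _round(obj):
            if isinstance(obj, float):
                return round(obj, 4)
            if isinstance(obj, dict):
                return {k: _round(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_round(v) for v in obj]
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return round(float(obj), 4)
            return obj

        return json.dumps(_round(self.__dict__), indent=indent, sort_keys=False)


def census_report(
    table: CensusTable,
    scale=None,
    sequon_distance: int = DEFAULT_SEQUON_DISTANCE,
    proportional: bool = True,
    windows: tuple[int, ...] = _charges.DEFAULT_WINDOWS,
) -> CensusSummary:
    """Run the full census over a validated table.

    Missing ΔG_app values are computed with the bundled hydrophobicity scale;
    recorded values are kept.
    """
    from .dg import default_scale, score_all_tmds

    summary = CensusSummary()
    summary.n_proteins = len(table)
    summary.parameters = {
        "sequon_min_tmd_distance": sequon_distance,
        "proportional_flank_scaling": proportional,
        "flank_windows": list(windows),
    }
    if len(table) == 0:
        return summary

    scale = scale or default_scale()
    summary.parameters["dg_scale"] = scale.provenance
    score_all_tmds(table, scale, rescore=False)

    segments_by_acc = {r.accession: segments_with_sides(r) for r in table}
    labels_by_acc: dict[str, TopologyLabels] = {
        r.accession: label_protein(r, segments_by_acc[r.accession]) for r in table
    }

    summary.n_tmds = sum(r.n_tmds for r in table)
    for cls in PROTEIN_CLASSES:
        n = sum(1 for r in table if labels_by_acc[r.accession].protein_class == cls)
        if n:
            summary.class_counts[cls] = n
            summary.tmd_counts_per_class[cls] = sum(
                r.n_tmds
                for r in table
                if labels_by_acc[r.accession].protein_class == cls
            )
    summary.class_counts["single_pass"] = sum(
        summary.class_counts.get(c, 0) for c in SP_CLASSES
    )
    summary.class_counts["multipass"] = sum(
        summary.class_counts.get(c, 0) for c in MP_CLASSES
    )

    sa_counts: dict[str, int] = {}
    for r in table:
        sa = labels_by_acc[r.accession].sa_class
        if sa:
            sa_counts[sa] = sa_counts.get(sa, 0) + 1
    summary.sa_class_counts = dict(sorted(sa_counts.items()))

    rxn: dict[str, int] = {}
    for r in table:
        for lab in labels_by_acc[r.accession].reactions:
            rxn[lab] = rxn.get(lab, 0) + 1
    summary.reaction_counts = dict(sorted(rxn.items()))

    summary.length_stats = length_summary(table, segments_by_acc).to_dict("records")
    summary.tmd_length = _stats(t.length for r in table for t in r.tmds)
    summary.dg_stats = dg_distribution(table, labels_by_acc).to_dict("records")
    summary.aa_freq = aa_frequency(table, labels_by_acc).to_dict("records")

    # loop-length classes for multipass inter-TMD loops, by side
    loop_counts: dict[str, int] = {}
    for r in table:
        if r.is_single_pass:
            continue
        labels = labels_by_acc[r.accession]
        for seg, cls in zip(segments_by_acc[r.accession], labels.loop_classes):
            if seg.kind != "internal_loop":
                continue
            side = "exoplasmic" if seg.side == OUTSIDE else "cytosolic"
            key = f"{side}_{cls}"
            loop_counts[key] = loop_counts.get(key, 0) + 1
    summary.loop_class_counts = dict(sorted(loop_counts.items()))

    pair_ctx: dict[str, int] = {}
    n_pairs = 0
    pair_loop_lengths: list[int] = []
    inside_biases: list[float] = []
    outside_biases: list[float] = []
    for r in table:
        labels = labels_by_acc[r.accession]
        for p in labels.pairs:
            n_pairs += 1
            pair_ctx[p.context] = pair_ctx.get(p.context, 0) + 1
            pair_loop_lengths.append(p.exo_loop.length)
            bias = _charges.pair_charge_bias(
                r, segments_by_acc[r.accession], p, proportional
            )
            inside_biases.append(bias["inside_bias"])
            outside_biases.append(bias["outside_bias"])
    summary.pair_counts = {"total": n_pairs, **dict(sorted(pair_ctx.items()))}
    summary.pair_bias = {
        "loop_length": _stats(pair_loop_lengths),
        "inside_bias": _stats(inside_biases),
        "outside_bias": _stats(outside_biases),
    }

    summary.flank_charge_means = _charges.positive_inside_summary(
        table, labels_by_acc, windows, proportional
    ).to_dict("records")

    total = usable = 0
    usable_sp = 0
    for r in table:
        seqs = find_sequons(
            r, segments_by_acc[r.accession], min_tmd_distance=sequon_distance
        )
        total += len(seqs)
        n_u = sum(1 for s in seqs if s.usable)
        usable += n_u
        if r.is_single_pass:
            usable_sp += n_u
    summary.sequon_counts = {
        "total": total,
        "usable": usable,
        "usable_single_pass": usable_sp,
        "usable_single_pass_pct": 100.0 * usable_sp / usable if usable else float("nan"),
    }
    return summary
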