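"""Charge statistics: TMD zone partitioning, charge depth maps, flanking
net-charge windows, combined interfacial+flank charges, and pair-level biases.

Each TMD is divided into five zones along the membrane normal — exoplasmic
interface (outermost 20%), three hydrophobic-core segments (15/30/15%), and
cytosolic interface (innermost 20%) — with boundaries at cumulative fractions
0.20/0.35/0.65/0.80 of TMD length, each rounded half-up so the zones always
tile the TMD. Charges are K/R (+1) and D/E (−1); His is not counted.

Flanking windows of 5, 10, or 15 residues are taken from the adjacent loop or
tail only (never reading through a neighboring TMD or into a cleaved signal
peptide); when the available flank is shorter than the window, the net charge
is scaled proportionally by W/L (flagged), which keeps it an expected count
over W residues. A configuration switch disables the scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .records import (
    INSIDE,
    OUTSIDE,
    LoopSegment,
    ProteinRecord,
    segments_with_sides,
)

ZONES = ("exo_interface", "core_outer", "core_center", "core_inner", "cyt_interface")
_CUM_FRACTIONS = (0.20, 0.35, 0.65, 0.80)

BASIC = set("KR")
ACIDIC = set("DE")
CHARGED = BASIC | ACIDIC

DEFAULT_WINDOWS = (5, 10, 15)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def zone_sizes(length: int) -> tuple[int, int, int, int, int]:
    """Residue counts of the five zones (exoplasmic to cytosolic order)."""
    if length < 5:
        raise ValueError(f"TMD of {length} aa too short for a five-zone partition")
    bounds = [_round_half_up(f * length) for f in _CUM_FRACTIONS]
    edges = [0, *bounds, length]
    return tuple(edges[i + 1] - edges[i] for i in range(5))  # type: ignore[return-value]


def tmd_orientation(record: ProteinRecord, segments: list[LoopSegment], tmd_index: int) -> str:
    """Side faced by the N-terminal end of the TMD ("outside" means the
    sequence runs exoplasmic → cytosolic)."""
    return segments[tmd_index - 1].side


def zone_partition(
    record: ProteinRecord, segments: list[LoopSegment], tmd_index: int
) -> list[str]:
    """Per-residue zone labels in sequence order (N to C) for one TMD."""
    tmd = record.tmds[tmd_index - 1]
    sizes = zone_sizes(tmd.length)
    labels: list[str] = []
    for zone, k in zip(ZONES, sizes):
        labels.extend([zone] * k)
    if tmd_orientation(record, segments, tmd_index) == INSIDE:
        labels.reverse()  # N end is cytosolic: sequence runs cyt -> exo
    return labels


@dataclass(frozen=True)
class FlankCharge:
    tmd_id: str
    side: str
    window: int
    net: float
    scaled: bool
    flank_length: int


def _flank_sequence(
    record: ProteinRecord, segments: list[LoopSegment], tmd_index: int, side: str
) -> str:
    """The loop/tail residues adjacent to a TMD on the given membrane side,
    nearest residue first."""
    if side not in (INSIDE, OUTSIDE):
        raise ValueError(f"invalid side {side!r}")
    n_side_seg = segments[tmd_index - 1]
    c_side_seg = segments[tmd_index]
    if n_side_seg.side == side:
        seq = n_side_seg.extract(record.sequence)
        return seq[::-1]  # nearest to the TMD first
    if c_side_seg.side == side:
        return c_side_seg.extract(record.sequence)
    raise ValueError(
        f"TMD{tmd_index} has no {side} flank (sides are "
        f"{n_side_seg.side}/{c_side_seg.side})"
    )


def _net(seq: Iterable[str]) -> int:
    return sum(1 for a in seq if a in BASIC) - sum(1 for a in seq if a in ACIDIC)


def flank_net_charge(
    record: ProteinRecord,
    segments: list[LoopSegment],
    tmd_index: int,
    side: str,
    window: int,
    proportional: bool = True,
) -> FlankCharge:
    """Net charge over the ``window`` flank residues adjacent to a TMD.

    Flanks shorter than the window are scaled by W/L (or counted as-is with
    ``proportional=False``); an empty flank contributes 0.
    """
    flank = _flank_sequence(record, segments, tmd_index, side)
    avail = len(flank)
    tid = f"{record.accession}/TMD{tmd_index}"
    if avail == 0:
        return FlankCharge(tid, side, window, 0.0, False, 0)
    counted = flank[:window]
    net = float(_net(counted))
    scaled = False
    if avail < window:
        if proportional:
            net *= window / avail
        scaled = True
    return FlankCharge(tid, side, window, net, scaled, avail)


def interfacial_net_charge(
    record: ProteinRecord, segments: list[LoopSegment], tmd_index: int, side: str
) -> int:
    """Net charge of the TMD's own interfacial zone on the given side."""
    zone = "cyt_interface" if side == INSIDE else "exo_interface"
    labels = zone_partition(record, segments, tmd_index)
    tmd = record.tmds[tmd_index - 1]
    return _net(a for a, z in zip(tmd.sequence, labels) if z == zone)


def combined_flank_charge(
    record: ProteinRecord,
    segments: list[LoopSegment],
    tmd_index: int,
    side: str,
    proportional: bool = True,
) -> float:
    """Interfacial-zone net charge (unscaled) plus the 10-residue flank."""
    fc = flank_net_charge(record, segments, tmd_index, side, 10, proportional)
    return interfacial_net_charge(record, segments, tmd_index, side) + fc.net


def pair_charge_bias(
    record: ProteinRecord,
    segments: list[LoopSegment],
    pair,
    proportional: bool = True,
) -> dict[str, float]:
    """Charge biases of a TMD pair treated as one unit.

    inside_bias sums the combined (interfacial + 10 aa flank) cytosolic
    charges of both TMDs; outside_bias is the net charge of the entire
    exoplasmic loop plus both exoplasmic interfacial zones, with no window
    truncation or scaling.
    """
    inside = sum(
        combined_flank_charge(record, segments, i, INSIDE, proportional)
        for i in (pair.first, pair.second)
    )
    loop_net = _net(pair.exo_loop.extract(record.sequence))
    outside = float(
        loop_net
        + interfacial_net_charge(record, segments, pair.first, OUTSIDE)
        + interfacial_net_charge(record, segments, pair.second, OUTSIDE)
    )
    return {"inside_bias": float(inside), "outside_bias": outside}


def charge_dot_map(
    records: Iterable[ProteinRecord],
    tmd_filter=None,
    subsample: Optional[int] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """One row per charged residue (K/R/D/E) in the selected TMDs, with its
    fractional depth from the exoplasmic end ((i − 0.5)/L over residue
    centers) and zone label.

    ``tmd_filter(record, tmd_index) -> bool`` selects TMDs; ``subsample``
    draws that many TMDs (not residues) reproducibly with ``seed``, matching
    the n-matched comparison panels.
    """
    selected: list[tuple[ProteinRecord, list[LoopSegment], int]] = []
    for rec in records:
        segs = segments_with_sides(rec)
        for tmd in rec.tmds:
            if tmd_filter is None or tmd_filter(rec, tmd.index):
                selected.append((rec, segs, tmd.index))
    if subsample is not None and subsample < len(selected):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(selected), size=subsample, replace=False)
        selected = [selected[i] for i in sorted(idx)]
    rows = []
    for rec, segs, ti in selected:
        tmd = rec.tmds[ti - 1]
        if tmd.length < 5:
            continue
        labels = zone_partition(rec, segs, ti)
        n_exo = tmd_orientation(rec, segs, ti) == OUTSIDE
        L = tmd.length
        for pos0, (aa, zone) in enumerate(zip(tmd.sequence, labels)):
            if aa not in CHARGED:
                continue
            from_exo = pos0 + 1 if n_exo else L - pos0
            rows.append(
                {
                    "tmd_id": f"{rec.accession}/TMD{ti}",
                    "residue": aa,
                    "depth": (from_exo - 0.5) / L,
                    "zone": zone,
                }
            )
    return pd.DataFrame(rows, columns=["tmd_id", "residue", "depth", "zone"])


def zone_charge_summary(
    records: Iterable[ProteinRecord], tmd_filter=None
) -> pd.DataFrame:
    """Per-zone positive:negative ratio and charge density (% of zone
    residues that are charged) over a TMD set."""
    totals = {z: 0 for z in ZONES}
    basic = {z: 0 for z in ZONES}
    acidic = {z: 0 for z in ZONES}
    for rec in records:
        segs = segments_with_sides(rec)
        for tmd in rec.tmds:
            if tmd_filter is not None and not tmd_filter(rec, tmd.index):
                continue
            if tmd.length < 5:
                continue
            labels = zone_partition(rec, segs, tmd.index)
            for aa, z in zip(tmd.sequence, labels):
                totals[z] += 1
                if aa in BASIC:
                    basic[z] += 1
                elif aa in ACIDIC:
                    acidic[z] += 1
    rows = []
    for z in ZONES:
        n = totals[z]
        charged = basic[z] + acidic[z]
        ratio = f"{basic[z]}:{acidic[z]}" if acidic[z] else f"{basic[z]}:0"
        rows.append(
            {
                "zone": z,
                "residues": n,
                "basic": basic[z],
                "acidic": acidic[z],
                "pos_neg_ratio": ratio,
                "charge_density_pct": 100.0 * charged / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def positive_inside_summary(
    table,
    labels_by_acc: dict,
    windows: tuple[int, ...] = DEFAULT_WINDOWS,
    proportional: bool = True,
) -> pd.DataFrame:
    """Mean net flanking charge per (stratum, side, window).

    Strata mirror the census analyses: all TMDs, SP/MP, TMD1 of SA proteins,
    downstream multipass TMDs, the three SA classes, and pair members. Empty
    strata are absent from the output, not reported as zero.
    """
    from .classify import NCYT_LONG_SA, NCYT_PAIR_SA, NEXO_SA, SP_CLASSES

    acc_rows: list[dict] = []
    for rec in table:
        labels = labels_by_acc[rec.accession]
        segs = segments_with_sides(rec)
        is_sp = labels.protein_class in SP_CLASSES
        paired = {p.first for p in labels.pairs} | {p.second for p in labels.pairs}
        for tmd in rec.tmds:
            strata = {"all", "SP" if is_sp else "MP"}
            if tmd.index == 1 and labels.sa_class is not None:
                strata.add("SA_TMD1")
                strata.add(f"SA:{labels.sa_class}")
            if not is_sp and tmd.index > 1:
                strata.add("MP_downstream")
            if tmd.index in paired:
                strata.add("pair_member")
            for side in (INSIDE, OUTSIDE):
                for w in windows:
                    fc = flank_net_charge(
                        rec, segs, tmd.index, side, w, proportional
                    )
                    for s in strata:
                        acc_rows.append(
                            {"stratum": s, "side": side, "window": w, "net": fc.net}
                        )
    if not acc_rows:
        return pd.DataFrame(columns=["stratum", "side", "window", "n", "mean_net"])
    df = pd.DataFrame(acc_rows)
    out = (
        df.groupby(["stratum", "side", "window"], sort=True)["net"]
        .agg(n="size", mean_net="mean")
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out
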