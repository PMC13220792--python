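"""Census-table reader/writer and FASTA input.

The canonical dialect is UTF-8 comma-separated text (tab accepted) with
columns: accession, gene_name, length, num_tmds, topology, n_terminus_side,
signal_start, signal_end, tmd_coords (semicolon-separated "start-end" pairs),
tmd_dg (semicolon-separated floats, optional), sequence. A tolerant reader
maps common column aliases and accepts per-TMD coordinate column pairs
(tmd1_start/tmd1_end, ...) instead of a coordinate string; every mapping and
rejected row is recorded in the parse report rather than silently dropped.
"""

from __future__ import annotations

import io as _io
import math
import re
from typing import IO, Iterable, Optional, Union

import pandas as pd
from Bio import SeqIO

from .records import (
    INSIDE,
    OUTSIDE,
    CensusTable,
    ParseReport,
    ProteinRecord,
    TmdSegment,
    deduce_segments,
    validate_record,
)

CANONICAL_COLUMNS = [
    "accession",
    "gene_name",
    "length",
    "num_tmds",
    "topology",
    "n_terminus_side",
    "signal_start",
    "signal_end",
    "tmd_coords",
    "tmd_dg",
    "sequence",
]

MANDATORY = {"accession", "sequence", "tmd_coords", "n_terminus_side"}

# alias -> canonical, keyed on lowercased alphanumeric-only names
_ALIASES = {
    "accession": "accession",
    "uniprot": "accession",
    "uniprotaccession": "accession",
    "acc": "accession",
    "id": "accession",
    "genename": "gene_name",
    "gene": "gene_name",
    "symbol": "gene_name",
    "length": "length",
    "proteinlength": "length",
    "numtmds": "num_tmds",
    "ntmds": "num_tmds",
    "numberoftmds": "num_tmds",
    "tmdcount": "num_tmds",
    "topology": "topology",
    "topologytype": "topology",
    "ntermside": "n_terminus_side",
    "nterminusside": "n_terminus_side",
    "nterminuslocation": "n_terminus_side",
    "orientation": "n_terminus_side",
    "signalstart": "signal_start",
    "signalend": "signal_end",
    "spstart": "signal_start",
    "spend": "signal_end",
    "tmdcoords": "tmd_coords",
    "tmdcoordinates": "tmd_coords",
    "tmdcoordinatestring": "tmd_coords",
    "tmddg": "tmd_dg",
    "tmddgapp": "tmd_dg",
    "dgapp": "tmd_dg",
    "sequence": "sequence",
    "fullsequence": "sequence",
    "seq": "sequence",
    "loopcoords": "loop_coords",
    "loopcoordinates": "loop_coords",
}

_SIDE_ALIASES = {
    "inside": INSIDE,
    "in": INSIDE,
    "cytosolic": INSIDE,
    "cyt": INSIDE,
    "ncyt": INSIDE,
    "n_cyt": INSIDE,
    "outside": OUTSIDE,
    "out": OUTSIDE,
    "exoplasmic": OUTSIDE,
    "exo": OUTSIDE,
    "lumenal": OUTSIDE,
    "nexo": OUTSIDE,
    "n_exo": OUTSIDE,
}

_REJECTED_LETTERS = set("BZUJO")


def _canon_col(name: str) -> Optional[str]:
    key = re.sub(r"[^a-z0-9]", "", str(name).lower())
    return _ALIASES.get(key)


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return str(value).strip() == ""


def _parse_coord_string(text: str) -> list[tuple[int, int]]:
    out = []
    for chunk in re.split(r"[;,]", str(text).strip()):
        chunk = chunk.strip()
        if not chunk:
            continue
        m = re.fullmatch(r"(\d+)\s*[-–]\s*(\d+)", chunk)
        if not m:
            raise ValueError(f"malformed coordinate span {chunk!r}")
        out.append((int(m.group(1)), int(m.group(2))))
    return out


def parse_census_table(
    source: Union[str, IO[str]], *, sep: Optional[str] = None
) -> CensusTable:
    """Read a census table from a path or text stream.

    Every well-formed row becomes a validated :class:`ProteinRecord`;
    malformed rows are reported in ``table.provenance`` with a reason.
    A missing mandatory column is a hard error naming the column.
    """
    name = source if isinstance(source, str) else getattr(source, "name", "<stream>")
    df = pd.read_csv(source, sep=sep, engine="python", dtype=str)
    report = ParseReport(source=str(name))

    mapping: dict[str, str] = {}
    for col in df.columns:
        canon = _canon_col(col)
        if canon is not None and canon not in mapping.values():
            mapping[col] = canon
    report.column_mapping = dict(mapping)
    df = df.rename(columns=mapping)

    # per-TMD coordinate column-pair dialect (tmd1_start, tmd1_end, ...)
    pair_cols = sorted(
        {
            int(m.group(1))
            for c in df.columns
            for m in [re.fullmatch(r"tmd(\d+)_start", str(c).lower())]
            if m
        }
    )
    if "tmd_coords" not in df.columns and pair_cols:
        def _join(row):
            spans = []
            for i in pair_cols:
                s, e = row.get(f"tmd{i}_start"), row.get(f"tmd{i}_end")
                if _is_missing(s) or _is_missing(e):
                    continue
                spans.append(f"{int(float(s))}-{int(float(e))}")
            return ";".join(spans)

        df["tmd_coords"] = df.apply(_join, axis=1)
        report.column_mapping["tmd1_start..tmdN_end"] = "tmd_coords"

    missing = MANDATORY - set(df.columns)
    if missing:
        raise ValueError(
            f"missing mandatory column(s): {', '.join(sorted(missing))}"
        )

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        report.rows_read += 1
        acc = str(row.get("accession", "")).strip()
        rowid = acc or f"row {idx + 2}"
        try:
            rec = _row_to_record(row)
        except ValueError as exc:
            report.rejected.append((rowid, str(exc)))
            continue
        violations = validate_record(rec)
        if violations:
            report.rejected.append(
                (rowid, "; ".join(str(v) for v in violations))
            )
            continue
        if rec.accession in seen:
            report.rejected.append((rowid, "duplicate accession"))
            continue
        if "loop_coords" in df.columns and not _is_missing(row.get("loop_coords")):
            mismatch = _crosscheck_loops(rec, str(row["loop_coords"]))
            if mismatch:
                report.loop_mismatches.append(f"{rowid}: {mismatch}")
        seen.add(rec.accession)
        records.append(rec)
        report.rows_accepted += 1
    return CensusTable(records=records, provenance=report)


def _row_to_record(row: pd.Series) -> ProteinRecord:
    acc = str(row["accession"]).strip()
    if not acc:
        raise ValueError("empty accession")
    seq = str(row["sequence"]).strip().upper()
    if not seq or seq == "NAN":
        raise ValueError("empty sequence")
    bad = set(seq) & _REJECTED_LETTERS
    if bad:
        raise ValueError(f"nonstandard residue(s) {sorted(bad)} rejected")

    side_raw = str(row["n_terminus_side"]).strip().lower()
    side = _SIDE_ALIASES.get(re.sub(r"[^a-z_]", "", side_raw))
    if side is None:
        raise ValueError(f"unrecognized n_terminus_side {row['n_terminus_side']!r}")

    sig = None
    s_raw, e_raw = row.get("signal_start"), row.get("signal_end")
    if not _is_missing(s_raw) and not _is_missing(e_raw):
        sig = (int(float(s_raw)), int(float(e_raw)))
        if side == INSIDE:
            raise ValueError(
                "signal peptide with n_terminus_side=inside is internally contradictory"
            )

    spans = _parse_coord_string(row["tmd_coords"])
    if not spans:
        raise ValueError("no TMD coordinates")
    for s, e in spans:
        if not (1 <= s <= e <= len(seq)):
            raise ValueError(f"TMD coordinate {s}-{e} outside sequence (1-{len(seq)})")

    dgs: list[Optional[float]] = [None] * len(spans)
    if not _is_missing(row.get("tmd_dg")):
        parts = [p.strip() for p in str(row["tmd_dg"]).split(";")]
        if len(parts) != len(spans):
            raise ValueError(
                f"tmd_dg lists {len(parts)} values for {len(spans)} TMDs"
            )
        dgs = [float(p) if p else None for p in parts]

    declared_len = row.get("length")
    length = len(seq) if _is_missing(declared_len) else int(float(declared_len))

    declared_n = row.get("num_tmds")
    if not _is_missing(declared_n) and int(float(declared_n)) != len(spans):
        raise ValueError(
            f"num_tmds={int(float(declared_n))} disagrees with "
            f"{len(spans)} coordinate spans"
        )

    tmds = [
        TmdSegment(index=i + 1, start=s, end=e, sequence=seq[s - 1 : e], dg_app=dg)
        for i, ((s, e), dg) in enumerate(zip(spans, dgs))
    ]
    gene = "" if _is_missing(row.get("gene_name")) else str(row["gene_name"]).strip()
    return ProteinRecord(
        accession=acc,
        gene_name=gene,
        length=length,
        sequence=seq,
        n_terminus_side=side,
        signal_peptide=sig,
        tmds=tmds,
    )


def _crosscheck_loops(rec: ProteinRecord, loop_coords: str) -> Optional[str]:
    """Loops are recomputed from TMDs; explicit loop columns are cross-checked
    and mismatches reported rather than trusted."""
    try:
        stated = _parse_coord_string(loop_coords)
    except ValueError as exc:
        return f"unparseable loop_coords ({exc})"
    deduced = [(s.start, s.end) for s in deduce_segments(rec)]
    if len(stated) != len(deduced):
        return f"{len(stated)} stated loops vs {len(deduced)} deduced"
    diffs = [i + 1 for i, (a, b) in enumerate(zip(stated, deduced)) if a != b]
    if diffs:
        return f"loop(s) {diffs} differ from deduced coordinates"
    return None


def write_census_table(table: CensusTable, target: Union[str, IO[str]]) -> None:
    """Emit the canonical comma dialect with a deterministic column order.

    The topology column is recomputed from the record, never copied through.
    """
    from .classify import classify_protein  # local import avoids a cycle
    from .records import segments_with_sides

    rows = []
    for rec in table:
        segs = segments_with_sides(rec)
        rows.append(
            {
                "accession": rec.accession,
                "gene_name": rec.gene_name,
                "length": rec.length,
                "num_tmds": rec.n_tmds,
                "topology": classify_protein(rec, segs),
                "n_terminus_side": rec.n_terminus_side,
                "signal_start": rec.signal_peptide[0] if rec.has_signal else "",
                "signal_end": rec.signal_peptide[1] if rec.has_signal else "",
                "tmd_coords": ";".join(f"{t.start}-{t.end}" for t in rec.tmds),
                "tmd_dg": ";".join(
                    "" if t.dg_app is None else format(t.dg_app, ".3f")
                    for t in rec.tmds
                )
                if any(t.dg_app is not None for t in rec.tmds)
                else "",
                "sequence": rec.sequence,
            }
        )
    df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    df.to_csv(target, index=False)


def read_fasta(source: Union[str, IO[str]]) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from standard FASTA, wrapped or not."""
    if isinstance(source, str):
        with open(source) as fh:
            return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(fh, "fasta")]
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(source, "fasta")]
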