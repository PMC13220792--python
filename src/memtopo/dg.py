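"""Position-dependent biological hydrophobicity scale (ΔG_app, kcal/mol).

The apparent free energy of translocon-mediated membrane insertion of a
candidate TMD of length L is

    ΔG_app = Σ_i ΔG_aa(pos_i) + c_mom · |Σ_i ΔG_i·e^(j·100°·i)| + ΔG_len(L)

where pos_i = 9·(2i/(L−1) − 1) maps the segment onto [−9, 9], each residue
contributes a Gaussian positional profile (W and Y carry an extra symmetric
two-Gaussian interface-preference term), the second term is a hydrophobic
moment at the α-helical periodicity of 100° per turn, and ΔG_len is a
quadratic length correction. Negative values favor insertion. The profile is
symmetric about the segment midpoint, which makes ΔG_app exactly invariant
under sequence reversal.

Coefficients ship as package data (``data/biological_hydrophobicity_scale.tsv``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np

from .records import CANONICAL_AA

_DATA_FILE = "biological_hydrophobicity_scale.tsv"

#: default window policy for minimal-ΔG scanning
DEFAULT_SCAN_RANGE = (19, 23)


class DgError(ValueError):
    """A segment cannot be scored (unsupported residue or length)."""


@dataclass(frozen=True)
class DgScale:
    """Coefficient set of the biological hydrophobicity scale."""

    profiles: dict[str, tuple[float, ...]]  # aa -> (a0, a1[, a2, a3, a4])
    moment_coef: float
    helix_angle_deg: float
    length_coefs: tuple[float, float, float]  # c0 + c1*L + c2*L^2
    min_len: int
    max_len: int
    provenance: str = ""

    def __post_init__(self):
        missing = CANONICAL_AA - set(self.profiles)
        if missing:
            raise ValueError(f"scale lacks residues {sorted(missing)}")

    def position_contribution(self, aa: str, pos: float) -> float:
        """ΔG contribution of one residue at normalized position pos ∈ [−9, 9]."""
        try:
            p = self.profiles[aa]
        except KeyError:
            raise DgError(f"residue {aa!r} is not scorable") from None
        dg = p[0] * math.exp(-p[1] * pos * pos)
        if len(p) == 5:
            a2, a3, a4 = p[2], p[3], p[4]
            dg += a2 * (
                math.exp(-a3 * (pos - a4) ** 2) + math.exp(-a3 * (pos + a4) ** 2)
            )
        return dg


def load_default_scale() -> DgScale:
    """Load the bundled full-model coefficient file."""
    text = (
        resources.files("memtopo.data").joinpath(_DATA_FILE).read_text(encoding="utf-8")
    )
    profiles: dict[str, tuple[float, ...]] = {}
    consts: dict[str, float] = {}
    provenance = ""
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "provenance:" in line:
                provenance = line.split("provenance:", 1)[1].strip()
            continue
        parts = line.split("\t")
        if parts[0] == "const":
            consts[parts[1]] = float(parts[2])
        elif parts[0] == "aa":
            profiles[parts[1]] = tuple(float(x) for x in parts[2:])
    return DgScale(
        profiles=profiles,
        moment_coef=consts["moment_coef"],
        helix_angle_deg=consts["helix_angle_deg"],
        length_coefs=(consts["len_c0"], consts["len_c1"], consts["len_c2"]),
        min_len=int(consts["min_len"]),
        max_len=int(consts["max_len"]),
        provenance=provenance,
    )


_default_scale: Optional[DgScale] = None
_vector_cache: dict[int, tuple] = {}


def default_scale() -> DgScale:
    global _default_scale
    if _default_scale is None:
        _default_scale = load_default_scale()
    return _default_scale


def _vectorized(scale: DgScale):
    """Per-residue coefficient arrays indexed by ord(aa) - ord('A')."""
    key = id(scale)
    cached = _vector_cache.get(key)
    if cached is not None:
        return cached
    a = np.zeros((5, 26))
    ok = np.zeros(26, dtype=bool)
    for aa, p in scale.profiles.items():
        i = ord(aa) - 65
        a[0, i], a[1, i] = p[0], p[1]
        if len(p) == 5:
            a[2, i], a[3, i], a[4, i] = p[2], p[3], p[4]
        ok[i] = True
    _vector_cache[key] = (a, ok)
    return a, ok


def _check_sequence(seq: str, scale: DgScale) -> np.ndarray:
    codes = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8) - 65
    _, ok = _vectorized(scale)
    invalid = (codes > 25) | ~ok[np.clip(codes, 0, 25)]
    if invalid.any():
        pos = int(np.argmax(invalid))
        raise DgError(
            f"unsupported residue {seq[pos]!r} at position {pos + 1}"
        )
    return codes


def _positional_contribs(codes: np.ndarray, scale: DgScale) -> np.ndarray:
    L = codes.size
    a, _ = _vectorized(scale)
    pos = 9.0 * (2.0 * np.arange(L) / (L - 1) - 1.0) if L > 1 else np.zeros(1)
    a0, a1, a2, a3, a4 = (a[k, codes] for k in range(5))
    dg = a0 * np.exp(-a1 * pos * pos)
    arom = a2 != 0
    if arom.any():
        dg[arom] += a2[arom] * (
            np.exp(-a3[arom] * (pos[arom] - a4[arom]) ** 2)
            + np.exp(-a3[arom] * (pos[arom] + a4[arom]) ** 2)
        )
    return dg


def dg_app(sequence: str, scale: Optional[DgScale] = None) -> float:
    """ΔG_app (kcal/mol) of a candidate TMD scored as a whole.

    Raises :class:`DgError` for unsupported residues (e.g. X) or lengths
    outside the scale's supported range.
    """
    scale = scale or default_scale()
    L = len(sequence)
    if not (scale.min_len <= L <= scale.max_len):
        raise DgError(
            f"segment length {L} outside supported range "
            f"[{scale.min_len}, {scale.max_len}]"
        )
    codes = _check_sequence(sequence, scale)
    dg = _positional_contribs(codes, scale)
    theta = np.deg2rad(scale.helix_angle_deg) * np.arange(L)
    moment = math.hypot(float(dg @ np.sin(theta)), float(dg @ np.cos(theta)))
    c0, c1, c2 = scale.length_coefs
    return float(dg.sum() + scale.moment_coef * moment + c0 + c1 * L + c2 * L * L)


@dataclass(frozen=True)
class DgResult:
    dg_app: float
    window_start: int  # 1-based, inclusive
    window_end: int
    @property
    def window_length(self) -> int:
        return self.window_end - self.window_start + 1


def dg_scan(
    sequence: str,
    length_range: tuple[int, int] = DEFAULT_SCAN_RANGE,
    scale: Optional[DgScale] = None,
) -> DgResult:
    """Minimal-ΔG window over all start positions and lengths in range.

    Ties break to the smallest start coordinate, then the smallest length.
    """
    scale = scale or default_scale()
    lmin, lmax = length_range
    if lmin > lmax:
        raise ValueError("empty length range")
    lmin = max(lmin, scale.min_len)
    lmax = min(lmax, scale.max_len)
    n = len(sequence)
    if n < lmin:
        raise DgError(f"sequence of {n} aa shorter than minimum window {lmin}")
    best: Optional[DgResult] = None
    for start in range(n - lmin + 1):  # start-major order implements the tie-break
        for L in range(lmin, min(lmax, n - start) + 1):
            val = dg_app(sequence[start : start + L], scale)
            if best is None or val < best.dg_app:
                best = DgResult(dg_app=val, window_start=start + 1, window_end=start + L)
    assert best is not None
    return best


def score_tmd(sequence: str, scale: Optional[DgScale] = None) -> float:
    """Score one recorded TMD: whole if ≤40 aa, else the minimal-ΔG window
    of the default scan range within the TMD span."""
    scale = scale or default_scale()
    if len(sequence) > scale.max_len:
        return dg_scan(sequence, DEFAULT_SCAN_RANGE, scale).dg_app
    return dg_app(sequence, scale)


@dataclass
class ScoreReport:
    scored: int = 0
    kept: int = 0
    errors: list[tuple[str, str]] = None  # (tmd id, reason)
    deltas: dict[str, float] = None  # tmd id -> recomputed - recorded

    def __post_init__(self):
        self.errors = self.errors or []
        self.deltas = self.deltas or {}


def score_all_tmds(table, scale: Optional[DgScale] = None, rescore: bool = False):
    """Fill ΔG_app for every TMD of a census table, in place.

    With ``rescore`` off, recorded values are kept and only missing ones are
    computed; with it on, all values are recomputed and per-TMD deltas against
    the previously recorded values reported. Scoring errors are collected in
    the report, never raised mid-run.
    """
    scale = scale or default_scale()
    report = ScoreReport()
    for rec in table:
        for tmd in rec.tmds:
            tid = f"{rec.accession}/TMD{tmd.index}"
            if tmd.dg_app is not None and not rescore:
                report.kept += 1
                continue
            try:
                value = score_tmd(tmd.sequence, scale)
            except DgError as exc:
                report.errors.append((tid, str(exc)))
                continue
            if rescore and tmd.dg_app is not None:
                report.deltas[tid] = value - tmd.dg_app
            tmd.dg_app = value
            report.scored += 1
    return report
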