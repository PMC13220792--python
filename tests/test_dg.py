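"""Biological hydrophobicity scale: oracles, invariants, and scanning."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import memtopo as mt
from memtopo.dg import DEFAULT_SCAN_RANGE, DgError, score_tmd

AA = "ACDEFGHIKLMNPQRSTVWY"

sequences = st.text(alphabet=AA, min_size=9, max_size=40)


def hand_dg(seq, scale=None):
    """Independent pure-Python oracle: direct sum over the coefficient table,
    computed with none of the implementation's vectorized machinery."""
    scale = scale or mt.default_scale()
    L = len(seq)
    contribs = []
    for i, aa in enumerate(seq):
        pos = 9.0 * (2.0 * i / (L - 1) - 1.0) if L > 1 else 0.0
        p = scale.profiles[aa]
        c = p[0] * math.exp(-p[1] * pos * pos)
        if len(p) == 5:
            c += p[2] * (
                math.exp(-p[3] * (pos - p[4]) ** 2)
                + math.exp(-p[3] * (pos + p[4]) ** 2)
            )
        contribs.append(c)
    sin_s = sum(c * math.sin(math.radians(100 * i)) for i, c in enumerate(contribs))
    cos_s = sum(c * math.cos(math.radians(100 * i)) for i, c in enumerate(contribs))
    c0, c1, c2 = scale.length_coefs
    return (
        sum(contribs)
        + scale.moment_coef * math.hypot(sin_s, cos_s)
        + c0
        + c1 * L
        + c2 * L * L
    )


def brute_force_scan(seq, lmin, lmax):
    """Exhaustive enumeration oracle with the documented tie-break."""
    best = None
    for start in range(len(seq) - lmin + 1):
        for L in range(lmin, min(lmax, len(seq) - start) + 1):
            val = mt.dg_app(seq[start : start + L])
            if best is None or val < best[0]:
                best = (val, start + 1, start + L)
    return best


class TestDgApp:
    def test_polyleucine_hand_oracle(self):
        """19-mer poly-Leu: frozen value from the independent hand calculation."""
        value = mt.dg_app("L" * 19)
        assert value == pytest.approx(-7.496562, abs=1e-4)
        assert value == pytest.approx(hand_dg("L" * 19), abs=1e-9)
        assert value < -2.0

    @given(seq=sequences)
    @settings(max_examples=60)
    def test_matches_independent_oracle(self, seq):
        assert mt.dg_app(seq) == pytest.approx(hand_dg(seq), abs=1e-9)

    @given(seq=sequences)
    @settings(max_examples=200)
    def test_reversal_invariance(self, seq):
        """Symmetric profile + moment magnitude make ΔG_app(S) == ΔG_app(rev S)."""
        assert mt.dg_app(seq) == pytest.approx(mt.dg_app(seq[::-1]), abs=1e-9)

    def test_unsupported_residue_names_position(self):
        with pytest.raises(DgError, match="position 4"):
            mt.dg_app("LLLXLLLLLLLLLLLLLLL")

    @pytest.mark.parametrize("length", [5, 8, 41, 60])
    def test_length_outside_supported_range_errors(self, length):
        with pytest.raises(DgError, match="supported range"):
            mt.dg_app("L" * length)

    @given(seq=st.text(alphabet=AA, min_size=19, max_size=30), data=st.data())
    @settings(max_examples=60)
    def test_hydrophobic_substitution(self, seq, data):
        """Replacing a residue whose positional contribution exceeds Leu's at
        that position never increases ΔG_app (moment coefficient < 1)."""
        i = data.draw(st.integers(0, len(seq) - 1))
        scale = mt.default_scale()
        L = len(seq)
        pos = 9.0 * (2.0 * i / (L - 1) - 1.0)
        if scale.position_contribution(seq[i], pos) <= scale.position_contribution("L", pos):
            return
        mutated = seq[:i] + "L" + seq[i + 1 :]
        assert mt.dg_app(mutated) <= mt.dg_app(seq) + 1e-9


class TestDgScan:
    def test_single_candidate_window(self):
        seq = "LILFVAGSTCLILFVAGST"  # exactly 19 aa
        res = mt.dg_scan(seq, (19, 19))
        assert (res.window_start, res.window_end) == (1, 19)
        assert res.dg_app == pytest.approx(mt.dg_app(seq))

    @pytest.mark.parametrize("seed", range(12))
    def test_equals_brute_force_enumeration(self, seed):
        import random

        rng = random.Random(seed)
        seq = "".join(rng.choice(AA) for _ in range(rng.randint(40, 120)))
        res = mt.dg_scan(seq, (19, 23))
        val, s, e = brute_force_scan(seq, 19, 23)
        assert (res.window_start, res.window_end) == (s, e)
        assert res.dg_app == pytest.approx(val)

    def test_hydrophobic_block_found(self):
        seq = "S" * 30 + "L" * 19 + "S" * 30
        res = mt.dg_scan(seq, (19, 23))
        val, s, e = brute_force_scan(seq, 19, 23)
        assert (res.window_start, res.window_end) == (s, e)
        # the minimal window must cover the poly-L block's core
        assert res.window_start <= 31 + 2 and res.window_end >= 49 - 2

    def test_monotone_under_extension(self):
        """Appending residues never raises the scan minimum."""
        import random

        rng = random.Random(5)
        seq = "".join(rng.choice(AA) for _ in range(60))
        base = mt.dg_scan(seq, DEFAULT_SCAN_RANGE).dg_app
        extended = mt.dg_scan(seq + "KKDDE", DEFAULT_SCAN_RANGE).dg_app
        assert extended <= base + 1e-9

    def test_too_short_sequence_errors(self):
        with pytest.raises(DgError, match="shorter"):
            mt.dg_scan("LLLL", (19, 23))

    def test_tie_break_smallest_start_then_length(self):
        # a homopolymer has massive ties: the first (start, length) must win
        res = mt.dg_scan("L" * 40, (19, 19))
        assert res.window_start == 1


class TestScoreAllTmds:
    def test_recorded_values_kept_without_rescore(self, small_proteome):
        import copy

        table = mt.CensusTable(records=[copy.deepcopy(small_proteome.table.records[0])])
        rec = table.records[0]
        for t in rec.tmds:
            t.dg_app = 1.234
        report = mt.score_all_tmds(table, rescore=False)
        assert report.scored == 0 and report.kept == rec.n_tmds
        assert all(t.dg_app == 1.234 for t in rec.tmds)

    def test_missing_values_computed_by_delegation(self, small_proteome):
        import copy

        rec = copy.deepcopy(small_proteome.table.records[1])
        table = mt.CensusTable(records=[rec])
        for t in rec.tmds:
            t.dg_app = None
        mt.score_all_tmds(table)
        for t in rec.tmds:
            assert t.dg_app == pytest.approx(score_tmd(t.sequence))

    def test_rescore_self_consistency(self, small_proteome):
        """Recomputing over a generated table must match dg_app exactly."""
        import copy

        recs = copy.deepcopy(small_proteome.table.records[:40])
        table = mt.CensusTable(records=recs)
        mt.score_all_tmds(table)
        report = mt.score_all_tmds(table, rescore=True)
        assert report.deltas and max(abs(d) for d in report.deltas.values()) == 0.0

    def test_scoring_errors_collected_not_raised(self):
        seq = "G" * 10 + "LLLLLLLLLXLLLLLLLLLL" + "G" * 10
        rec = mt.ProteinRecord(
            accession="XERR",
            gene_name="x",
            length=len(seq),
            sequence=seq,
            n_terminus_side=mt.INSIDE,
            tmds=[mt.TmdSegment(1, 11, 30, seq[10:30])],
        )
        report = mt.score_all_tmds(mt.CensusTable(records=[rec]))
        assert report.errors and "XERR/TMD1" in report.errors[0][0]

    def test_long_tmd_scored_by_internal_scan(self):
        seq = "G" * 5 + "L" * 45 + "G" * 5
        rec = mt.ProteinRecord(
            accession="LONG",
            gene_name="x",
            length=len(seq),
            sequence=seq,
            n_terminus_side=mt.INSIDE,
            tmds=[mt.TmdSegment(1, 6, 50, seq[5:50])],
        )
        mt.score_all_tmds(mt.CensusTable(records=[rec]))
        expected = mt.dg_scan("L" * 45, DEFAULT_SCAN_RANGE).dg_app
        assert rec.tmds[0].dg_app == pytest.approx(expected)
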