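"""Zone partitioning, charge depth maps, and flanking charge windows."""

import numpy as np
import pytest

import memtopo as mt
from memtopo.charges import (
    interfacial_net_charge,
    tmd_orientation,
    zone_charge_summary,
)
from conftest import make_record


def _single_tmd_record(n_tail_seq, tmd_seq, c_tail_seq, n_side=mt.INSIDE, acc="CH1"):
    seq = n_tail_seq + tmd_seq + c_tail_seq
    start = len(n_tail_seq) + 1
    end = start + len(tmd_seq) - 1
    return mt.ProteinRecord(
        accession=acc,
        gene_name="c",
        length=len(seq),
        sequence=seq,
        n_terminus_side=n_side,
        tmds=[mt.TmdSegment(1, start, end, tmd_seq)],
    )


class TestZonePartition:
    def test_20aa_exact_fractions(self):
        assert mt.zone_sizes(20) == (4, 3, 6, 3, 4)

    def test_23aa_cumulative_half_up_rounding(self):
        assert mt.zone_sizes(23) == (5, 3, 7, 3, 5)

    @pytest.mark.parametrize("L", range(5, 41))
    def test_sizes_always_tile(self, L):
        assert sum(mt.zone_sizes(L)) == L

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="too short"):
            mt.zone_sizes(4)

    def test_orientation_flips_zone_order(self):
        # N_cyt single TMD: N tail inside, so the TMD's N end is cytosolic
        rec = make_record(n_side=mt.INSIDE, tmd_len=20)
        segs = mt.segments_with_sides(rec)
        labels = mt.zone_partition(rec, segs, 1)
        assert labels[0] == "cyt_interface" and labels[-1] == "exo_interface"
        rec2 = make_record(n_side=mt.OUTSIDE, tmd_len=20)
        segs2 = mt.segments_with_sides(rec2)
        labels2 = mt.zone_partition(rec2, segs2, 1)
        assert labels2[0] == "exo_interface" and labels2[-1] == "cyt_interface"


class TestChargeDotMap:
    def test_uncharged_tmd_has_no_entries(self):
        rec = make_record(tmd_aa="L")
        assert len(mt.charge_dot_map([rec])) == 0

    def test_depth_of_k_near_exoplasmic_end(self):
        # 20-aa TMD, K at position 2 from the exoplasmic end: depth (2-0.5)/20
        tmd = "LKLLLLLLLLLLLLLLLLLL"  # K at position 2 from the N end
        rec = _single_tmd_record("G" * 10, tmd, "G" * 10, n_side=mt.OUTSIDE)
        dots = mt.charge_dot_map([rec])
        assert len(dots) == 1
        assert dots.depth.iloc[0] == pytest.approx(0.075)
        assert dots.zone.iloc[0] == "exo_interface"

    def test_subsample_reproducible_and_sized(self, small_proteome):
        recs = small_proteome.table.records[:80]
        a = mt.charge_dot_map(recs, subsample=40, seed=3)
        b = mt.charge_dot_map(recs, subsample=40, seed=3)
        assert a.equals(b)
        assert a.tmd_id.nunique() <= 40

    def test_conservation_of_charge_counts(self, small_proteome):
        """Zone-resolved entries sum to each TMD's total K/R/D/E count."""
        recs = small_proteome.table.records[:60]
        dots = mt.charge_dot_map(recs)
        by_tmd = dots.groupby("tmd_id").size()
        for rec in recs:
            for tmd in rec.tmds:
                if tmd.length < 5:
                    continue
                expected = sum(1 for a in tmd.sequence if a in "KRDE")
                got = int(by_tmd.get(f"{rec.accession}/TMD{tmd.index}", 0))
                assert got == expected


class TestZoneChargeSummary:
    def test_balanced_core_gives_unit_ratio_and_density(self):
        tmd = "LLLLLLKLLLLLLELLLLLL"  # 20 aa; K at 7, E at 14 are both core
        rec = _single_tmd_record("G" * 10, tmd, "G" * 10)
        out = zone_charge_summary([rec])
        core = out[out.zone.isin(["core_outer", "core_center", "core_inner"])]
        assert int(core.basic.sum()) == 1 and int(core.acidic.sum()) == 1
        assert (out.charge_density_pct.dropna() <= 100).all()

    def test_zero_acidic_reported_as_pos_to_zero(self):
        tmd = "LLLLLLLLLKLLLLLLLLLL"
        rec = _single_tmd_record("G" * 10, tmd, "G" * 10)
        out = zone_charge_summary([rec])
        row = out[out.zone == "core_center"].iloc[0]
        assert row.pos_neg_ratio == "1:0"


class TestFlankNetCharge:
    def test_uncharged_flank_is_zero(self):
        rec = _single_tmd_record("GASGG", "L" * 21, "GASGG")
        segs = mt.segments_with_sides(rec)
        assert mt.flank_net_charge(rec, segs, 1, mt.INSIDE, 5).net == 0.0

    def test_two_basic_residues(self):
        # inside flank (N tail, N_cyt): nearest-to-TMD residues counted first
        rec = _single_tmd_record("GRKAS"[::-1], "L" * 21, "GGGGG")
        segs = mt.segments_with_sides(rec)
        fc = mt.flank_net_charge(rec, segs, 1, mt.INSIDE, 5)
        assert fc.net == 2.0 and not fc.scaled

    def test_proportional_scaling_of_short_flank(self):
        rec = _single_tmd_record("KR", "L" * 21, "G" * 30)
        segs = mt.segments_with_sides(rec)
        fc = mt.flank_net_charge(rec, segs, 1, mt.INSIDE, 10)
        assert fc.net == pytest.approx(2 * 10 / 2)
        assert fc.scaled
        raw = mt.flank_net_charge(rec, segs, 1, mt.INSIDE, 10, proportional=False)
        assert raw.net == 2.0 and raw.scaled

    def test_empty_flank_contributes_zero(self):
        rec = make_record(tail_n=0)
        segs = mt.segments_with_sides(rec)
        fc = mt.flank_net_charge(rec, segs, 1, mt.INSIDE, 10)
        assert fc.net == 0.0 and fc.flank_length == 0

    def test_scaling_never_changes_sign(self, small_proteome):
        for rec in small_proteome.table.records[:50]:
            segs = mt.segments_with_sides(rec)
            for tmd in rec.tmds:
                for side in (mt.INSIDE, mt.OUTSIDE):
                    scaled = mt.flank_net_charge(rec, segs, tmd.index, side, 15)
                    raw = mt.flank_net_charge(
                        rec, segs, tmd.index, side, 15, proportional=False
                    )
                    assert np.sign(scaled.net) == np.sign(raw.net)

    def test_window_stops_at_neighboring_tmd(self):
        # internal loop of 4 aa between two TMDs: flank is those 4 aa only
        rec = make_record(n_tmds=2, n_side=mt.INSIDE, loops=[4], loop_aa="K")
        segs = mt.segments_with_sides(rec)
        fc = mt.flank_net_charge(rec, segs, 1, mt.OUTSIDE, 10, proportional=False)
        assert fc.flank_length == 4 and fc.net == 4.0

    def test_invalid_side_errors(self):
        rec = make_record()
        segs = mt.segments_with_sides(rec)
        with pytest.raises(ValueError, match="invalid side"):
            mt.flank_net_charge(rec, segs, 1, "up", 5)


class TestCombinedFlankCharge:
    def test_no_charges_is_zero(self):
        rec = make_record()
        segs = mt.segments_with_sides(rec)
        assert mt.combined_flank_charge(rec, segs, 1, mt.INSIDE) == 0.0

    def test_interfacial_and_flank_cancel(self):
        # N_cyt: cytosolic interface = last 4 of 20-aa TMD; R there, D in flank
        tmd = "L" * 16 + "RLLL"
        rec = _single_tmd_record("G" * 20, tmd, "GDGGGGGGGGGG", n_side=mt.OUTSIDE)
        segs = mt.segments_with_sides(rec)
        assert interfacial_net_charge(rec, segs, 1, mt.INSIDE) == 1
        assert mt.combined_flank_charge(rec, segs, 1, mt.INSIDE) == 0.0

    def test_reduces_to_flank_when_interface_uncharged(self):
        rec = _single_tmd_record("G" * 5 + "KKRGG", "L" * 21, "G" * 20)
        segs = mt.segments_with_sides(rec)
        fc = mt.flank_net_charge(rec, segs, 1, mt.INSIDE, 10)
        assert mt.combined_flank_charge(rec, segs, 1, mt.INSIDE) == fc.net

    def test_antisymmetry_under_orientation_flip(self, small_proteome):
        """Flipping a record's orientation swaps inside/outside biases."""
        for rec in small_proteome.table.records[:25]:
            if rec.has_signal:
                continue  # a signal pins the orientation
            import copy

            flipped = copy.deepcopy(rec)
            flipped.n_terminus_side = mt.opposite(rec.n_terminus_side)
            segs = mt.segments_with_sides(rec)
            fsegs = mt.segments_with_sides(flipped)
            for tmd in rec.tmds:
                a_in = mt.combined_flank_charge(rec, segs, tmd.index, mt.INSIDE)
                a_out = mt.combined_flank_charge(rec, segs, tmd.index, mt.OUTSIDE)
                b_in = mt.combined_flank_charge(flipped, fsegs, tmd.index, mt.INSIDE)
                b_out = mt.combined_flank_charge(flipped, fsegs, tmd.index, mt.OUTSIDE)
                assert a_in == pytest.approx(b_out)
                assert a_out == pytest.approx(b_in)


class TestPairChargeBias:
    def _paired_record(self, loop_seq):
        tmd = "L" * 20
        seq = "G" * 20 + tmd + loop_seq + tmd + "G" * 20
        s1 = 21
        e1 = 40
        s2 = e1 + len(loop_seq) + 1
        return mt.ProteinRecord(
            accession="PR1",
            gene_name="p",
            length=len(seq),
            sequence=seq,
            n_terminus_side=mt.INSIDE,
            tmds=[
                mt.TmdSegment(1, s1, e1, tmd),
                mt.TmdSegment(2, s2, s2 + 19, tmd),
            ],
        )

    def test_uncharged_pair_is_zero(self):
        rec = self._paired_record("GGGG")
        segs = mt.segments_with_sides(rec)
        labels = mt.label_protein(rec, segs)
        bias = mt.pair_charge_bias(rec, segs, labels.pairs[0])
        assert bias == {"inside_bias": 0.0, "outside_bias": 0.0}

    def test_acidic_loop_counts_toward_outside_bias(self):
        rec = self._paired_record("NDTE")
        segs = mt.segments_with_sides(rec)
        labels = mt.label_protein(rec, segs)
        bias = mt.pair_charge_bias(rec, segs, labels.pairs[0])
        assert bias["outside_bias"] == -2.0

    def test_inside_bias_is_sum_of_member_combined_charges(self, small_proteome):
        for rec in small_proteome.table.records[:30]:
            segs = mt.segments_with_sides(rec)
            labels = mt.label_protein(rec, segs)
            for p in labels.pairs:
                bias = mt.pair_charge_bias(rec, segs, p)
                expected = sum(
                    mt.combined_flank_charge(rec, segs, i, mt.INSIDE)
                    for i in (p.first, p.second)
                )
                assert bias["inside_bias"] == pytest.approx(expected)


class TestPositiveInsideSummary:
    def test_single_element_stratum_mean(self):
        rec = _single_tmd_record("GASGG" + "GRKAS"[::-1], "L" * 21, "G" * 20)
        table = mt.CensusTable(records=[rec])
        labels = {rec.accession: mt.label_protein(rec)}
        out = mt.positive_inside_summary(table, labels, windows=(5,))
        row = out[(out.stratum == "SP") & (out.side == mt.INSIDE) & (out.window == 5)]
        assert row.mean_net.iloc[0] == pytest.approx(2.0)
        assert int(row.n.iloc[0]) == 1

    def test_empty_strata_absent_not_zero(self):
        rec = make_record(n_side=mt.INSIDE, tail_c=30)  # a TA protein: no SA
        table = mt.CensusTable(records=[rec])
        labels = {rec.accession: mt.label_protein(rec)}
        out = mt.positive_inside_summary(table, labels)
        assert "MP" not in set(out.stratum)
        assert not any(out.stratum.str.startswith("SA:"))
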