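"""Splice-region anatomy: HGVS parsing, region taxonomy, mechanism, frame arithmetic."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cardiosplice.anatomy import (
    FrameConsequence,
    HgvsParseError,
    Mechanism,
    Region,
    analyse_variant,
    classify_region,
    frame_consequence,
    in_frame_amino_acids,
    infer_mechanism,
    parse_hgvs_offset,
)
from cardiosplice.models import (
    DataError,
    FunctionalOutcome,
    OutcomeKind,
    SpliceScores,
)


class TestHgvsParsing:
    @pytest.mark.parametrize(
        "hgvs,pos,offset,edit",
        [
            ("c.477+5G>A", 477, 5, "G>A"),
            ("c.1224-80G>A", 1224, -80, "G>A"),
            ("c.100G>A", 100, 0, "G>A"),
            ("c.848+1G>A", 848, 1, "G>A"),
            ("c.477+5 G > A", 477, 5, "G>A"),  # whitespace tolerated
            ("c.601-1G>A", 601, -1, "G>A"),
            ("c.300del", 300, 0, "del"),
            ("c.300dupA", 300, 0, "dupA"),
            ("c.300_302del", 300, 0, "del"),
            ("c.*12G>A", 12, 0, "G>A"),
        ],
    )
    def test_examples(self, hgvs, pos, offset, edit):
        parsed = parse_hgvs_offset(hgvs)
        assert (parsed.coding_pos, parsed.intron_offset, parsed.edit) == (
            pos,
            offset,
            edit,
        )

    def test_range_uses_most_splice_proximal_nucleotide(self):
        # a deletion spanning into the intron is placed at its boundary-nearest base
        parsed = parse_hgvs_offset("c.477+3_477+6del")
        assert parsed.intron_offset == 3
        parsed = parse_hgvs_offset("c.1458-9_1458-7del")
        assert parsed.intron_offset == -7

    @pytest.mark.parametrize("bad", ["p.Arg100Ter", "c.?", "g.123A>T", "", "c.12x>y"])
    def test_unparseable_raises(self, bad):
        with pytest.raises(HgvsParseError):
            parse_hgvs_offset(bad)

    def test_unparseable_is_flagged_not_skipped(self):
        anatomy = analyse_variant("not-hgvs-at-all")
        assert not anatomy.parse_ok


class TestRegionClassification:
    @pytest.mark.parametrize(
        "offset,region,essential",
        [
            (1, Region.donor_site, True),
            (2, Region.donor_site, True),
            (5, Region.donor_site, False),
            (6, Region.donor_site, False),
            (7, Region.deep_intronic, False),
            (-1, Region.acceptor_site, True),
            (-2, Region.acceptor_site, True),
            (-7, Region.acceptor_site, False),
            (-20, Region.acceptor_site, False),
            (-21, Region.deep_intronic, False),
            (-80, Region.deep_intronic, False),
        ],
    )
    def test_intronic_windows(self, offset, region, essential):
        anatomy = classify_region(offset)
        assert anatomy.region is region
        assert anatomy.essential_dinucleotide is essential

    @pytest.mark.parametrize(
        "ebd,region,edge",
        [
            (-1, Region.donor_site, True),    # last nucleotide of an exon
            (-3, Region.donor_site, False),
            (1, Region.acceptor_site, True),  # first nucleotide of an exon
            (3, Region.acceptor_site, False),
            (-4, Region.exonic_other, False),
            (4, Region.exonic_other, False),
            (None, Region.exonic_other, False),
        ],
    )
    def test_exonic_positions(self, ebd, region, edge):
        anatomy = classify_region(0, exon_boundary_distance=ebd)
        assert anatomy.region is region
        assert anatomy.exon_edge is edge
        assert not anatomy.essential_dinucleotide

    @given(
        offset=st.integers(min_value=-400, max_value=400),
        ebd=st.one_of(st.none(), st.integers(min_value=-30, max_value=30)),
    )
    def test_partition(self, offset, ebd):
        """Every parsed variant maps to exactly one region."""
        if ebd == 0:
            ebd = None
        anatomy = classify_region(offset, exon_boundary_distance=ebd)
        assert anatomy.region in list(Region)
        if anatomy.essential_dinucleotide:
            assert anatomy.region in (Region.donor_site, Region.acceptor_site)
        if anatomy.region is Region.deep_intronic:
            assert anatomy.offset > 6 or anatomy.offset < -20

    def test_demo_variants_map_to_expected_regions(self, demo_variants):
        expected = {
            "014": Region.donor_site,
            "015": Region.acceptor_site,  # first nucleotide of an exon
            "051": Region.deep_intronic,
            "054": Region.acceptor_site,
            "102": Region.donor_site,
            "125": Region.donor_site,  # last nucleotide of an exon
        }
        for dv in demo_variants:
            obs = dv.observation
            anatomy = analyse_variant(
                obs.hgvs_c, obs.scores, obs.exon_boundary_distance
            )
            assert anatomy.region is expected[dv.family], dv.family


class TestMechanism:
    def test_deep_intronic_new_site(self):
        anatomy = classify_region(-80)
        scores = SpliceScores(mes_delta=7.96, spliceai=0.94)
        assert infer_mechanism(anatomy, scores) is Mechanism.site_gain

    def test_essential_donor_is_site_loss(self):
        anatomy = classify_region(1)
        assert infer_mechanism(anatomy, SpliceScores()) is Mechanism.site_loss

    def test_exonic_without_gain_signal_is_ambiguous(self):
        anatomy = classify_region(0)
        assert infer_mechanism(anatomy, SpliceScores()) is Mechanism.ambiguous


class TestFrameArithmetic:
    @pytest.mark.parametrize(
        "kind,length,expected",
        [
            (OutcomeKind.exon_skip, 91, FrameConsequence.frameshift_ptc),
            (OutcomeKind.exon_skip, 75, FrameConsequence.in_frame_change),
            (OutcomeKind.new_exon_inclusion, 78, FrameConsequence.in_frame_change),
            (OutcomeKind.exon_extension, 78, FrameConsequence.in_frame_change),
            (OutcomeKind.exon_extension, 5, FrameConsequence.frameshift_ptc),
            (OutcomeKind.exon_skip, 141, FrameConsequence.in_frame_change),
            (OutcomeKind.exon_skip, 0, FrameConsequence.none),
        ],
    )
    def test_examples(self, kind, length, expected):
        outcome = FunctionalOutcome(kind, affected_length_nt=length)
        assert frame_consequence(outcome) is expected

    def test_intron_retention_defaults_to_ptc(self):
        assert (
            frame_consequence(FunctionalOutcome(OutcomeKind.intron_retention))
            is FrameConsequence.frameshift_ptc
        )
        # a multiple-of-3 retention is in-frame only when the caller asserts it
        retained = FunctionalOutcome(OutcomeKind.intron_retention, affected_length_nt=90)
        assert frame_consequence(retained) is FrameConsequence.frameshift_ptc
        assert (
            frame_consequence(retained, allow_in_frame_retention=True)
            is FrameConsequence.in_frame_change
        )

    def test_no_change_and_non_splicing_outcomes(self):
        for kind in (
            OutcomeKind.no_change,
            OutcomeKind.impaired_protein_function,
            OutcomeKind.unreported_consequence,
            OutcomeKind.inconsistent,
        ):
            assert frame_consequence(FunctionalOutcome(kind)) is FrameConsequence.none

    def test_missing_length_is_an_error(self):
        with pytest.raises(DataError):
            frame_consequence(FunctionalOutcome(OutcomeKind.exon_skip))

    @given(st.integers(min_value=1, max_value=600))
    def test_period_three(self, k):
        """In-frame vs frameshift alternates with period 3 in the length."""
        a = frame_consequence(FunctionalOutcome(OutcomeKind.exon_skip, k))
        b = frame_consequence(FunctionalOutcome(OutcomeKind.exon_skip, k + 3))
        assert a is b

    def test_amino_acid_arithmetic(self):
        assert in_frame_amino_acids(75) == 25
        assert in_frame_amino_acids(78) == 26
        assert in_frame_amino_acids(141) == 47
        with pytest.raises(DataError):
            in_frame_amino_acids(91)
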