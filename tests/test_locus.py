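"""Transcript coordinate system: g. <-> c. mapping and region annotation."""

import pytest

from haplotile.locus import CoordinateError, c_to_g, g_to_c


def test_transcript_shape(locus):
    t = locus.transcript
    assert len(t.exons) == 15
    assert t.exon_index(t.cds_start) == 2  # translation start in exon 3
    assert t.coding_length() == 1416


@pytest.mark.parametrize(
    "cstr, expected_offset",
    [
        ("c.1", 0),                 # definition of c.1
        ("c.-132", -132),           # 5'UTR inside the start exon
        ("c.1-15966", -15966),      # linear upstream convention
    ],
)
def test_anchor_coordinates(locus, cstr, expected_offset):
    t = locus.transcript
    pos = t.cds_start + expected_offset
    assert g_to_c(pos, t) == cstr
    assert c_to_g(cstr, t) == pos


def test_intronic_offset_anchors(locus):
    t = locus.transcript
    exon3_end = t.exons[2][1]
    assert c_to_g("c.120+3887", t) == exon3_end + 3887
    assert g_to_c(exon3_end + 3887, t) == "c.120+3887"
    # acceptor-side offset
    exon6_start = t.exons[5][0]
    assert g_to_c(exon6_start - 1, t) == "c.430-1"
    assert c_to_g("c.430-2", t) == exon6_start - 2


def test_round_trip_over_locus(locus):
    """g_to_c and c_to_g are mutual inverses across the whole locus."""
    t = locus.transcript
    for pos in range(1, locus.reference.length + 1, 7):
        assert c_to_g(g_to_c(pos, t), t) == pos


def test_region_labels_and_boundaries(locus):
    t = locus.transcript
    assert t.region_label(c_to_g("c.220", t)) == "exon 4"
    assert t.region_label(c_to_g("c.-132", t)) == "5'UTR"
    assert t.region_label(c_to_g("c.609+7", t)) == "intron 6"
    assert t.boundary_distance(c_to_g("c.609+7", t)) == 7
    assert t.boundary_distance(c_to_g("c.1156", t)) == 0
    assert t.region_label(25_000) == "intron 1"


def test_out_of_range_positions_raise(locus):
    t = locus.transcript
    with pytest.raises(CoordinateError):
        g_to_c(0, t)
    with pytest.raises(CoordinateError):
        g_to_c(locus.reference.length + 1, t, locus_length=locus.reference.length)
    with pytest.raises(CoordinateError):
        c_to_g("c.banana", t)
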