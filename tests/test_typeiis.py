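"""Type IIS registry geometry, site finding, digestion and virtual gels."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import linkforge as lf


@pytest.mark.parametrize(
    "name,overhang_len,polarity",
    [
        ("BtsI", 2, "three_prime"),
        ("BsrDI", 2, "three_prime"),
        ("SapI", 3, "five_prime"),
        ("BspQI", 3, "five_prime"),  # SapI isoschizomer
        ("BsaI", 4, "five_prime"),
        ("BbsI", 4, "five_prime"),
        ("BsmBI", 4, "five_prime"),
    ],
)
def test_registry_geometry(name, overhang_len, polarity):
    e = lf.get_enzyme(name)
    assert e.overhang_length == overhang_len
    assert e.polarity == polarity


def test_registry_unknown_enzyme():
    with pytest.raises(lf.IngestError):
        lf.get_enzyme("EcoRI")


class TestFindSites:
    def test_btsi_plus_strand_coordinates(self):
        m = lf.DnaMolecule("m", "AAAGCAGTGCATTTTTTTT", "linear")
        (site,) = lf.find_sites(m, lf.get_enzyme("BtsI"))
        assert (site.strand, site.recognition_start, site.recognition_end) == ("plus", 3, 9)
        assert (site.scissile_top, site.scissile_bottom) == (11, 9)

    def test_sapi_plus_strand_coordinates(self):
        m = lf.DnaMolecule("m", "AAGCTCTTCTATGCCCGGG", "linear")
        (site,) = lf.find_sites(m, lf.get_enzyme("SapI"))
        assert (site.scissile_top, site.scissile_bottom) == (10, 13)

    def test_no_recognition_no_sites(self):
        m = lf.DnaMolecule("m", "AAAAAA", "linear")
        for e in lf.registry():
            assert lf.find_sites(m, e) == []

    def test_noncleavable_site_near_linear_end(self):
        # recognition present but the cut would fall past the molecule end
        m = lf.DnaMolecule("m", "AAAGCAGTGC", "linear")
        (site,) = lf.find_sites(m, lf.get_enzyme("BtsI"))
        assert not site.cleavable
        frags = lf.digest(m, ["BtsI"])
        assert len(frags) == 1 and frags[0].id.endswith("|uncut")

    def test_origin_spanning_site_on_circular(self):
        seq = "GTGCATTTTTTTTAAAGCA"  # GCAGTG wraps the origin
        m = lf.DnaMolecule("m", seq, "circular")
        (site,) = lf.find_sites(m, lf.get_enzyme("BtsI"))
        assert site.recognition_start == 16

    def test_minus_strand_mirror_property(self, cfg):
        seq = "AAGCTCTTCTATGCCCGGGAT"
        fwd = lf.DnaMolecule("f", seq, "linear")
        rev = lf.DnaMolecule("r", lf.revcomp(seq), "linear")
        e = lf.get_enzyme("SapI")
        (sf,) = lf.find_sites(fwd, e)
        (sr,) = lf.find_sites(rev, e)
        n = len(seq)
        assert sr.strand == "minus"
        assert sr.recognition_start == n - sf.recognition_end
        assert sr.scissile_top == n - sf.scissile_bottom
        assert sr.scissile_bottom == n - sf.scissile_top


class TestDigest:
    def test_btsi_linear_fragments(self):
        m = lf.DnaMolecule("m", "AAAGCAGTGCATTTTTTTT", "linear")
        left, right = lf.digest(m, ["BtsI"])
        assert left.sequence == "AAAGCAGTGCA"
        assert (left.right_end.polarity, left.right_end.overhang) == ("three_prime", "CA")
        assert (right.left_end.polarity, right.left_end.overhang) == ("three_prime", "TG")
        # duplex portion of the right fragment begins after the overhang region
        assert right.sequence[len(right.left_end):].startswith("TTTT")
        assert lf.ends_compatible(left.right_end, right.left_end)

    def test_single_cut_circular_conserves_length(self, cfg):
        pz = lf.build_reference_pz(marker="resA", config=cfg)
        (frag,) = lf.digest(pz, ["SapI"])
        assert frag.footprint == len(pz)
        assert frag.left_end.polarity == frag.right_end.polarity == "five_prime"
        assert len(frag.left_end) == len(frag.right_end) == 3

    def test_two_cut_circular_conservation(self, cfg):
        pz = lf.build_reference_pz(marker="resA", config=cfg)
        frags = lf.digest(pz, ["SapI", "BsaI"])
        assert len(frags) == 2
        assert sum(f.footprint for f in frags) == len(pz)

    def test_uncut_circular_returned_intact(self):
        m = lf.DnaMolecule("m", "ACGT" * 20, "circular")
        (frag,) = lf.digest(m, ["SapI"])
        assert frag.circular and frag.sequence == m.sequence

    def test_overhang_reconstruction_invariant(self, cfg, small_cds):
        donor = lf.build_reference_donor(small_cds, "resB", "pD", cfg, cycle_index=1)
        for f in lf.digest(donor, ["SapI", "BbsI"]):
            assert f.end_overhang_from_sequence("left") == f.left_end.overhang
            assert f.end_overhang_from_sequence("right") == f.right_end.overhang

    def test_overhang_length_matches_registry_through_digestion(self, cfg):
        pz = lf.build_reference_pz(marker="resA", config=cfg)
        for name in ("SapI", "BsaI"):
            (frag,) = lf.digest(pz, [name])
            e = lf.get_enzyme(name)
            for end in (frag.left_end, frag.right_end):
                assert len(end) == e.overhang_length
                assert end.polarity == e.polarity

    def test_double_cut_overhang_clash_raises(self):
        # two SapI sites on opposite strands cutting into the same bases
        seq = "AA" + "GCTCTTC" + "A" + "GGTA" + lf.revcomp("GCTCTTC") + "AA"
        m = lf.DnaMolecule("m", seq, "linear")
        with pytest.raises(lf.DesignError, match="clash"):
            lf.digest(m, ["SapI"])

    def test_strand_symmetry(self, cfg, small_cds):
        donor = lf.build_reference_donor(small_cds, "resB", "pD", cfg, cycle_index=1)
        flipped = lf.DnaMolecule("rc", lf.revcomp(donor.sequence), "circular")
        # fragment multisets identical up to per-fragment reverse complement
        a = sorted(min(f.sequence, lf.revcomp(f.sequence))
                   for f in lf.digest(donor, ["SapI", "BbsI"]))
        b = sorted(min(f.sequence, lf.revcomp(f.sequence))
                   for f in lf.digest(flipped, ["SapI", "BbsI"]))
        assert a == b


class TestAnalyticalDigest:
    def test_uncut_flagged(self):
        m = lf.DnaMolecule("m", "ACGT" * 1000, "circular")
        rows = lf.analytical_digest(m, ["SapI"])
        assert rows == [
            {"fragment_id": "m|uncut", "size_bp": 4000,
             "left_polarity": "blunt", "left_overhang": "",
             "right_polarity": "blunt", "right_overhang": "", "uncut": True}
        ]

    def test_sizes_sorted_and_conserved(self, cfg):
        pz = lf.build_reference_pz(marker="resA", config=cfg)
        rows = lf.analytical_digest(pz, ["SapI", "BsaI"])
        sizes = [r["size_bp"] for r in rows]
        assert sizes == sorted(sizes, reverse=True)
        assert sum(sizes) == len(pz)
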