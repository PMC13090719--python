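"""The elementary assembly cycle: reference architectures, selection,
marker alternation, ccdB counterselection, and plasmid regeneration."""

import pytest
from dataclasses import replace

import linkforge as lf


@pytest.fixture(scope="module")
def first_cycle(cfg, small_cds):
    pz = lf.build_reference_pz(marker="resA", config=cfg, cycle_index=1)
    donor = lf.build_reference_donor(small_cds, "resB", "pD", cfg, cycle_index=1)
    return pz, donor, cfg.cycle_spec(1)


class TestReferencePz:
    def test_exactly_one_junction_and_one_backbone_site(self, cfg):
        pz = lf.build_reference_pz(marker="resA", config=cfg)
        assert len(lf.find_sites(pz, lf.get_enzyme("SapI"))) == 1
        assert len(lf.find_sites(pz, lf.get_enzyme("BsaI"))) == 1
        for other in ("BtsI", "BbsI", "BsmBI", "BsrDI"):
            assert lf.find_sites(pz, lf.get_enzyme(other)) == []
        assert len(lf.analytical_digest(pz, ["SapI", "BsaI"])) == 2

    def test_keeper_carries_origin_and_orf_discard_carries_marker(self, cfg):
        pz = lf.build_reference_pz(marker="resA", config=cfg)
        frags = lf.digest(pz, ["SapI", "BsaI"])
        keeper = next(f for f in frags
                      if any(ft.key == "origin" for ft in f.features))
        discard = next(f for f in frags if f is not keeper)
        assert {ft.key for ft in keeper.features} >= {"origin", "rbs", "cds"}
        assert any(ft.key == "marker" for ft in discard.features)
        assert not any(ft.key == "marker" for ft in keeper.features)

    def test_no_ccdb_anywhere(self, cfg):
        pz = lf.build_reference_pz(marker="resA", config=cfg)
        assert pz.features_by_key("ccdb") == []

    def test_genbank_round_trip_rebuild(self, tmp_path, cfg):
        pz = lf.build_reference_pz(marker="resA", config=cfg)
        lf.write_genbank(pz, tmp_path / "pz.gb")
        assert lf.read_genbank(tmp_path / "pz.gb")[0].sequence == \
            lf.build_reference_pz(marker="resA", config=cfg).sequence

    def test_part_with_internal_site_rejected(self, cfg):
        bad = "ATG" + "GGTCTC" + "AAA" * 20  # internal BsaI site
        with pytest.raises(lf.DesignError, match="BsaI"):
            lf.build_reference_donor(bad, "resB", "pD", cfg, cycle_index=1)


class TestReferenceDonor:
    def test_digestion_yields_keeper_plus_ccdb_discard(self, cfg, small_cds):
        donor = lf.build_reference_donor(small_cds, "resB", "pD", cfg, cycle_index=1)
        frags = lf.digest(donor, ["SapI", "BbsI"])
        assert len(frags) == 2
        keeper = next(f for f in frags
                      if any(ft.key == "part" for ft in f.features))
        discard = next(f for f in frags if f is not keeper)
        assert any(ft.key == "marker" for ft in keeper.features)
        assert any(ft.key == "ccdb" for ft in discard.features)

    def test_keeper_ends_match_pz_keeper_ends(self, cfg, small_cds, first_cycle):
        pz, donor, _ = first_cycle
        pz_keeper = next(f for f in lf.digest(pz, ["SapI", "BsaI"])
                         if any(ft.key == "origin" for ft in f.features))
        d_keeper = next(f for f in lf.digest(donor, ["SapI", "BbsI"])
                        if any(ft.key == "part" for ft in f.features))
        assert lf.ends_compatible(pz_keeper.right_end, d_keeper.left_end)
        assert lf.ends_compatible(d_keeper.right_end, pz_keeper.left_end)

    def test_donor_religation_recovers_original(self, cfg, small_cds):
        donor = lf.build_reference_donor(small_cds, "resB", "pD", cfg, cycle_index=1)
        assert lf.religation_check(donor, ["SapI", "BbsI"])


class TestCycleSpecValidation:
    def test_backbones_must_differ(self):
        with pytest.raises(lf.DesignError):
            lf.CycleSpec("BsaI", "BsaI", "SapI", "resB")

    def test_junction_must_differ_from_backbones(self):
        with pytest.raises(lf.DesignError):
            lf.CycleSpec("BsaI", "BbsI", "BsaI", "resB")


class TestRunCycle:
    def test_unique_survivor_with_marker_switch(self, first_cycle, cfg):
        pz, donor, spec = first_cycle
        result = lf.run_cycle(pz, donor, spec, cfg)
        assert result.ok and len(result.survivors) == 1
        out = result.output_pz
        markers = {f.qualifier("resistance") for f in out.features_by_key("marker")}
        assert markers == {"resB"}
        assert out.features_by_key("ccdb") == []

    def test_orf_extended_in_frame(self, first_cycle, cfg, small_cds):
        pz, donor, spec = first_cycle
        out = lf.run_cycle(pz, donor, spec, cfg).output_pz
        (orf,) = [f for f in out.features if f.key == "cds" and f.label == "orf"]
        seq = out.region(orf.start, orf.end)
        assert seq == "ATG" + lf.SCAR_CODON + small_cds
        assert lf.translate(seq) == "MG" + lf.translate(small_cds)

    def test_product_is_contained_in_the_oracle(self, first_cycle, cfg):
        pz, donor, spec = first_cycle
        result = lf.run_cycle(pz, donor, spec, cfg)
        pool = lf.digest(pz, ["BsaI", "SapI"]) + lf.digest(donor, ["BbsI", "SapI"])
        forms = {p.canonical_form for p in lf.enumerate_circular(pool, 2)}
        assert lf.canonical_sequence(result.output_pz.sequence) in forms

    def test_undigested_donor_excluded_by_ccdb(self, first_cycle, cfg):
        pz, donor, spec = first_cycle
        result = lf.run_cycle(pz, donor, spec, cfg)
        reasons = [d["reason"] for d in result.diagnostics["discards"]]
        assert any("ccdb" in r for r in reasons)  # donor religation rejected
        assert any("marker" in r for r in reasons)  # pZ religation rejected

    def test_zero_survivors_reported_as_failure(self, first_cycle, cfg):
        pz, donor, _ = first_cycle
        wrong = lf.CycleSpec("BsaI", "BbsI", "SapI", expected_marker="resX")
        result = lf.run_cycle(pz, donor, wrong, cfg)
        assert not result.ok
        assert "failed" in result.diagnostics["error"]


class TestNoLigaseControl:
    def test_valid_fixtures_yield_zero(self, first_cycle, cfg):
        pz, donor, spec = first_cycle
        assert lf.no_ligase_control(pz, donor, spec, cfg) == 0

    def test_donor_lacking_ccdb_is_caught_by_control(self, first_cycle, cfg):
        pz, donor, spec = first_cycle
        broken = replace(
            donor, features=tuple(f for f in donor.features if f.key != "ccdb")
        )
        # the undigested... donor religates whole; without ccdB nothing stops it
        frags = lf.digest(broken, [spec.donor_backbone_enzyme, spec.junction_enzyme])
        pool = lf.LigationPool(tuple(frags))
        products = lf.enumerate_circular(pool, 2)
        rule = lf.SelectionRule(required_marker=spec.expected_marker)
        assert sum(1 for p in products if rule.reject_reason(p) is None) > 0

    def test_pz_already_carrying_expected_marker(self, cfg, small_cds):
        pz = lf.build_reference_pz(marker="resB", config=cfg, cycle_index=1)
        donor = lf.build_reference_donor(small_cds, "resB", "pD", cfg, cycle_index=1)
        spec = cfg.cycle_spec(1)
        result = lf.run_cycle(pz, donor, spec, cfg)
        # selection cannot distinguish input religation from product
        assert len(result.survivors) > 1 or (
            result.ok is False and "ambiguous" in result.diagnostics.get("error", "")
        )


class TestRegeneration:
    def test_three_cycle_chain_alternates_everything(self, cfg, small_cds):
        pz = lf.build_reference_pz(marker=cfg.marker(0), config=cfg, cycle_index=1)
        for k in (1, 2, 3):
            spec = cfg.cycle_spec(k)
            donor = lf.build_reference_donor(
                small_cds, spec.expected_marker, "pD", cfg, cycle_index=k
            )
            result = lf.run_cycle(pz, donor, spec, cfg)
            assert result.ok, result.diagnostics
            out = result.output_pz
            markers = {f.qualifier("resistance")
                       for f in out.features_by_key("marker")}
            assert markers == {spec.expected_marker}
            pz_marker = {f.qualifier("resistance")
                         for f in pz.features_by_key("marker")}
            assert markers != pz_marker
            pz = out
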