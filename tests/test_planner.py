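"""Build planning, simulation agreement, scar/frame verification, linkers."""

import pytest

import linkforge as lf


class TestLinkerCds:
    @pytest.mark.parametrize(
        "kind,repeats,protein,length",
        [
            ("GGS", 3, "GGSGGSGGS", 27),
            ("TP_T", 4, "TPTPTPTPT", 27),
            ("GGS", 1, "GGS", 9),
        ],
    )
    def test_linker_composition(self, kind, repeats, protein, length):
        part = lf.linker_cds(kind, repeats)
        assert part.role == "linker"
        assert lf.translate(part.cds) == protein
        assert len(part.cds) == length

    def test_bad_kind_and_repeats(self):
        with pytest.raises(lf.DesignError):
            lf.linker_cds("EAAAK", 3)
        with pytest.raises(lf.DesignError):
            lf.linker_cds("GGS", 0)


class TestPartValidation:
    def test_frame_and_stop_rules(self):
        with pytest.raises(lf.IngestError):
            lf.Part("p", "domain", "ATGG")  # not a whole number of codons
        with pytest.raises(lf.IngestError):
            lf.Part("p", "domain", "ATGTAAGGG")  # internal stop
        # rbs/stop parts are exempt from frame bookkeeping
        lf.Part("s", "stop", "TAAT")

    def test_unknown_role(self):
        with pytest.raises(lf.IngestError):
            lf.Part("p", "promoter", "ATGGGT")


class TestPlanBuild:
    def test_nine_step_schedule(self, nine_plan):
        assert len(nine_plan.steps) == 9
        markers = nine_plan.marker_schedule
        assert all(markers[i] != markers[i + 1] for i in range(8))
        backbones = [s.pz_backbone_enzyme for s in nine_plan.steps_specs()]
        donors = [s.donor_backbone_enzyme for s in nine_plan.steps_specs()]
        for i in range(8):
            assert backbones[i] != backbones[i + 1]
            assert donors[i] == backbones[i + 1]  # donor supplies next site
        junctions = [s.junction_enzyme for s in nine_plan.steps_specs()]
        assert all(junctions[i] != junctions[i + 1] for i in range(8))

    def test_single_part_plan(self, cfg, small_cds):
        plan = lf.plan_build([lf.Part("d", "domain", small_cds)], cfg)
        assert len(plan.steps) == 1
        assert plan.final_orf == "ATG" + lf.SCAR_CODON + plan.effective_cds[0]

    def test_empty_part_list_rejected(self, cfg):
        with pytest.raises(lf.DesignError):
            lf.plan_build([], cfg)

    def test_undomesticated_part_rejected(self, cfg):
        bad = lf.Part("bad", "domain", "ATG" + "GGTCTC" + "AAA" * 5)
        with pytest.raises(lf.DesignError, match="domesticate"):
            lf.plan_build([bad], cfg)

    def test_shared_junction_enzyme_clash_named(self, cfg, small_cds):
        parts = [lf.Part("a", "domain", small_cds), lf.Part("b", "domain", small_cds)]
        with pytest.raises(lf.DesignError, match="part skipping"):
            lf.plan_build(parts, cfg, junction_overrides={"a": "SapI", "b": "SapI"})

    def test_boundary_spanning_site_repaired_synonymously(self, cfg):
        # scar GGT + a CDS starting CTC forms a BsaI site across the junction
        tail = lf.random_cds(
            lf.SynthSpec(seed=0, n_residues=30,
                         forbidden_enzymes=cfg.domestication_enzymes)
        ).cds
        cds = "CTC" + tail
        assert lf.scan_forbidden_sites(cds, cfg.domestication_enzymes) == []
        plan = lf.plan_build([lf.Part("edge", "domain", cds)], cfg)
        eff = plan.effective_cds[0]
        assert eff != cds
        assert lf.translate(eff) == lf.translate(cds)
        assert lf.scan_forbidden_sites(
            lf.SCAR_CODON + eff, cfg.domestication_enzymes) == []


class TestSimulateBuild:
    def test_plan_execution_agreement(self, nine_plan, nine_build):
        (orf_feat,) = [f for f in nine_build.final_plasmid.features
                       if f.key == "cds" and f.label == "orf"]
        orf = nine_build.final_plasmid.region(orf_feat.start, orf_feat.end)
        assert orf == nine_plan.final_orf
        for inter, predicted in zip(nine_build.intermediates,
                                    nine_plan.predicted_sequences):
            assert inter.sequence == predicted

    def test_five_domain_copy_number(self, nine_plan, nine_build):
        domain = nine_plan.effective_cds[0]
        assert nine_build.final_plasmid.sequence.count(domain) == 5

    def test_two_part_fusion_protein(self, cfg, small_cds):
        parts = [lf.Part("d1", "domain", small_cds), lf.linker_cds("GGS", 3)]
        plan = lf.plan_build(parts, cfg)
        result = lf.simulate_build(plan, cfg)
        expected = "M" + "G" + lf.translate(plan.effective_cds[0]) + "G" + "GGSGGSGGS"
        assert plan.final_protein == expected
        assert result.scar_report.total_scars == 1

    def test_qc_ladder_monotone_growth(self, nine_build):
        orf_fragment_sizes = [max(r["size_bp"] for r in table)
                              for table in nine_build.qc_table]
        assert all(a < b for a, b in zip(orf_fragment_sizes, orf_fragment_sizes[1:]))
        totals = [sum(r["size_bp"] for r in t) for t in nine_build.qc_table]
        assert all(a < b for a, b in zip(totals, totals[1:]))

    def test_scar_accounting(self, nine_build, nine_plan):
        report = nine_build.scar_report
        assert report.total_scars == 8  # 9 parts -> 8 inter-part junctions
        assert report.scar_count_per_junction == 1
        assert all(residue == "G" for _, residue, _ in report.junctions)
        protein = nine_plan.final_protein
        for pos, residue, _ in report.junctions:
            assert protein[pos] == residue


class TestVerifyOrf:
    def test_two_part_build_single_junction(self, cfg, small_cds):
        parts = [lf.Part("d1", "domain", small_cds), lf.linker_cds("GGS", 3)]
        plan = lf.plan_build(parts, cfg)
        result = lf.simulate_build(plan, cfg)
        eff = [lf.Part(p.id, p.role, c)
               for p, c in zip(plan.parts, plan.effective_cds)]
        report = lf.verify_orf(result.final_plasmid, eff, cfg, plan)
        assert len(report.junctions) == 1

    def test_corrupted_junction_detected_as_frameshift(self, cfg, small_cds):
        parts = [lf.Part("d1", "domain", small_cds), lf.linker_cds("GGS", 3)]
        plan = lf.plan_build(parts, cfg)
        result = lf.simulate_build(plan, cfg)
        mol = result.final_plasmid
        (orf,) = [f for f in mol.features if f.key == "cds" and f.label == "orf"]
        cut = orf.start + 3 + len(plan.effective_cds[0]) + 4  # inside junction 2
        corrupted_seq = mol.sequence[:cut] + mol.sequence[cut + 1:]  # 1 nt deletion
        from dataclasses import replace
        corrupted = replace(
            mol, sequence=corrupted_seq,
            features=tuple(f for f in mol.features
                           if f.end <= len(corrupted_seq)),
        )
        eff = [lf.Part(p.id, p.role, c)
               for p, c in zip(plan.parts, plan.effective_cds)]
        with pytest.raises(lf.DesignError):
            lf.verify_orf(corrupted, eff, cfg, plan)
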