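import pytest

import linkforge as lf


@pytest.fixture(scope="session")
def cfg():
    return lf.AssemblyConfig()


@pytest.fixture(scope="session")
def domain_cds(cfg):
    """A ~236-residue fluorescent-protein-sized stand-in CDS."""
    return lf.random_cds(
        lf.SynthSpec(seed=11, n_residues=236,
                     forbidden_enzymes=cfg.domestication_enzymes)
    ).cds


@pytest.fixture(scope="session")
def small_cds(cfg):
    return lf.random_cds(
        lf.SynthSpec(seed=5, n_residues=40,
                     forbidden_enzymes=cfg.domestication_enzymes)
    ).cds


@pytest.fixture(scope="session")
def nine_parts(cfg, domain_cds):
    """Five identical domains interleaved with four (GGS)3 linkers."""
    parts = []
    for i in range(1, 6):
        parts.append(lf.Part(f"dom{i}", "domain", domain_cds))
        if i < 5:
            parts.append(lf.linker_cds("GGS", 3, part_id=f"ggs{i}"))
    return parts


@pytest.fixture(scope="session")
def nine_plan(cfg, nine_parts):
    return lf.plan_build(nine_parts, cfg)


@pytest.fixture(scope="session")
def nine_build(cfg, nine_plan):
    return lf.simulate_build(nine_plan, cfg)


@pytest.fixture(scope="session")
def tu_set(cfg):
    """Four adaptor-flanked TU plasmids plus their acceptor."""
    sites = lf.default_fusion_sites(5)
    tus = []
    for i, label in enumerate(["fpRed", "fpOrange", "fpGreen", "fpCyan"]):
        cds = lf.random_cds(
            lf.SynthSpec(seed=100 + i, n_residues=236,
                         forbidden_enzymes=cfg.domestication_enzymes)
        ).cds
        tus.append(lf.build_tu_plasmid(label, cds, sites[i], sites[i + 1], cfg))
    acceptor = lf.build_acceptor(sites[0], sites[-1], cfg)
    return tus, acceptor
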