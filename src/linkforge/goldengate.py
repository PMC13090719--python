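"""BsmBI Golden Gate layer: translation units into a poly-cistronic construct.

Each translation unit (TU: RBS + CDS + stop) is flanked by *adaptor
modules* — a head adaptor carrying the translation-initiation payload and a
tail adaptor carrying the termination payload — each with a positioning
module that yields a defined 4 nt overhang upon BsmBI digestion.  Chaining
the fusion sites (tail site of TU_i = head site of TU_{i+1}) lets a one-pot
digestion/ligation compile any number of TUs, in order, into an acceptor
backbone.  The acceptor reuses the genetic-purification machinery: a
distinct resistance marker plus a ccdB dropout between its two BsmBI sites,
so the only selection-passing circle is the complete poly-cistron.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .cycle import AssemblyConfig, SelectionRule
from .ligation import CircularProduct, LigationPool, enumerate_circular
from .seqmodel import DesignError, DnaMolecule, Feature, revcomp
from .typeiis import digest, find_sites, get_enzyme

__all__ = [
    "AdaptorModule",
    "TUPlasmid",
    "validate_fusion_sites",
    "default_fusion_sites",
    "attach_adaptors",
    "build_tu_plasmid",
    "build_acceptor",
    "gg_assemble",
]

#: documented candidate list; the shipped set is the validated prefix
_FUSION_CANDIDATES = (
    "AATG", "GCTT", "CGAA", "TTAC", "CCAT", "AGGT", "TGAC", "CAGC",
)


def validate_fusion_sites(sites: Sequence[str]) -> dict:
    """Flag duplicates, palindromes, and mutually reverse-complementary pairs.

    Any of those would let a junction ligate in the wrong place or the
    wrong orientation.
    """
    problems: list[str] = []
    for s in sites:
        if len(s) != 4 or set(s) - set("ACGT"):
            problems.append(f"{s!r}: fusion sites are 4 nt ACGT")
        elif s == revcomp(s):
            problems.append(f"{s}: palindromic (self-complementary)")
    seen: dict[str, int] = {}
    for i, s in enumerate(sites):
        if s in seen:
            problems.append(f"{s}: duplicated (positions {seen[s]} and {i})")
        else:
            seen[s] = i
    for i, a in enumerate(sites):
        for j in range(i + 1, len(sites)):
            if revcomp(a) == sites[j]:
                problems.append(
                    f"{a}/{sites[j]}: mutual reverse complements "
                    "(would permit inverted insertion)"
                )
    return {"ok": not problems, "sites": list(sites), "problems": problems}


def default_fusion_sites(n: int) -> list[str]:
    """First ``n`` candidates that pass :func:`validate_fusion_sites`."""
    chosen: list[str] = []
    for cand in _FUSION_CANDIDATES:
        if validate_fusion_sites(chosen + [cand])["ok"]:
            chosen.append(cand)
        if len(chosen) == n:
            return chosen
    raise DesignError(f"candidate list exhausted before {n} valid fusion sites")


@dataclass(frozen=True)
class AdaptorModule:
    """Positioning module (+ optional functional payload) for one TU side."""

    side: str  # head | tail
    fusion_site: str
    payload: str = ""  # RBS for head, stop region for tail; may be empty

    def __post_init__(self) -> None:
        if self.side not in ("head", "tail"):
            raise DesignError(f"adaptor side must be head/tail, got {self.side!r}")
        report = validate_fusion_sites([self.fusion_site])
        if not report["ok"]:
            raise DesignError("; ".join(report["problems"]))
        if self.payload and set(self.payload) - set("ACGT"):
            raise DesignError("adaptor payload must be ACGT")


@dataclass(frozen=True)
class TUPlasmid:
    """A donor-style plasmid whose BsmBI digest releases one TU keeper."""

    molecule: DnaMolecule
    marker: str
    head_site: str
    tail_site: str
    label: str


def attach_adaptors(
    tu_orf: DnaMolecule | str,
    head: AdaptorModule,
    tail: AdaptorModule,
    config: AssemblyConfig | None = None,
    label: str = "tu",
) -> TUPlasmid:
    """Flank a TU ORF with head/tail adaptors on a donor-style backbone.

    BsmBI digestion of the result yields the keeper with 5' overhangs
    ``head.fusion_site`` / complement of ``tail.fusion_site``.  An internal
    BsmBI site in the ORF is a domestication error.
    """
    cfg = config or AssemblyConfig()
    report = validate_fusion_sites([head.fusion_site, tail.fusion_site])
    if not report["ok"]:
        raise DesignError("; ".join(report["problems"]))
    if head.side != "head" or tail.side != "tail":
        raise DesignError("adaptor sides must be (head, tail)")
    orf_seq = tu_orf if isinstance(tu_orf, str) else tu_orf.sequence
    enzyme = get_enzyme(cfg.gg_enzyme)
    probe = DnaMolecule("probe", orf_seq, "linear")
    if find_sites(probe, enzyme):
        raise DesignError(
            f"TU ORF contains internal {cfg.gg_enzyme} site(s); domesticate first"
        )
    marker = cfg.markers[0]

    segs = [
        enzyme.recognition, "A" * enzyme.cut_top, head.fusion_site,
        head.payload, orf_seq, tail.payload,
        tail.fusion_site, "A" * enzyme.cut_top, revcomp(enzyme.recognition),
        cfg.marker_seq(marker), cfg.donor_origin_seq,
    ]
    seq = "".join(segs)
    pos = [0]
    for s in segs:
        pos.append(pos[-1] + len(s))
    feats = [
        Feature("adaptor", f"head-{head.fusion_site}", pos[0], pos[4]),
        Feature("cds", label, pos[4], pos[5], qualifiers=(("role", "fp"),)),
        Feature("adaptor", f"tail-{tail.fusion_site}", pos[5], pos[9]),
        Feature("marker", f"marker-{marker}", pos[9], pos[10],
                qualifiers=(("resistance", marker),)),
        Feature("origin", "tu-origin", pos[10], pos[11]),
    ]
    if head.payload:
        feats.insert(1, Feature("rbs", "rbs", pos[3], pos[4]))
    if tail.payload:
        feats.insert(-2, Feature("stop", "stop", pos[5], pos[6]))
    mol = DnaMolecule(f"pTU[{label}]", seq, "circular", tuple(feats))
    sites = find_sites(mol, enzyme)
    if len(sites) != 2:
        raise DesignError(
            f"TU plasmid must carry exactly 2 {cfg.gg_enzyme} sites, found {len(sites)}"
        )
    return TUPlasmid(mol, marker, head.fusion_site, tail.fusion_site, label)


def build_tu_plasmid(
    label: str,
    cds: str,
    head_site: str,
    tail_site: str,
    config: AssemblyConfig | None = None,
) -> TUPlasmid:
    """Convenience fixture: RBS head adaptor, start codon + CDS + stop,
    stop-payload tail adaptor."""
    cfg = config or AssemblyConfig()
    head = AdaptorModule("head", head_site, payload=cfg.rbs_seq)
    tail = AdaptorModule("tail", tail_site, payload="")
    orf = "ATG" + cds + "TAA"
    return attach_adaptors(orf, head, tail, cfg, label=label)


def build_acceptor(
    first_site: str,
    last_site: str,
    config: AssemblyConfig | None = None,
) -> DnaMolecule:
    """The Golden Gate destination: marker + origin backbone whose ccdB
    dropout is excised by BsmBI, exposing ``first_site``/``last_site``."""
    cfg = config or AssemblyConfig()
    enzyme = get_enzyme(cfg.gg_enzyme)
    report = validate_fusion_sites([first_site, last_site])
    if not report["ok"]:
        raise DesignError("; ".join(report["problems"]))
    segs = [
        enzyme.recognition, "A" * enzyme.cut_top, last_site,
        cfg.origin_seq, cfg.marker_seq(cfg.gg_marker),
        first_site, "A" * enzyme.cut_top, revcomp(enzyme.recognition),
        cfg.ccdb_seq,
    ]
    seq = "".join(segs)
    pos = [0]
    for s in segs:
        pos.append(pos[-1] + len(s))
    feats = [
        Feature("origin", "origin", pos[3], pos[4]),
        Feature("marker", f"marker-{cfg.gg_marker}", pos[4], pos[5],
                qualifiers=(("resistance", cfg.gg_marker),)),
        Feature("ccdb", "ccdB", pos[8], pos[9]),
    ]
    mol = DnaMolecule("pAcceptor", seq, "circular", tuple(feats))
    if len(find_sites(mol, enzyme)) != 2:
        raise DesignError("acceptor must carry exactly 2 Golden Gate sites")
    return mol


def gg_assemble(
    tus: Sequence[TUPlasmid],
    acceptor: DnaMolecule,
    config: AssemblyConfig | None = None,
) -> CircularProduct:
    """One-pot BsmBI compilation of ``tus`` (in order) into ``acceptor``.

    Digest everything, enumerate all circular ligation products, apply the
    acceptor-marker / no-ccdB selection, and require a unique survivor that
    contains every TU in the requested order.
    """
    cfg = config or AssemblyConfig()
    if not tus:
        raise DesignError("need at least one translation unit")
    sites = [tus[0].head_site] + [tu.tail_site for tu in tus]
    report = validate_fusion_sites(sites)
    if not report["ok"]:
        raise DesignError("fusion-site clash: " + "; ".join(report["problems"]))
    for i in range(len(tus) - 1):
        if tus[i].tail_site != tus[i + 1].head_site:
            raise DesignError(
                f"chain gap at junction {i + 1}->{i + 2}: tail site "
                f"{tus[i].tail_site} does not meet head site {tus[i + 1].head_site}"
            )

    frags = digest(acceptor, [cfg.gg_enzyme])
    for tu in tus:
        frags.extend(digest(tu.molecule, [cfg.gg_enzyme]))
    products = enumerate_circular(
        LigationPool(tuple(frags)), max_fragments=len(tus) + 1,
        frontier_limit=cfg.frontier_limit,
    )
    rule = SelectionRule(required_marker=cfg.gg_marker, forbidden_feature="ccdb")
    survivors = [p for p in products if rule.reject_reason(p) is None]
    if not survivors:
        raise DesignError(
            "assembly failed: no selection-passing product "
            "(check the fusion-site chain)"
        )
    if len(survivors) > 1:
        raise DesignError(
            f"fusion-site clash: {len(survivors)} selection-passing products"
        )
    product = survivors[0]
    fp_order = [
        f.label for f in sorted(product.molecule.features, key=lambda f: f.start)
        if f.key == "cds" and f.qualifier("role") == "fp"
    ]
    if fp_order != [tu.label for tu in tus]:
        raise DesignError(
            f"product TU order {fp_order} differs from requested "
            f"{[tu.label for tu in tus]}"
        )
    return product
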