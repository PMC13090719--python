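"""One elementary assembly cycle: digest, ligate, select, regenerate.

The framework grows a fusion-protein ORF directly in a circular destination
plasmid (pZ).  Each cycle recombines pZ with a donor plasmid (pD for a
functional domain, pL for a linker) through a one-pot digestion/ligation:

* pZ is pre-digested with its backbone enzyme (BsaI or BbsI) and the cycle's
  junction enzyme (SapI or BtsI), splitting it into a *keeper* fragment
  (origin + RBS + growing ORF) and a *discard* fragment (the old antibiotic
  marker plus both spent recognition sites);
* the donor is digested with the complementary backbone enzyme and the same
  junction enzyme, yielding a *keeper* (fusion overhang + part CDS +
  next-cycle junction site + new marker + next-cycle backbone site) and a
  *discard* carrying ccdB and the donor origin;
* ligation joins the two keepers through a 2-3 nt fusion overhang at the ORF
  end (one glycine scar codon, GGT, per junction) and a designed 4 nt
  overhang at the marker|origin boundary;
* a T5-exonuclease step removes everything linear, and transformation
  selects for the new marker and against ccdB.

Both recognition sites consumed from pZ leave with the discard fragment and
are re-supplied by the donor keeper, so the unique surviving product is a
pZ of identical architecture with opposite parity — the cycle regenerates
its own substrate and can be iterated indefinitely.  Junction and backbone
enzymes alternate between consecutive cycles (SapI/BtsI and BsaI/BbsI) so
that a donor's next-cycle sites are inert in the current reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

from .ligation import CircularProduct, LigationPool, enumerate_circular
from .seqmodel import DesignError, DnaMolecule, Feature, revcomp
from .typeiis import digest, get_enzyme, scan_forbidden_sites

__all__ = [
    "AssemblyConfig",
    "CycleSpec",
    "SelectionRule",
    "CycleResult",
    "SCAR_CODON",
    "build_reference_pz",
    "build_reference_donor",
    "run_cycle",
    "no_ligase_control",
]

#: the single-residue scar every junction leaves in the fused protein
SCAR_CODON = "GGT"  # glycine


@dataclass(frozen=True)
class AssemblyConfig:
    """Tunable framework parameters; defaults realise the shipped design."""

    markers: tuple[str, ...] = ("resA", "resB")
    junction_enzymes: tuple[str, str] = ("SapI", "BtsI")
    backbone_enzymes: tuple[str, str] = ("BsaI", "BbsI")
    backbone_overhang: str = "CGCT"  # 4 nt, non-palindromic
    orf_prefix: str = ""  # optional codons after ATG (e.g. a His6 tag)
    max_fragments: int = 2
    frontier_limit: int = 10**6
    domestication_enzymes: tuple[str, ...] = (
        "BtsI", "BsrDI", "SapI", "BsaI", "BbsI", "BsmBI",
    )
    # Golden Gate layer
    gg_enzyme: str = "BsmBI"
    gg_marker: str = "resC"

    def __post_init__(self) -> None:
        if len(self.markers) < 2 or len(set(self.markers)) != len(self.markers):
            raise DesignError("need >=2 distinct alternating markers")
        W = self.backbone_overhang
        if len(W) != 4 or W == revcomp(W):
            raise DesignError("backbone overhang must be 4 nt and non-palindromic")
        if len(self.orf_prefix) % 3:
            raise DesignError("orf_prefix must be whole codons")

    # --- per-cycle schedules (cycle_index is 1-based) ---------------------
    def junction(self, cycle_index: int) -> str:
        return self.junction_enzymes[(cycle_index - 1) % 2]

    def pz_backbone(self, cycle_index: int) -> str:
        return self.backbone_enzymes[(cycle_index - 1) % 2]

    def donor_backbone(self, cycle_index: int) -> str:
        return self.backbone_enzymes[cycle_index % 2]

    def marker(self, cycle_index: int) -> str:
        """Marker carried by the pZ *output* of cycle ``cycle_index``.

        Cycle 0 denotes the starting plasmid.
        """
        return self.markers[cycle_index % 2]

    def cycle_spec(self, cycle_index: int, junction_override: str | None = None) -> "CycleSpec":
        return CycleSpec(
            pz_backbone_enzyme=self.pz_backbone(cycle_index),
            donor_backbone_enzyme=self.donor_backbone(cycle_index),
            junction_enzyme=junction_override or self.junction(cycle_index),
            expected_marker=self.marker(cycle_index),
        )

    # --- fixed placeholder sequences (deterministic, site-free) -----------
    @property
    def origin_seq(self) -> str:
        return _filler("origin", 80, self.domestication_enzymes)

    @property
    def donor_origin_seq(self) -> str:
        return _filler("donor-origin", 60, self.domestication_enzymes)

    @property
    def rbs_seq(self) -> str:
        return "AGGAGG" + _filler("rbs-gap", 7, self.domestication_enzymes)

    def marker_seq(self, label: str) -> str:
        return _coding("marker-" + label, 18, self.domestication_enzymes)

    @property
    def ccdb_seq(self) -> str:
        return _coding("ccdb", 14, self.domestication_enzymes)


@lru_cache(maxsize=None)
def _filler(label: str, n: int, forbidden: tuple[str, ...]) -> str:
    from .partsynth import filler_dna

    return filler_dna(label, n, list(forbidden))


@lru_cache(maxsize=None)
def _coding(label: str, n_res: int, forbidden: tuple[str, ...]) -> str:
    from .partsynth import coding_filler

    return coding_filler(label, n_res, list(forbidden))


# ---------------------------------------------------------------------------
# cassette geometry
# ---------------------------------------------------------------------------

def scar_overhang(junction_enzyme: str) -> str:
    """The fusion-overhang bases for a junction enzyme (GGT or its GG prefix)."""
    e = get_enzyme(junction_enzyme)
    if e.overhang_length not in (2, 3):
        raise DesignError(
            f"{junction_enzyme} leaves a {e.overhang_length} nt overhang; "
            "fusion junctions use 2-3 nt"
        )
    return SCAR_CODON[: e.overhang_length]


def junction_cassette(junction_enzyme: str) -> str:
    """pZ sequence downstream of the ORF: scar bases, spacer, recognition
    on the minus strand so the cut falls at the ORF 3' end."""
    e = get_enzyme(junction_enzyme)
    gap = min(e.cut_top, e.cut_bottom)
    return scar_overhang(junction_enzyme) + "A" * gap + revcomp(e.recognition)


def donor_lead(junction_enzyme: str) -> str:
    """Donor sequence 5' of the part CDS: recognition on the plus strand,
    spacer, scar bases, and (for 2 nt overhangs) the codon-completing base."""
    e = get_enzyme(junction_enzyme)
    gap = min(e.cut_top, e.cut_bottom)
    ov = scar_overhang(junction_enzyme)
    completion = SCAR_CODON[len(ov):]
    return e.recognition + "A" * gap + ov + completion


def backbone_cassette(backbone_enzyme: str, W: str) -> str:
    """Recognition + spacer + the 4 nt backbone fusion overhang ``W``."""
    e = get_enzyme(backbone_enzyme)
    if e.polarity != "five_prime" or e.overhang_length != 4:
        raise DesignError(f"{backbone_enzyme} is not a 4 nt 5'-overhang backbone enzyme")
    return e.recognition + "A" * e.cut_top + W


def _validate_site_counts(m: DnaMolecule, expected: dict[str, int],
                          registry_names: Sequence[str]) -> None:
    for name in registry_names:
        hits = scan_forbidden_sites(m.sequence, [name], circular=m.is_circular)
        want = expected.get(name, 0)
        if len(hits) != want:
            raise DesignError(
                f"{m.id}: expected {want} {name} site(s), found {len(hits)} "
                f"at {[(s, p) for _, s, p in hits]} — stray sites must be "
                "removed by domestication"
            )


# ---------------------------------------------------------------------------
# reference architectures
# ---------------------------------------------------------------------------

def build_reference_pz(
    orf_parts_so_far: Sequence = (),
    marker: str | None = None,
    config: AssemblyConfig | None = None,
    cycle_index: int | None = None,
    junction: str | None = None,
) -> DnaMolecule:
    """The destination plasmid carrying ``orf_parts_so_far`` already fused.

    Layout (circular): W | origin | RBS | ATG [+prefix] [+GGT+part]* |
    junction cassette | marker | backbone recognition+spacer (whose
    overhang is the leading W).  Exactly one junction site and one
    backbone site; no other registry-enzyme sites.
    """
    cfg = config or AssemblyConfig()
    parts = [p if isinstance(p, str) else p.cds for p in orf_parts_so_far]
    k = cycle_index if cycle_index is not None else len(parts) + 1
    marker = marker if marker is not None else cfg.marker(k - 1)
    J, E = junction or cfg.junction(k), cfg.pz_backbone(k)
    W = cfg.backbone_overhang

    orf = "ATG" + cfg.orf_prefix + "".join(SCAR_CODON + cds for cds in parts)
    jcas = junction_cassette(J)
    bbcas = backbone_cassette(E, W)
    recspacer = bbcas[: -len(W)]  # W itself wraps to the front

    segs = [W, cfg.origin_seq, cfg.rbs_seq, orf, jcas, cfg.marker_seq(marker),
            recspacer]
    seq = "".join(segs)
    pos = [0]
    for s in segs:
        pos.append(pos[-1] + len(s))
    feats = [
        Feature("origin", "origin", pos[1], pos[2]),
        Feature("rbs", "rbs", pos[2], pos[3]),
        Feature("cds", "orf", pos[3], pos[4]),
        Feature("site", f"junction-{J}", pos[4], pos[5], strand=-1),
        Feature("marker", f"marker-{marker}", pos[5], pos[6],
                qualifiers=(("resistance", marker),)),
        Feature("site", f"backbone-{E}", pos[6], pos[7] + len(W)),  # wraps
    ]
    m = DnaMolecule(f"pZ[{len(parts)}]", seq, "circular", tuple(feats))
    _validate_site_counts(m, {J: 1, E: 1}, cfg.domestication_enzymes)
    return m


def build_reference_donor(
    part,
    new_marker: str,
    kind: str = "pD",
    config: AssemblyConfig | None = None,
    cycle_index: int = 1,
    junction: str | None = None,
    next_junction: str | None = None,
) -> DnaMolecule:
    """A donor plasmid delivering ``part`` in cycle ``cycle_index``.

    Layout (circular): junction lead | part CDS | next-cycle junction
    cassette | new marker | next-cycle backbone cassette | ccdB | donor
    origin.  Digestion with {donor backbone, junction} yields exactly the
    keeper (everything from the fusion overhang through the backbone
    overhang) plus a ccdB-bearing discard.
    """
    cfg = config or AssemblyConfig()
    if kind not in ("pD", "pL"):
        raise DesignError(f"donor kind must be pD or pL, got {kind!r}")
    cds = part if isinstance(part, str) else part.cds
    label = getattr(part, "id", None) or "part"
    J = junction or cfg.junction(cycle_index)
    Jn = next_junction or cfg.junction(cycle_index + 1)
    En = cfg.donor_backbone(cycle_index)
    W = cfg.backbone_overhang

    segs = [
        donor_lead(J),
        cds,
        junction_cassette(Jn),
        cfg.marker_seq(new_marker),
        backbone_cassette(En, W),
        cfg.ccdb_seq,
        cfg.donor_origin_seq,
    ]
    seq = "".join(segs)
    pos = [0]
    for s in segs:
        pos.append(pos[-1] + len(s))
    feats = [
        Feature("site", f"junction-{J}", pos[0], pos[1]),
        Feature("part", label, pos[1], pos[2],
                qualifiers=(("role", getattr(part, "role", "domain")),)),
        Feature("site", f"junction-{Jn}", pos[2], pos[3], strand=-1),
        Feature("marker", f"marker-{new_marker}", pos[3], pos[4],
                qualifiers=(("resistance", new_marker),)),
        Feature("site", f"backbone-{En}", pos[4], pos[5]),
        Feature("ccdb", "ccdB", pos[5], pos[6]),
        Feature("origin", "donor-origin", pos[6], pos[7]),
    ]
    m = DnaMolecule(f"{kind}[{label}]", seq, "circular", tuple(feats))
    expected = {J: 1, Jn: 1, En: 1}
    if J == Jn:  # same-junction override: both cassettes use one enzyme
        expected = {J: 2, En: 1}
    _validate_site_counts(m, expected, cfg.domestication_enzymes)
    if not any(f.key == "ccdb" for f in m.features):
        raise DesignError("donor must carry ccdB in its discard region")
    return m


# ---------------------------------------------------------------------------
# cycle execution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CycleSpec:
    pz_backbone_enzyme: str
    donor_backbone_enzyme: str
    junction_enzyme: str
    expected_marker: str
    forbidden_feature: str = "ccdb"

    def __post_init__(self) -> None:
        if self.pz_backbone_enzyme == self.donor_backbone_enzyme:
            raise DesignError("pZ and donor backbone enzymes must differ")
        if self.junction_enzyme in (self.pz_backbone_enzyme, self.donor_backbone_enzyme):
            raise DesignError("junction enzyme must differ from both backbones")


@dataclass(frozen=True)
class SelectionRule:
    """Genetic purification: transformability + marker + counterselection."""

    required_marker: str
    forbidden_feature: str = "ccdb"
    circular_only: bool = True  # the T5 exonuclease step

    def reject_reason(self, product: CircularProduct) -> str | None:
        feats = product.molecule.features
        markers = {
            f.qualifier("resistance")
            for f in feats if f.key == "marker"
        }
        if self.required_marker not in markers:
            return f"marker {self.required_marker} absent (carries {sorted(m for m in markers if m) or 'none'})"
        if any(f.key == self.forbidden_feature for f in feats):
            return f"carries forbidden feature {self.forbidden_feature}"
        return None


@dataclass(frozen=True)
class CycleResult:
    survivors: tuple[CircularProduct, ...]
    output_pz: DnaMolecule | None
    diagnostics: dict

    @property
    def ok(self) -> bool:
        return self.output_pz is not None


def _extend_orf_annotation(mol: DnaMolecule) -> DnaMolecule:
    """Merge the carried-over ORF feature with the newly fused part.

    In a valid product the part CDS begins exactly one scar codon after the
    previous ORF end; the ORF feature is extended across both.
    """
    orfs = [f for f in mol.features if f.key == "cds" and f.label == "orf"]
    parts = [f for f in mol.features if f.key == "part"]
    if len(orfs) != 1 or len(parts) != 1:
        return mol
    orf, part = orfs[0], parts[0]
    if part.start != orf.end + len(SCAR_CODON):
        raise DesignError(
            f"fused part starts at {part.start}, expected {orf.end + 3}: "
            "junction is out of frame"
        )
    new_feats = []
    for f in mol.features:
        if f is orf:
            new_feats.append(replace(f, end=part.end))
        elif f is part:
            new_feats.append(replace(f, key="cds"))
        else:
            new_feats.append(f)
    return replace(mol, features=tuple(new_feats))


def run_cycle(
    pz: DnaMolecule,
    donor: DnaMolecule,
    spec: CycleSpec,
    config: AssemblyConfig | None = None,
    ligase: bool = True,
) -> CycleResult:
    """Execute one elementary assembly cycle.

    Pipeline: separate complete digests of pZ and donor, pooled ligation
    enumerated exhaustively, then selection (circular-only, required
    marker, no ccdB).  Exactly one surviving product class yields
    ``output_pz``, annotated and ready to seed the next cycle.
    """
    cfg = config or AssemblyConfig()
    pz_frags = digest(pz, [spec.pz_backbone_enzyme, spec.junction_enzyme])
    donor_frags = digest(donor, [spec.donor_backbone_enzyme, spec.junction_enzyme])
    pool = LigationPool(tuple(pz_frags + donor_frags))
    if ligase:
        products = enumerate_circular(
            pool, max_fragments=cfg.max_fragments, frontier_limit=cfg.frontier_limit
        )
    else:
        # without ligase no junction can be sealed; only molecules that
        # entered the reaction already circular remain transformable
        products = enumerate_circular(
            LigationPool(tuple(f for f in pool.fragments if f.circular)),
            max_fragments=1,
        ) if any(f.circular for f in pool.fragments) else []

    rule = SelectionRule(spec.expected_marker, spec.forbidden_feature)
    survivors, discards = [], []
    for p in products:
        reason = rule.reject_reason(p)
        if reason is None:
            survivors.append(p)
        else:
            discards.append({"length": len(p), "reason": reason,
                             "composition": list(map(list, p.composition))})

    diagnostics = {
        "pz_fragments": len(pz_frags),
        "donor_fragments": len(donor_frags),
        "circular_products": len(products),
        "survivors": len(survivors),
        "discards": discards,
        "ligase": ligase,
    }
    output = None
    if len(survivors) == 1:
        mol = _extend_orf_annotation(survivors[0].molecule)
        output = replace(mol, id=f"{pz.id}+{donor.id}")
    elif len(survivors) == 0:
        diagnostics["error"] = "assembly failed: zero selection-passing products"
    else:
        diagnostics["error"] = (
            "ambiguous design: "
            + ", ".join(p.canonical_form[:16] + "..." for p in survivors)
        )
    return CycleResult(tuple(survivors), output, diagnostics)


def no_ligase_control(
    pz: DnaMolecule, donor: DnaMolecule, spec: CycleSpec,
    config: AssemblyConfig | None = None,
) -> int:
    """Survivor count with ligation disabled; 0 for every valid design."""
    return len(run_cycle(pz, donor, spec, config, ligase=False).survivors)
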