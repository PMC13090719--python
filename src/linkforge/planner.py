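"""Build planning: from an ordered part list to a validated cycle schedule.

The planner is a *static* predictor of the simulator: it derives, by pure
string assembly, the exact sequence of every intermediate destination
plasmid, the final ORF, the per-cycle enzyme/marker schedule and the
expected analytical-digest sizes.  :func:`simulate_build` then executes the
same plan through the digestion/ligation machinery and the two routes must
agree — the core integration guarantee of the package.

Parts must arrive domesticated (no internal registry-enzyme sites).  The
planner additionally repairs *boundary-spanning* sites: a recognition
sequence can arise where a part CDS meets the fixed scar/cassette context,
and is removed by synonymous substitution within the part's own codons
(smallest replacement codon, leftmost position on ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .cycle import (
    SCAR_CODON,
    AssemblyConfig,
    CycleSpec,
    build_reference_donor,
    build_reference_pz,
    run_cycle,
)
from .seqmodel import (
    CODON_TABLE,
    SYNONYMOUS_CODONS,
    DesignError,
    DnaMolecule,
    IngestError,
    translate,
)
from .typeiis import analytical_digest, get_enzyme, scan_forbidden_sites
from .cycle import donor_lead, junction_cassette, scar_overhang

__all__ = [
    "Part",
    "BuildPlan",
    "ScarReport",
    "BuildResult",
    "plan_build",
    "simulate_build",
    "verify_orf",
    "linker_cds",
]

_ROLES = frozenset({"domain", "linker", "rbs", "stop", "adaptor"})


@dataclass(frozen=True)
class Part:
    """A modular building block delivered by one donor plasmid."""

    id: str
    role: str
    cds: str

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise IngestError(f"part {self.id}: unknown role {self.role!r}")
        if not self.cds or set(self.cds) - set("ACGT"):
            raise IngestError(f"part {self.id}: CDS must be non-empty ACGT")
        if self.role in ("domain", "linker"):
            if len(self.cds) % 3:
                raise IngestError(f"part {self.id}: CDS length not divisible by 3")
            if "*" in translate(self.cds):
                raise IngestError(f"part {self.id}: internal stop codon")

    @property
    def protein(self) -> str:
        if self.role in ("domain", "linker"):
            return translate(self.cds)
        return ""


@dataclass(frozen=True)
class ScarReport:
    """Inter-part junction accounting for a fused ORF."""

    junctions: tuple[tuple[int, str, str], ...]  # (protein index, residue, enzyme)

    @property
    def scar_count_per_junction(self) -> int:
        return 1 if self.junctions else 0

    @property
    def total_scars(self) -> int:
        return len(self.junctions)


@dataclass(frozen=True)
class BuildPlan:
    parts: tuple[Part, ...]
    effective_cds: tuple[str, ...]  # after boundary repair
    steps: tuple[tuple[str, CycleSpec], ...]
    marker_schedule: tuple[str, ...]
    predicted_intermediates: tuple[tuple[int, ...], ...]  # digest sizes per step
    predicted_sequences: tuple[str, ...]  # full pZ sequence after each step
    final_orf: str
    final_protein: str
    config: AssemblyConfig

    def steps_specs(self) -> list[CycleSpec]:
        return [spec for _, spec in self.steps]


_GGS_CODONS = {"G1": "GGT", "G2": "GGC", "S": "TCT"}
_TPT_CODONS = {"T": "ACC", "P": "CCG"}


def linker_cds(kind: str, repeats: int, part_id: str | None = None) -> Part:
    """A flexible (GGS)n or rigid (TP)nT linker with fixed codon choices."""
    if repeats < 1:
        raise DesignError("repeats must be >= 1")
    if kind == "GGS":
        unit = _GGS_CODONS["G1"] + _GGS_CODONS["G2"] + _GGS_CODONS["S"]
        cds = unit * repeats
        pid = part_id or f"ggs{repeats}"
    elif kind == "TP_T":
        unit = _TPT_CODONS["T"] + _TPT_CODONS["P"]
        cds = unit * repeats + _TPT_CODONS["T"]
        pid = part_id or f"tpt{repeats}"
    else:
        raise DesignError(f"linker kind must be GGS or TP_T, got {kind!r}")
    from .partsynth import domesticate

    cds, _ = domesticate(cds, AssemblyConfig().domestication_enzymes)
    return Part(id=pid, role="linker", cds=cds)


# ---------------------------------------------------------------------------
# boundary-aware domestication
# ---------------------------------------------------------------------------

def _windows(prev_tail: str, cds: str, j_cur: str, j_next: str,
             marker_head: str) -> list[tuple[str, int, set]]:
    """(window, cds offset, designed (enzyme, pos) set) for one part.

    Windows cover every sequence context the part's edges ever sit in:
    fused after the previous ORF end, inside its donor, and (tail side)
    ahead of a subsequent fusion.
    """
    jc = junction_cassette(j_next)
    right = jc + marker_head
    lead = donor_lead(j_cur)
    e_next = get_enzyme(j_next)
    gap_next = min(e_next.cut_top, e_next.cut_bottom)

    def jc_recog_pos(left_len: int) -> int:
        return left_len + len(scar_overhang(j_next)) + gap_next

    w1 = prev_tail + SCAR_CODON + cds + right
    d1 = {(j_next, jc_recog_pos(len(prev_tail) + 3 + len(cds)))}
    w2 = lead + cds + right
    d2 = {(j_cur, 0), (j_next, jc_recog_pos(len(lead) + len(cds)))}
    w3 = prev_tail + SCAR_CODON + cds + SCAR_CODON
    return [
        (w1, len(prev_tail) + 3, d1),
        (w2, len(lead), d2),
        (w3, len(prev_tail) + 3, set()),
    ]


def _stray_hits(window: str, designed: set, enzymes) -> list[tuple[str, str, int]]:
    return [
        h for h in scan_forbidden_sites(window, enzymes)
        if (h[0], h[2]) not in designed
    ]


def _repair_boundaries(prev_tail: str, cds: str, j_cur: str, j_next: str,
                       marker_head: str, enzymes,
                       part_id: str) -> str:
    """Remove recognition sites spanning the part's junction contexts."""
    for _ in range(len(cds) + 10):
        windows = _windows(prev_tail, cds, j_cur, j_next, marker_head)
        strays = []
        for wi, (w, off, designed) in enumerate(windows):
            for enz, strand, pos in _stray_hits(w, designed, enzymes):
                strays.append((wi, pos, enz, off, len(w)))
        if not strays:
            return cds
        total = len(strays)
        wi, pos, enz, off, _ = min(strays)
        width = len(get_enzyme(enz).recognition)
        lo, hi = pos, pos + width
        if hi <= off or lo >= off + len(cds):
            raise DesignError(
                f"part {part_id}: stray {enz} site at window position {pos} "
                "lies wholly outside the editable part codons"
            )
        first = max(0, (lo - off) // 3)
        last = min(len(cds) // 3 - 1, (hi - 1 - off) // 3)
        candidates = []
        for ci in range(first, last + 1):
            old = cds[3 * ci : 3 * ci + 3]
            for new in SYNONYMOUS_CODONS[CODON_TABLE[old]]:
                if new == old:
                    continue
                trial = cds[: 3 * ci] + new + cds[3 * ci + 3 :]
                n_after = sum(
                    len(_stray_hits(w, d, enzymes))
                    for w, _, d in _windows(prev_tail, trial, j_cur, j_next,
                                            marker_head)
                )
                if n_after < total:
                    candidates.append((new, ci, trial))
        if not candidates:
            raise DesignError(
                f"part {part_id}: boundary {enz} site cannot be removed by "
                "synonymous substitution within the part"
            )
        _, _, cds = min(candidates)
    raise DesignError(f"part {part_id}: boundary repair did not converge")


# ---------------------------------------------------------------------------
# planning and execution
# ---------------------------------------------------------------------------

def plan_build(
    parts: Sequence[Part],
    config: AssemblyConfig | None = None,
    junction_overrides: dict[str, str] | None = None,
) -> BuildPlan:
    """Schedule one assembly cycle per part with alternating enzymes/markers.

    Raises :class:`DesignError` for an empty part list, undomesticated
    parts, or junction assignments whose identical overhangs would permit
    part skipping.
    """
    cfg = config or AssemblyConfig()
    overrides = junction_overrides or {}
    if not parts:
        raise DesignError("cannot plan an empty part list")
    for p in parts:
        internal = scan_forbidden_sites(p.cds, cfg.domestication_enzymes)
        if internal:
            raise DesignError(
                f"part {p.id} contains internal registry sites {internal}; "
                "domesticate it first"
            )

    junctions = [overrides.get(p.id) or cfg.junction(k)
                 for k, p in enumerate(parts, start=1)]
    for i in range(len(junctions) - 1):
        if junctions[i] == junctions[i + 1]:
            raise DesignError(
                f"junction clash between parts {parts[i].id} and "
                f"{parts[i + 1].id}: consecutive cycles share enzyme "
                f"{junctions[i]}, whose identical fusion overhangs would "
                "permit part skipping"
            )

    # boundary repair, left to right
    effective: list[str] = []
    prev_tail = (cfg.rbs_seq + "ATG" + cfg.orf_prefix)[-9:]
    for k, part in enumerate(parts, start=1):
        j_cur = junctions[k - 1]
        j_next = junctions[k] if k < len(junctions) else cfg.junction(k + 1)
        marker_head = cfg.marker_seq(cfg.marker(k))[:9]
        cds = _repair_boundaries(
            prev_tail, part.cds, j_cur, j_next, marker_head,
            cfg.domestication_enzymes, part.id,
        )
        effective.append(cds)
        prev_tail = cds[-9:]

    steps = tuple(
        (p.id, cfg.cycle_spec(k, junction_override=overrides.get(p.id)))
        for k, p in enumerate(parts, start=1)
    )
    markers = tuple(cfg.marker(k) for k in range(1, len(parts) + 1))

    predicted_seqs = []
    predicted_digests = []
    for k in range(1, len(parts) + 1):
        j_after = junctions[k] if k < len(junctions) else cfg.junction(k + 1)
        inter = build_reference_pz(
            orf_parts_so_far=effective[:k], marker=markers[k - 1],
            config=cfg, cycle_index=k + 1, junction=j_after,
        )
        predicted_seqs.append(inter.sequence)
        qc = analytical_digest(inter, [j_after, cfg.pz_backbone(k + 1)])
        predicted_digests.append(tuple(r["size_bp"] for r in qc))

    final_orf = "ATG" + cfg.orf_prefix + "".join(
        SCAR_CODON + cds for cds in effective
    )
    return BuildPlan(
        parts=tuple(parts),
        effective_cds=tuple(effective),
        steps=steps,
        marker_schedule=markers,
        predicted_intermediates=tuple(predicted_digests),
        predicted_sequences=tuple(predicted_seqs),
        final_orf=final_orf,
        final_protein=translate(final_orf),
        config=cfg,
    )


@dataclass(frozen=True)
class BuildResult:
    final_plasmid: DnaMolecule
    intermediates: tuple[DnaMolecule, ...]
    scar_report: ScarReport
    qc_table: tuple[tuple[dict, ...], ...]  # analytical digest rows per step


def simulate_build(plan: BuildPlan, config: AssemblyConfig | None = None) -> BuildResult:
    """Execute every cycle of ``plan`` through the full digestion/ligation
    pipeline, asserting survivor uniqueness and agreement with the plan."""
    cfg = config or plan.config
    pz = build_reference_pz(marker=cfg.marker(0), config=cfg, cycle_index=1)
    intermediates = []
    qc = []
    for k, ((part_id, spec), part, eff) in enumerate(
        zip(plan.steps, plan.parts, plan.effective_cds), start=1
    ):
        eff_part = Part(id=part.id, role=part.role, cds=eff) \
            if part.role in ("domain", "linker") else part
        j_after = (plan.steps[k][1].junction_enzyme if k < len(plan.steps)
                   else cfg.junction(k + 1))
        donor = build_reference_donor(
            part=eff_part,
            new_marker=spec.expected_marker,
            kind="pL" if part.role == "linker" else "pD",
            config=cfg, cycle_index=k,
            junction=spec.junction_enzyme, next_junction=j_after,
        )
        result = run_cycle(pz, donor, spec, cfg)
        if not result.ok:
            raise DesignError(
                f"build aborted at step {k} ({part_id}): "
                f"{result.diagnostics.get('error')}; diagnostics: "
                f"{result.diagnostics}"
            )
        pz = result.output_pz
        if pz.sequence != plan.predicted_sequences[k - 1]:
            raise DesignError(
                f"step {k}: simulated plasmid disagrees with planned sequence"
            )
        intermediates.append(pz)
        qc.append(tuple(analytical_digest(
            pz, [cfg.junction(k + 1), cfg.pz_backbone(k + 1)]
        )))

    report = verify_orf(pz, [
        Part(p.id, p.role, eff) for p, eff in zip(plan.parts, plan.effective_cds)
    ], config=cfg, plan=plan)
    orf_feats = [f for f in pz.features if f.key == "cds" and f.label == "orf"]
    orf_seq = pz.region(orf_feats[0].start, orf_feats[0].end)
    if orf_seq != plan.final_orf:
        raise DesignError("final ORF does not match the planned ORF")
    return BuildResult(pz, tuple(intermediates), report, tuple(qc))


def verify_orf(
    final_plasmid: DnaMolecule,
    parts: Sequence[Part],
    config: AssemblyConfig | None = None,
    plan: BuildPlan | None = None,
) -> ScarReport:
    """Check frame and scar structure of the assembled ORF.

    The ORF must decompose as start codon (plus optional prefix), then each
    part preceded by exactly one scar codon.  Any deviation raises
    :class:`DesignError` naming the first out-of-frame junction.
    """
    cfg = config or AssemblyConfig()
    orfs = [f for f in final_plasmid.features
            if f.key == "cds" and f.label == "orf"]
    if len(orfs) != 1:
        raise DesignError(
            f"expected exactly one ORF feature, found {len(orfs)}"
        )
    seq = final_plasmid.region(orfs[0].start, orfs[0].end)
    if len(seq) % 3:
        raise DesignError(f"ORF length {len(seq)} not divisible by 3: frameshift")
    head = "ATG" + cfg.orf_prefix
    if not seq.startswith(head):
        raise DesignError("ORF does not begin with the start module")
    idx = len(head)
    junctions = []
    protein_pos = len(head) // 3
    for i, part in enumerate(parts, start=1):
        if seq[idx : idx + 3] != SCAR_CODON:
            raise DesignError(
                f"frameshift at junction {i} (part {part.id}): expected scar "
                f"codon {SCAR_CODON} at nt {idx}, found {seq[idx:idx + 3]!r}"
            )
        if seq[idx + 3 : idx + 3 + len(part.cds)] != part.cds:
            raise DesignError(
                f"junction {i}: part {part.id} sequence mismatch at nt {idx + 3}"
            )
        if i > 1:  # the scar before part 1 belongs to the start module
            enzyme = (plan.steps[i - 1][1].junction_enzyme if plan is not None
                      else cfg.junction(i))
            junctions.append((protein_pos, CODON_TABLE[SCAR_CODON], enzyme))
        protein_pos += 1 + len(part.cds) // 3
        idx += 3 + len(part.cds)
    if idx != len(seq):
        raise DesignError(f"{len(seq) - idx} unexplained nt at ORF 3' end")
    return ScarReport(tuple(junctions))
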