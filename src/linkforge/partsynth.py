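"""Deterministic synthetic sequence generation and CDS domestication.

The framework's guarantees are sequence-agnostic, so all fixtures are
generated here: random domesticated coding sequences standing in for
fluorescent proteins, placeholder marker/ccdB/origin cassettes whose
function is carried by feature annotation rather than sequence realism,
and complete plasmid fixture sets for the assembly pipeline.  Every
generator is a pure function of its seed — identical inputs give
bit-identical output.

Domestication removes internal type IIS recognition sites from a CDS by
synonymous codon substitution, scanning left to right and choosing, among
all site-destroying synonymous codon swaps, the lexicographically smallest
replacement codon (leftmost position on ties).
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .seqmodel import (
    CODON_TABLE,
    SYNONYMOUS_CODONS,
    DesignError,
    IngestError,
    translate,
)
from .typeiis import TypeIISEnzyme, get_enzyme, registry, scan_forbidden_sites

__all__ = [
    "SynthSpec",
    "DomesticationEdit",
    "DomesticationError",
    "random_cds",
    "domesticate",
    "filler_dna",
    "coding_filler",
    "make_fixture_set",
]

_STOP_FREE_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")


class DomesticationError(DesignError):
    """A forbidden site cannot be destroyed by synonymous substitution."""


@dataclass(frozen=True)
class SynthSpec:
    seed: int
    n_residues: int
    gc_bounds: tuple[float, float] = (0.35, 0.65)
    forbidden_enzymes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_residues < 10:
            raise DesignError("random CDSs are at least 10 residues")


@dataclass(frozen=True)
class DomesticationEdit:
    codon_index: int
    old_codon: str
    new_codon: str
    site_enzyme: str
    site_position: int

    def __post_init__(self) -> None:
        if CODON_TABLE[self.old_codon] != CODON_TABLE[self.new_codon]:
            raise DesignError("domestication edit is not synonymous")


def _gc(s: str) -> float:
    return (s.count("G") + s.count("C")) / len(s) if s else 0.0


def _resolve(forbidden: Iterable[TypeIISEnzyme | str]) -> list[TypeIISEnzyme]:
    return [get_enzyme(e) if isinstance(e, str) else e for e in forbidden]


def domesticate(
    cds: str, forbidden: Iterable[TypeIISEnzyme | str]
) -> tuple[str, list[DomesticationEdit]]:
    """Remove forbidden recognition sites from ``cds``, translation intact.

    Greedy left-to-right: repeatedly take the leftmost remaining site on
    either strand, enumerate synonymous swaps of the codons it overlaps
    that destroy the site without introducing a new one, and apply the
    lexicographically smallest replacement codon.  Raises
    :class:`DomesticationError` for a stuck site.
    """
    if len(cds) % 3:
        raise IngestError("CDS length must be divisible by 3")
    enzymes = _resolve(forbidden)
    protein = translate(cds)
    seq = cds
    seen = {seq}
    edits: list[DomesticationEdit] = []
    for _ in range(3 * len(cds) + 10):  # generous loop guard
        hits = scan_forbidden_sites(seq, enzymes)
        if not hits:
            break
        target = hits[0]
        enz_name, _strand, pos = target
        width = len(get_enzyme(enz_name).recognition)
        candidates: list[tuple[str, int, str]] = []  # (new_codon, idx, new_seq)
        first_codon = pos // 3
        last_codon = (pos + width - 1) // 3
        for ci in range(first_codon, last_codon + 1):
            old = seq[3 * ci : 3 * ci + 3]
            for new in SYNONYMOUS_CODONS[CODON_TABLE[old]]:
                if new == old:
                    continue
                trial = seq[: 3 * ci] + new + seq[3 * ci + 3 :]
                if trial in seen:
                    continue
                # the swap must kill the target site; it may relocate a
                # problem (same total) but never make things worse
                trial_hits = scan_forbidden_sites(trial, enzymes)
                if target not in trial_hits and len(trial_hits) <= len(hits):
                    candidates.append((new, ci, trial))
        if not candidates:
            raise DomesticationError(
                f"site {enz_name} at {pos} cannot be removed by synonymous "
                "substitution (codons offer no site-destroying alternative)"
            )
        new, ci, trial = min(candidates)
        edits.append(
            DomesticationEdit(ci, seq[3 * ci : 3 * ci + 3], new, enz_name, pos)
        )
        seq = trial
        seen.add(seq)
    else:
        raise DomesticationError("domestication did not converge")
    assert translate(seq) == protein, "domestication altered the translation"
    return seq, edits


def random_cds(spec: SynthSpec):
    """Deterministic random domain Part: no internal stops, GC in bounds,
    domesticated against ``spec.forbidden_enzymes``."""
    from .planner import Part  # Part lives with the build planner

    rng = random.Random(spec.seed)
    lo, hi = spec.gc_bounds
    for _ in range(200):
        codons = [rng.choice(_STOP_FREE_CODONS) for _ in range(spec.n_residues)]
        cds = "".join(codons)
        if lo <= _gc(cds) <= hi:
            try:
                cds, _ = domesticate(cds, spec.forbidden_enzymes)
            except DomesticationError:
                continue  # a genuinely stuck site; draw a fresh sequence
            return Part(id=f"cds_s{spec.seed}", role="domain", cds=cds)
    raise DesignError(
        f"could not sample a CDS inside GC bounds {spec.gc_bounds} "
        f"(n_residues={spec.n_residues})"
    )


def _label_seed(label: str, salt: int = 0) -> int:
    return (zlib.crc32(label.encode()) + 0x9E37 * salt) % (2**31)


def filler_dna(label: str, n: int, forbidden: Sequence[str] | None = None) -> str:
    """Deterministic non-coding filler free of the forbidden recognitions."""
    forb = _resolve(forbidden if forbidden is not None else
                    [e.name for e in registry()])
    for salt in range(100):
        rng = random.Random(_label_seed(label, salt))
        s = "".join(rng.choice("ACGT") for _ in range(n))
        if not scan_forbidden_sites(s, forb):
            return s
    raise DesignError(f"could not generate clean filler for {label!r}")


def coding_filler(label: str, n_residues: int,
                  forbidden: Sequence[str] | None = None) -> str:
    """Deterministic placeholder ORF (ATG ... TAA), site-free, stop-free body."""
    forb = forbidden if forbidden is not None else [e.name for e in registry()]
    rng = random.Random(_label_seed(label, 77))
    body = "".join(rng.choice(_STOP_FREE_CODONS) for _ in range(n_residues))
    cds = "ATG" + body + "TAA"
    # TAA at the tail cannot complete a recognition site of this registry,
    # but the body might carry one: fix by synonymous substitution
    dom_body, _ = domesticate("ATG" + body, _resolve(forb))
    cds = dom_body + "TAA"
    if scan_forbidden_sites(cds, _resolve(forb)):
        # a site straddling the TAA boundary: retry with fresh body
        for salt in range(1, 50):
            rng = random.Random(_label_seed(label, 77 + salt))
            body = "".join(rng.choice(_STOP_FREE_CODONS) for _ in range(n_residues))
            dom_body, _ = domesticate("ATG" + body, _resolve(forb))
            cds = dom_body + "TAA"
            if not scan_forbidden_sites(cds, _resolve(forb)):
                break
        else:
            raise DesignError(f"could not build placeholder ORF {label!r}")
    return cds


def make_fixture_set(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write a mutually consistent GenBank fixture family to ``out_dir``.

    Contents: the empty-ORF destination plasmid, nine donors realising a
    five-domain / four-linker iterative build, four adaptor-flanked
    translation-unit plasmids (fluorescent-protein stand-ins) and a Golden
    Gate acceptor.  Byte-identical across runs with the same seed.
    """
    # imported here: cycle/planner/goldengate build on this module's primitives
    from .cycle import AssemblyConfig, build_reference_donor, build_reference_pz
    from .goldengate import build_acceptor, build_tu_plasmid, default_fusion_sites
    from .planner import Part, linker_cds, plan_build
    from .seqmodel import write_genbank

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = AssemblyConfig()
    written: dict[str, Path] = {}

    def emit(name: str, mol) -> None:
        p = out / f"{name}.gb"
        write_genbank(mol, p)
        written[name] = p

    domain = random_cds(
        SynthSpec(seed=seed, n_residues=236,
                  forbidden_enzymes=tuple(cfg.domestication_enzymes))
    ).cds
    parts = []
    for i in range(1, 6):
        parts.append(Part(id=f"dom{i}", role="domain", cds=domain))
        if i < 5:
            parts.append(linker_cds("GGS", 3, part_id=f"ggs{i}"))
    plan = plan_build(parts, cfg)

    pz = build_reference_pz(marker=cfg.markers[0], config=cfg)
    emit("pz_empty", pz)
    for k, (part, eff, spec) in enumerate(
        zip(plan.parts, plan.effective_cds, plan.steps_specs()), start=1
    ):
        donor = build_reference_donor(
            part=Part(part.id, part.role, eff), new_marker=spec.expected_marker,
            kind="pL" if part.role == "linker" else "pD",
            config=cfg, cycle_index=k,
        )
        emit(f"donor_{k:02d}_{part.id}", donor)

    sites = default_fusion_sites(5)
    fp_labels = ["fpRed", "fpOrange", "fpGreen", "fpCyan"]
    tus = []
    for i, lab in enumerate(fp_labels):
        fp = random_cds(
            SynthSpec(seed=seed + 101 + i, n_residues=236,
                      forbidden_enzymes=tuple(cfg.domestication_enzymes))
        ).cds
        tu = build_tu_plasmid(
            label=lab, cds=fp, head_site=sites[i], tail_site=sites[i + 1],
            config=cfg,
        )
        tus.append(tu)
        emit(f"tu_{i + 1}_{lab}", tu.molecule)
    acceptor = build_acceptor(first_site=sites[0], last_site=sites[-1], config=cfg)
    emit("acceptor", acceptor)
    return written
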