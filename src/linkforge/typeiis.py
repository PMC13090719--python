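"""Type IIS enzymes: registry, site finding, digestion, virtual gels.

A type IIS enzyme cuts outside its recognition sequence at a fixed offset,
leaving a programmable single-stranded overhang.  Geometry is expressed as
``recognition(cut_top/cut_bottom)``: both offsets are counted in nt
downstream of the recognition 3' end, with the bottom-strand cut projected
onto top-strand coordinates.  ``cut_bottom > cut_top`` leaves a 5'
overhang, ``<`` a 3' overhang, ``=`` a blunt cut.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

from .seqmodel import (
    BLUNT,
    DesignError,
    DnaMolecule,
    Fragment,
    IngestError,
    StickyEnd,
    revcomp,
)

__all__ = [
    "TypeIISEnzyme",
    "CutSite",
    "registry",
    "get_enzyme",
    "load_registry",
    "find_sites",
    "digest",
    "analytical_digest",
    "scan_forbidden_sites",
]


@dataclass(frozen=True)
class TypeIISEnzyme:
    name: str
    recognition: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self) -> None:
        if not self.recognition or set(self.recognition) - set("ACGT"):
            raise IngestError(f"enzyme {self.name}: bad recognition {self.recognition!r}")
        if self.cut_top < 0 or self.cut_bottom < 0:
            raise IngestError(f"enzyme {self.name}: negative cut offset")

    @property
    def overhang_length(self) -> int:
        return abs(self.cut_bottom - self.cut_top)

    @property
    def polarity(self) -> str:
        if self.cut_bottom > self.cut_top:
            return "five_prime"
        if self.cut_bottom < self.cut_top:
            return "three_prime"
        return "blunt"

    @property
    def max_reach(self) -> int:
        """Furthest cut coordinate downstream of the recognition 3' end."""
        return max(self.cut_top, self.cut_bottom)


@dataclass(frozen=True)
class CutSite:
    """A located, oriented recognition site with absolute cut coordinates.

    ``scissile_top``/``scissile_bottom`` are between-base indices on the
    top-strand coordinate frame of the molecule (mod length if circular).
    ``cleavable`` is False when a cut coordinate falls outside a linear
    molecule; such sites are reported but excluded from digestion.
    """

    enzyme: str
    strand: str  # plus | minus
    recognition_start: int
    recognition_end: int
    scissile_top: int
    scissile_bottom: int
    cleavable: bool = True

    @property
    def cut_min(self) -> int:
        return min(self.scissile_top, self.scissile_bottom)

    @property
    def cut_max(self) -> int:
        return max(self.scissile_top, self.scissile_bottom)

    @property
    def overhang_length(self) -> int:
        return self.cut_max - self.cut_min


_DEFAULT_REGISTRY: list[TypeIISEnzyme] | None = None


def load_registry(path: str | Path) -> list[TypeIISEnzyme]:
    """Load an enzyme table (TSV: name, recognition, cut_top, cut_bottom)."""
    enzymes = []
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t")
                if r and not r[0].startswith("#")]
    header, *body = rows
    if [h.strip() for h in header[:4]] != ["name", "recognition", "cut_top", "cut_bottom"]:
        raise IngestError(f"bad enzyme table header in {path}: {header!r}")
    for row in body:
        enzymes.append(
            TypeIISEnzyme(row[0].strip(), row[1].strip(), int(row[2]), int(row[3]))
        )
    names = [e.name for e in enzymes]
    if len(set(names)) != len(names):
        raise IngestError("duplicate enzyme names in registry")
    return enzymes


def registry() -> list[TypeIISEnzyme]:
    """The shipped enzyme registry (immutable copies, validated at load)."""
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        with resources.as_file(
            resources.files("linkforge.data").joinpath("enzymes.tsv")
        ) as p:
            _DEFAULT_REGISTRY = load_registry(p)
    return list(_DEFAULT_REGISTRY)


def get_enzyme(name: str, enzymes: Iterable[TypeIISEnzyme] | None = None) -> TypeIISEnzyme:
    for e in enzymes if enzymes is not None else registry():
        if e.name == name:
            return e
    raise IngestError(f"unknown enzyme {name!r}")


def _occurrences(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def find_sites(m: DnaMolecule, e: TypeIISEnzyme) -> list[CutSite]:
    """All recognition occurrences on both strands, with cut coordinates.

    Circular molecules include origin-spanning occurrences and cuts; on
    linear molecules a site whose scissile coordinates fall outside the
    sequence is flagged non-cleavable.
    """
    n = len(m)
    r = len(e.recognition)
    if m.is_circular:
        # extend enough to catch wrapped recognitions; duplicates collapse mod n
        search = m.sequence + m.sequence[: min(n, r - 1)]
    else:
        search = m.sequence
    sites: list[CutSite] = []
    for strand, recog in (("plus", e.recognition), ("minus", revcomp(e.recognition))):
        for a in _occurrences(search, recog):
            if a >= n:
                continue
            if strand == "plus":
                top = a + r + e.cut_top
                bottom = a + r + e.cut_bottom
            else:
                top = a - e.cut_bottom
                bottom = a - e.cut_top
            cleavable = True
            if m.is_circular:
                top %= n
                bottom %= n
            else:
                lo, hi = min(top, bottom), max(top, bottom)
                cleavable = 0 <= lo and hi <= n
            sites.append(
                CutSite(e.name, strand, a, a + r, top, bottom, cleavable)
            )
    sites.sort(key=lambda s: (s.recognition_start, s.strand))
    return sites


def _end_pair(seq: str, ov: int, polarity: str) -> tuple[StickyEnd, StickyEnd]:
    """(left_end_of_right_fragment, right_end_of_left_fragment) at one cut.

    ``seq`` here is the ``ov``-long overhang region read on the top strand.
    """
    if ov == 0:
        return BLUNT, BLUNT
    if polarity == "five_prime":
        return StickyEnd("five_prime", seq), StickyEnd("five_prime", revcomp(seq))
    return StickyEnd("three_prime", revcomp(seq)), StickyEnd("three_prime", seq)


def _cut_polarity(site: CutSite) -> str:
    if site.scissile_bottom > site.scissile_top:
        return "five_prime"
    if site.scissile_bottom < site.scissile_top:
        return "three_prime"
    return "blunt"


def _check_clashes(cuts: list[CutSite], n: int, circular: bool) -> None:
    spans = sorted(((c.cut_min, c.cut_max, c) for c in cuts),
                   key=lambda t: t[:2])
    for (lo1, hi1, c1), (lo2, hi2, c2) in zip(spans, spans[1:]):
        if lo2 < hi1:
            raise DesignError(
                f"scissile clash: {c1.enzyme} cut [{lo1},{hi1}) overlaps "
                f"{c2.enzyme} cut [{lo2},{hi2})"
            )
    if circular and len(spans) >= 2:
        lo_first, _, c1 = spans[0]
        _, hi_last, c2 = spans[-1]
        if hi_last > n and hi_last - n > lo_first:
            raise DesignError(
                f"scissile clash across origin: {c2.enzyme} overlaps {c1.enzyme}"
            )


def _fragment_features(m: DnaMolecule, start: int, end: int) -> tuple:
    """Features of m fully contained in the unwrapped window [start, end)."""
    n = len(m)
    out = []
    for f in m.features:
        for shift in ((0, n, -n) if m.is_circular else (0,)):
            fs, fe = f.start + shift, f.end + shift
            if start <= fs and fe <= end:
                out.append(f.shifted(shift - start))
                break
    return tuple(out)


def digest(
    m: DnaMolecule,
    enzymes: Iterable[TypeIISEnzyme | str],
) -> list[Fragment]:
    """Complete digestion of ``m`` with a set of enzymes.

    A circular molecule with k cleavable cuts yields k fragments (or is
    returned intact, flagged ``circular``, if uncut); a linear molecule
    yields k+1 fragments with the original outer ends.  Overlapping
    scissile positions from two sites raise :class:`DesignError`.
    """
    enz = [get_enzyme(e) if isinstance(e, str) else e for e in enzymes]
    cuts: list[CutSite] = []
    for e in enz:
        cuts.extend(s for s in find_sites(m, e) if s.cleavable)
    n = len(m)
    if not cuts:
        if m.is_circular:
            return [
                Fragment(
                    sequence=m.sequence, circular=True, id=f"{m.id}|uncut",
                    provenance=((m.id, (0, n)),), features=m.features,
                )
            ]
        return [
            Fragment(
                sequence=m.sequence, id=f"{m.id}|uncut",
                provenance=((m.id, (0, n)),), features=m.features,
            )
        ]

    # normalise circular cuts so cut_min is the sort key in [0, n)
    cuts.sort(key=lambda c: c.cut_min)
    _check_clashes(cuts, n, m.is_circular)

    frags: list[Fragment] = []

    def overhang_region(c: CutSite) -> str:
        return m.region(c.cut_min, c.cut_max)

    def circ_region(start: int, end: int) -> str:
        # like m.region but tolerates span up to n + 4: a single-cut
        # fragment's full span carries the same overhang at both ends
        return (m.sequence * 3)[start:end]

    if m.is_circular:
        k = len(cuts)
        for i, c in enumerate(cuts):
            nxt = cuts[(i + 1) % k]
            start = c.cut_min
            end = nxt.cut_min + (n if i == k - 1 else 0) + nxt.overhang_length
            seq = circ_region(start, end)
            left, _ = _end_pair(overhang_region(c), c.overhang_length, _cut_polarity(c))
            _, right = _end_pair(overhang_region(nxt), nxt.overhang_length, _cut_polarity(nxt))
            frags.append(
                Fragment(
                    sequence=seq, left_end=left, right_end=right,
                    provenance=((m.id, (start, end)),),
                    features=_fragment_features(m, start, end),
                    id=f"{m.id}|{i}",
                )
            )
    else:
        bounds = [0] + [c.cut_min for c in cuts] + [n]
        # fragment i spans bounds[i] .. (cut_i.cut_max or n)
        for i in range(len(cuts) + 1):
            start = bounds[i] if i == 0 else cuts[i - 1].cut_min
            end = n if i == len(cuts) else cuts[i].cut_max
            left = BLUNT if i == 0 else _end_pair(
                overhang_region(cuts[i - 1]), cuts[i - 1].overhang_length,
                _cut_polarity(cuts[i - 1]))[0]
            right = BLUNT if i == len(cuts) else _end_pair(
                overhang_region(cuts[i]), cuts[i].overhang_length,
                _cut_polarity(cuts[i]))[1]
            frags.append(
                Fragment(
                    sequence=m.sequence[start:end], left_end=left, right_end=right,
                    provenance=((m.id, (start, end)),),
                    features=_fragment_features(m, start, end),
                    id=f"{m.id}|{i}",
                )
            )
    return frags


def analytical_digest(
    m: DnaMolecule, enzymes: Iterable[TypeIISEnzyme | str]
) -> list[dict]:
    """Virtual-gel report: one row per fragment, sizes descending.

    Row keys: fragment_id, size_bp, left_polarity, left_overhang,
    right_polarity, right_overhang, uncut.
    """
    frags = digest(m, enzymes)
    rows = []
    for f in frags:
        rows.append(
            {
                "fragment_id": f.id,
                "size_bp": f.footprint if not f.circular else len(f),
                "left_polarity": f.left_end.polarity,
                "left_overhang": f.left_end.overhang,
                "right_polarity": f.right_end.polarity,
                "right_overhang": f.right_end.overhang,
                "uncut": f.id.endswith("|uncut"),
            }
        )
    rows.sort(key=lambda r: -r["size_bp"])
    return rows


def scan_forbidden_sites(
    seq: str, forbidden: Iterable[TypeIISEnzyme | str], circular: bool = False
) -> list[tuple[str, str, int]]:
    """(enzyme, strand, position) for every recognition occurrence."""
    mol = DnaMolecule("scan", seq, "circular" if circular else "linear")
    hits = []
    for e in forbidden:
        enz = get_enzyme(e) if isinstance(e, str) else e
        for s in find_sites(mol, enz):
            hits.append((enz.name, s.strand, s.recognition_start))
    return sorted(hits, key=lambda h: (h[2], h[0]))
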