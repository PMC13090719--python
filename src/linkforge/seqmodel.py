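"""Core DNA representations for type IIS assembly simulation.

A :class:`DnaMolecule` is an annotated double-stranded DNA, circular or
linear, stored as its top strand 5'->3'.  Digestion produces
:class:`Fragment` objects carrying explicit :class:`StickyEnd` overhangs;
ligation re-joins them.  All coordinates are 0-based, half-open; circular
coordinates are reduced modulo the molecule length.

Fragment sequences use the *full-span* convention: ``Fragment.sequence`` is
the top-strand reading of the whole footprint between the outermost cut
coordinates, including positions where only the bottom strand is physically
present (read as the complement).  Under this convention joining two
compatible fragments is plain concatenation with the shared overhang bases
written once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = [
    "LinkforgeError",
    "IngestError",
    "DesignError",
    "Feature",
    "DnaMolecule",
    "StickyEnd",
    "Fragment",
    "BLUNT",
    "revcomp",
    "translate",
    "rotate_canonical",
    "canonical_sequence",
    "ends_compatible",
    "read_genbank",
    "write_genbank",
    "read_fasta",
]


class LinkforgeError(Exception):
    """Base class for all errors raised by this package."""


class IngestError(LinkforgeError):
    """Malformed input sequence or file."""


class DesignError(LinkforgeError):
    """A construct or reaction violates the framework's design rules."""


_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_DNA_ALPHABET = frozenset("ACGT")

#: codon -> amino acid, stops rendered as '*'
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
CODON_TABLE.update({c: "*" for c in standard_dna_table.stop_codons})

#: amino acid -> sorted list of codons (includes '*')
SYNONYMOUS_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TABLE.items()):
    SYNONYMOUS_CODONS.setdefault(_aa, []).append(_codon)


def _check_dna(s: str) -> str:
    bad = set(s) - _DNA_ALPHABET
    if bad:
        raise IngestError(
            f"sequence contains non-ACGT characters: {sorted(bad)!r} "
            "(ambiguity codes are rejected; supply fully specified sequence)"
        )
    return s


def revcomp(s: str) -> str:
    """Reverse complement of a top-strand string (involution)."""
    _check_dna(s)
    return s.translate(_COMPLEMENT)[::-1]


def translate(s: str, frame: int = 0) -> str:
    """Standard-code translation of complete codons from ``frame``.

    Trailing partial codons are ignored; stop codons render as ``'*'``.
    """
    _check_dna(s)
    if len(s) - frame < 3:
        raise IngestError(f"fewer than one codon after frame offset {frame}")
    out = []
    for i in range(frame, len(s) - 2, 3):
        out.append(CODON_TABLE[s[i : i + 3]])
    return "".join(out)


@dataclass(frozen=True)
class Feature:
    """A located annotation on a molecule.

    ``key`` is one of {marker, ccdb, cds, rbs, stop, adaptor, site, origin,
    part}.  ``span`` is (start, end) 0-based half-open on the top strand;
    a circular span may wrap once, in which case ``end > molecule length``
    and positions are understood modulo the length.
    """

    key: str
    label: str
    start: int
    end: int
    strand: int = 1
    qualifiers: tuple[tuple[str, str], ...] = ()

    KEYS = frozenset(
        {"marker", "ccdb", "cds", "rbs", "stop", "adaptor", "site", "origin", "part"}
    )

    def __post_init__(self) -> None:
        if self.key not in self.KEYS:
            raise IngestError(f"unknown feature key {self.key!r}")
        if self.end <= self.start:
            raise IngestError(f"feature {self.label!r} has empty span")
        if self.key == "marker" and "resistance" not in dict(self.qualifiers):
            raise IngestError(
                f"marker feature {self.label!r} must carry a 'resistance' qualifier"
            )

    def qualifier(self, name: str) -> str | None:
        return dict(self.qualifiers).get(name)

    def shifted(self, offset: int) -> "Feature":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class DnaMolecule:
    """Annotated dsDNA; ``sequence`` is the top strand 5'->3'."""

    id: str
    sequence: str
    topology: str = "linear"  # or "circular"
    features: tuple[Feature, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise IngestError(f"molecule {self.id!r} has empty sequence")
        _check_dna(self.sequence)
        if self.topology not in ("circular", "linear"):
            raise IngestError(f"topology must be circular or linear, got {self.topology!r}")
        n = len(self.sequence)
        for f in self.features:
            if self.topology == "linear":
                if f.start < 0 or f.end > n:
                    raise IngestError(f"feature {f.label!r} outside linear bounds")
            else:
                if f.start < 0 or f.start >= n or f.end - f.start > n:
                    raise IngestError(f"feature {f.label!r} wraps more than once")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def region(self, start: int, end: int) -> str:
        """Top-strand sequence of [start, end); wraps on circular molecules."""
        n = len(self.sequence)
        if self.topology == "linear":
            if start < 0 or end > n or end < start:
                raise IngestError(f"region [{start},{end}) outside linear molecule")
            return self.sequence[start:end]
        span = end - start
        if span < 0 or span > n:
            raise IngestError(f"bad circular region [{start},{end})")
        start %= n
        return (self.sequence + self.sequence)[start : start + span]

    def features_by_key(self, key: str) -> list[Feature]:
        return [f for f in self.features if f.key == key]


def rotate_canonical(m: DnaMolecule) -> DnaMolecule:
    """Deterministic canonical form of a circular molecule.

    The canonical sequence is the lexicographically smallest rotation over
    both strands; two circular molecules are equivalent iff their canonical
    sequences are identical.  Features are not remapped (the canonical form
    is an identity key, not a working coordinate system).
    """
    if not m.is_circular:
        raise DesignError(f"rotate_canonical requires a circular molecule, got {m.id!r}")
    return replace(m, sequence=canonical_sequence(m.sequence), features=())


def canonical_sequence(s: str) -> str:
    """Smallest rotation of min(s, revcomp(s)) — circular identity key."""
    n = len(s)
    best = None
    for strand in (s, revcomp(s)):
        doubled = strand + strand
        for i in range(n):
            cand = doubled[i : i + n]
            if best is None or cand < best:
                best = cand
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# sticky ends and fragments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StickyEnd:
    """A fragment terminus.

    ``overhang`` is read 5'->3' on the protruding strand; empty iff blunt.
    """

    polarity: str  # five_prime | three_prime | blunt
    overhang: str = ""

    def __post_init__(self) -> None:
        if self.polarity not in ("five_prime", "three_prime", "blunt"):
            raise IngestError(f"bad polarity {self.polarity!r}")
        if self.polarity == "blunt" and self.overhang:
            raise IngestError("blunt end cannot carry an overhang")
        if self.polarity != "blunt" and not 1 <= len(self.overhang) <= 4:
            raise IngestError("sticky overhangs are 1-4 nt in this framework")
        if self.overhang:
            _check_dna(self.overhang)

    def __len__(self) -> int:
        return len(self.overhang)


BLUNT = StickyEnd("blunt")


def ends_compatible(a: StickyEnd, b: StickyEnd) -> bool:
    """True iff the two ends can anneal and be ligated.

    Requires identical polarity, identical nonzero length, and the two
    protruding strands to be reverse complements.  Blunt ends never ligate
    in this simulator.
    """
    if a.polarity == "blunt" or b.polarity == "blunt":
        return False
    return (
        a.polarity == b.polarity
        and len(a) == len(b)
        and a.overhang == revcomp(b.overhang)
    )


@dataclass(frozen=True)
class Fragment:
    """A digestion product (or joined chain of them).

    ``sequence`` is the full-span top-strand reading including overhang
    regions at both ends (see module docstring).  ``circular`` marks an
    uncut circular molecule passed through digestion intact; such a
    fragment has blunt placeholder ends and can only "ligate" to itself
    (it already is a circle).
    """

    sequence: str
    left_end: StickyEnd = BLUNT
    right_end: StickyEnd = BLUNT
    provenance: tuple[tuple[str, tuple[int, int]], ...] = ()
    features: tuple[Feature, ...] = ()
    circular: bool = False
    id: str = ""

    def __post_init__(self) -> None:
        _check_dna(self.sequence)
        core = len(self.sequence) - len(self.left_end) - len(self.right_end)
        if not self.circular and core < 1:
            raise DesignError(
                f"fragment {self.id or self.sequence[:12]!r}: duplex core would be "
                f"{core} bp (overhangs overlap)"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def footprint(self) -> int:
        """Length contribution that sums to molecule length over a digest."""
        return len(self.sequence) - len(self.right_end)

    def flipped(self) -> "Fragment":
        """The same physical molecule read from the other strand."""
        n = len(self.sequence)
        feats = tuple(
            replace(f, start=n - f.end, end=n - f.start, strand=-f.strand)
            for f in self.features
        )
        return Fragment(
            sequence=revcomp(self.sequence),
            left_end=self.right_end,
            right_end=self.left_end,
            provenance=self.provenance,
            features=feats,
            circular=self.circular,
            id=self.id + "'" if self.id else "",
        )

    def end_overhang_from_sequence(self, side: str) -> str:
        """Re-derive an overhang string from the stored sequence (invariant)."""
        end = self.left_end if side == "left" else self.right_end
        k = len(end)
        if k == 0:
            return ""
        if side == "left":
            region = self.sequence[:k]
            return region if end.polarity == "five_prime" else revcomp(region)
        region = self.sequence[-k:]
        return revcomp(region) if end.polarity == "five_prime" else region


# ---------------------------------------------------------------------------
# GenBank / FASTA I/O
# ---------------------------------------------------------------------------

# our feature key <-> GenBank feature type.  The `note="key:<k>"` qualifier
# is authoritative on read; the type mapping is the fallback for foreign
# files.  This table is a repo convention (documented in docs/methods.md).
_KEY_TO_GB = {
    "marker": "CDS",
    "ccdb": "CDS",
    "cds": "CDS",
    "part": "CDS",
    "rbs": "RBS",
    "stop": "misc_feature",
    "adaptor": "misc_feature",
    "site": "protein_bind",
    "origin": "rep_origin",
}
_GB_TO_KEY = {"RBS": "rbs", "rep_origin": "origin", "protein_bind": "site"}


def _feature_to_gb(f: Feature, n: int) -> SeqFeature:
    if f.end <= n:
        loc = FeatureLocation(f.start, f.end, strand=f.strand)
    else:  # wraps the origin once
        loc = CompoundLocation(
            [FeatureLocation(f.start, n, strand=f.strand),
             FeatureLocation(0, f.end - n, strand=f.strand)]
        )
    quals: dict[str, list[str]] = {"label": [f.label], "note": [f"key:{f.key}"]}
    for k, v in f.qualifiers:
        quals.setdefault(k, []).append(v)
    return SeqFeature(location=loc, type=_KEY_TO_GB[f.key], qualifiers=quals)


def _gb_to_feature(sf: SeqFeature, n: int) -> Feature | None:
    quals = {k: v[0] for k, v in sf.qualifiers.items() if v}
    key = None
    note = quals.pop("note", "")
    if note.startswith("key:"):
        key = note[4:]
    if key is None:
        label_lc = quals.get("label", "").lower()
        if "ccdb" in label_lc:
            key = "ccdb"
        elif sf.type == "CDS":
            key = "marker" if "resistance" in quals else "cds"
        else:
            key = _GB_TO_KEY.get(sf.type)
    if key is None or key not in Feature.KEYS:
        return None
    parts = sorted(sf.location.parts, key=lambda p: int(p.start))
    start = int(parts[0].start)
    end = int(parts[-1].end)
    if len(parts) == 2 and int(parts[0].start) == 0 and int(parts[-1].end) == n:
        # origin-wrapping compound span
        start = int(parts[-1].start)
        end = n + int(parts[0].end)
    label = quals.pop("label", key)
    strand = sf.location.strand or 1
    return Feature(
        key=key, label=label, start=start, end=end, strand=strand,
        qualifiers=tuple(sorted(quals.items())),
    )


def write_genbank(molecules: DnaMolecule | Iterable[DnaMolecule], path: str | Path) -> None:
    if isinstance(molecules, DnaMolecule):
        molecules = [molecules]
    records = []
    for m in molecules:
        rec = SeqRecord(
            Seq(m.sequence), id=m.id, name=m.id[:16] or "plasmid", description="",
            annotations={"molecule_type": "DNA", "topology": m.topology},
        )
        rec.features = [_feature_to_gb(f, len(m)) for f in m.features]
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


def read_genbank(path: str | Path) -> list[DnaMolecule]:
    """Read GenBank records; topology comes from the LOCUS line."""
    out = []
    for rec in SeqIO.parse(str(path), "genbank"):
        seq = _check_dna(str(rec.seq).upper())
        topology = rec.annotations.get("topology", "linear")
        feats = []
        for sf in rec.features:
            if sf.type == "source":
                continue
            f = _gb_to_feature(sf, len(seq))
            if f is not None:
                feats.append(f)
        out.append(DnaMolecule(rec.id, seq, topology, tuple(feats)))
    if not out:
        raise IngestError(f"no GenBank records in {path}")
    return out


def read_fasta(path: str | Path, topology: str = "linear") -> list[DnaMolecule]:
    out = [
        DnaMolecule(rec.id, _check_dna(str(rec.seq).upper()), topology)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not out:
        raise IngestError(f"no FASTA records in {path}")
    return out
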