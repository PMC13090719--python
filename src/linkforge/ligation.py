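"""Overhang-directed ligation and exhaustive circular-product enumeration.

:func:`enumerate_circular` is the brute-force oracle of the package: it
lists every distinct circular molecule formable from a pool of sticky-ended
fragments, deduplicated by canonical rotation/strand identity.  Every
designed assembly product elsewhere in the package is required (and tested)
to be an element of this enumeration on the same fragment pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .seqmodel import (
    DesignError,
    DnaMolecule,
    Feature,
    Fragment,
    LinkforgeError,
    canonical_sequence,
    ends_compatible,
)

__all__ = [
    "LigationError",
    "EnumerationLimitError",
    "LigationPool",
    "CircularProduct",
    "join",
    "circularize",
    "enumerate_circular",
    "religation_check",
]


class LigationError(DesignError):
    """Attempted join between incompatible ends."""


class EnumerationLimitError(LinkforgeError):
    """Combinatorial guard tripped during product enumeration."""


@dataclass(frozen=True)
class LigationPool:
    fragments: tuple[Fragment, ...]
    allow_rotation_duplicates: bool = False

    def __post_init__(self) -> None:
        for f in self.fragments:
            if not f.circular and len(f.left_end) == 0 and len(f.right_end) == 0:
                raise DesignError(
                    f"fragment {f.id!r} is blunt at both ends and can never "
                    "circularize in this simulator"
                )


@dataclass(frozen=True)
class CircularProduct:
    """A circular ligation product with its build recipe."""

    molecule: DnaMolecule
    composition: tuple[tuple[str, str], ...]  # (fragment id, as_is|flipped)
    canonical_form: str

    def __len__(self) -> int:
        return len(self.molecule)


def join(a: Fragment, b: Fragment, orientation_b: str = "as_is") -> Fragment:
    """Ligate ``b`` (optionally flipped) onto the right end of ``a``.

    Under the full-span sequence convention the junction overhang bases are
    written exactly once; outer ends are preserved.
    """
    if a.circular or b.circular:
        raise LigationError("cannot join an already-circular molecule")
    if orientation_b == "flipped":
        b = b.flipped()
    elif orientation_b != "as_is":
        raise LigationError(f"bad orientation {orientation_b!r}")
    if not ends_compatible(a.right_end, b.left_end):
        raise LigationError(
            f"incompatible ends: right {a.right_end.polarity}/"
            f"{a.right_end.overhang or '-'} vs left {b.left_end.polarity}/"
            f"{b.left_end.overhang or '-'}"
        )
    k = len(a.right_end)
    assert a.sequence[-k:] == b.sequence[:k], "full-span junction mismatch"
    offset = len(a.sequence) - k
    feats = a.features + tuple(f.shifted(offset) for f in b.features)
    return Fragment(
        sequence=a.sequence + b.sequence[k:],
        left_end=a.left_end,
        right_end=b.right_end,
        provenance=a.provenance + b.provenance,
        features=feats,
        id=f"{a.id}+{b.id}",
    )


def circularize(chain: Fragment, product_id: str = "") -> DnaMolecule:
    """Close a linear chain whose outer ends are mutually compatible."""
    if not ends_compatible(chain.right_end, chain.left_end):
        raise LigationError(
            f"cannot self-circularize: {chain.right_end.overhang or '-'} vs "
            f"{chain.left_end.overhang or '-'}"
        )
    k = len(chain.left_end)
    assert chain.sequence[:k] == chain.sequence[-k:]
    return DnaMolecule(
        id=product_id or f"circle({chain.id})",
        sequence=chain.sequence[:-k],
        topology="circular",
        features=chain.features,
    )


def _as_product(mol: DnaMolecule, composition) -> CircularProduct:
    return CircularProduct(
        molecule=mol,
        composition=tuple(composition),
        canonical_form=canonical_sequence(mol.sequence),
    )


def enumerate_circular(
    pool: LigationPool | list[Fragment],
    max_fragments: int,
    frontier_limit: int = 10**6,
) -> list[CircularProduct]:
    """All distinct circular products from <= ``max_fragments`` fragment uses.

    Each pool fragment is used at most once per product (list it twice for
    explicit multiplicity).  Both orientations are explored, deterministic
    order: fragments in input order, ``as_is`` before ``flipped``.  Distinct
    means distinct canonical (rotation + strand-flip) form.  Intact circular
    pool members pass through as single-"fragment" products.
    """
    if isinstance(pool, list):
        pool = LigationPool(tuple(pool))
    if max_fragments < 1:
        raise DesignError("max_fragments must be >= 1")
    frags = pool.fragments
    products: dict[str, CircularProduct] = {}
    frontier = 0

    def note(mol: DnaMolecule, composition) -> None:
        prod = _as_product(mol, composition)
        products.setdefault(prod.canonical_form, prod)

    def extend(chain: Fragment, used: set[int], start: int, composition) -> None:
        nonlocal frontier
        frontier += 1
        if frontier > frontier_limit:
            raise EnumerationLimitError(
                f"ligation search frontier exceeded {frontier_limit} partial paths"
            )
        if ends_compatible(chain.right_end, chain.left_end):
            note(circularize(chain), composition)
        if len(used) >= max_fragments:
            return
        for j in range(len(frags)):
            # rotations are collapsed by anchoring each product at its
            # lowest-index member; only higher indices may extend
            if j in used or j <= start:
                continue
            nxt = frags[j]
            if nxt.circular:
                continue
            for orient in ("as_is", "flipped"):
                cand = nxt if orient == "as_is" else nxt.flipped()
                if ends_compatible(chain.right_end, cand.left_end):
                    extend(
                        join(chain, nxt, orient),
                        used | {j},
                        start,
                        composition + [(nxt.id, orient)],
                    )

    for i, f in enumerate(frags):
        if f.circular:
            note(
                DnaMolecule(f.id or f"pool{i}", f.sequence, "circular", f.features),
                [(f.id, "as_is")],
            )
            continue
        for orient in ("as_is", "flipped"):
            chain = f if orient == "as_is" else f.flipped()
            extend(chain, {i}, i, [(f.id, orient)])

    return list(products.values())


def religation_check(m: DnaMolecule, enzymes) -> bool:
    """Digest ``m`` and ask whether re-ligation can restore it.

    True iff the canonical form of ``m`` is among the circular products of
    its own digest — digestion is invertible by ligation.
    """
    from .typeiis import digest  # local import; typeiis does not need us

    if not m.is_circular:
        raise DesignError("religation_check requires a circular molecule")
    frags = digest(m, enzymes)
    products = enumerate_circular(LigationPool(tuple(frags)), max_fragments=len(frags))
    target = canonical_sequence(m.sequence)
    return any(p.canonical_form == target for p in products)
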