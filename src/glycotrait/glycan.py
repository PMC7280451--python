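"""Glycan tree model, condensed-notation parser and mass arithmetic.

Released, reduced glycans are modelled as rooted trees of monosaccharide
residues.  The reducing end (an open-ring alditol after NaBH4 reduction) is
the tree root; every other residue is attached to its parent through a
glycosidic linkage recorded as (child anomeric position, parent position).

The text notation is a condensed-IUPAC dialect: residues are written
child-first toward the root, e.g. ``Neu5Acα2-3Galβ1-4Glc-ol`` (GM3 glycan),
with branches in parentheses attached to the residue that follows them,
``Galβ1-4(Fucα1-3)GlcNAc…`` (Lewis X).  ``?`` marks an unknown anomer or
position and the suffix ``-ol`` marks the reducing-end alditol.  ``a``/``b``
are accepted as ASCII aliases for α/β on input.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional

__all__ = [
    "Anomer",
    "GlycanContext",
    "Residue",
    "Linkage",
    "GlycanNode",
    "Glycan",
    "GlycanComposition",
    "GlycanParseError",
    "parse_glycan",
    "serialize_glycan",
    "compute_composition",
    "compute_mass",
    "match_compositions",
    "RESIDUE_CLASS",
    "RESIDUE_MASS",
    "WATER",
    "REDUCTION",
    "PROTON",
]


class Anomer(str, Enum):
    alpha = "α"
    beta = "β"
    unknown = "?"


class GlycanContext(str, Enum):
    O_GLYCAN = "O_glycan"
    GSL = "GSL"
    FREE = "free"


#: residue alphabet and generic composition classes
RESIDUE_CLASS = {
    "Gal": "Hex",
    "Glc": "Hex",
    "GalNAc": "HexNAc",
    "GlcNAc": "HexNAc",
    "Fuc": "dHex",
    "Neu5Ac": "Neu5Ac",
}

# Monoisotopic residue masses (Da), i.e. the free monosaccharide minus water,
# derived from atomic monoisotopic masses (C 12, H 1.00782503, N 14.00307401,
# O 15.99491462).
_H = 1.007825031898
_C = 12.0
_N = 14.003074004251
_O = 15.994914619257


def _formula_mass(c: int, h: int, n: int, o: int) -> float:
    return c * _C + h * _H + n * _N + o * _O


RESIDUE_MASS = {
    "Hex": _formula_mass(6, 10, 0, 5),      # 162.05282
    "HexNAc": _formula_mass(8, 13, 1, 5),   # 203.07937
    "dHex": _formula_mass(6, 10, 0, 4),     # 146.05791
    "Neu5Ac": _formula_mass(11, 17, 1, 8),  # 291.09542
}
WATER = _formula_mass(0, 2, 0, 1)           # 18.01056
REDUCTION = 2 * _H                          # +2.01565 on the reduced end
PROTON = 1.007276466621                     # [M-H]- subtracts one proton


class GlycanParseError(ValueError):
    """Raised for text that violates the condensed-notation grammar."""


@dataclass(frozen=True)
class Residue:
    identity: str
    anomer: Anomer = Anomer.unknown
    alditol: bool = False

    def __post_init__(self) -> None:
        if self.identity not in RESIDUE_CLASS:
            raise GlycanParseError(f"unknown residue {self.identity!r}")
        if self.alditol and self.identity == "Neu5Ac":
            raise GlycanParseError("Neu5Ac cannot be the reduced alditol")


@dataclass(frozen=True)
class Linkage:
    """child anomeric position -> parent position; None = unknown position."""

    child_position: Optional[int]
    parent_position: Optional[int]

    def __post_init__(self) -> None:
        if self.child_position is not None and self.child_position not in (1, 2):
            raise GlycanParseError(
                f"anomeric position must be 1 or 2, got {self.child_position}"
            )
        if self.parent_position is not None and not 2 <= self.parent_position <= 8:
            raise GlycanParseError(
                f"parent position must be in 2..8, got {self.parent_position}"
            )


@dataclass
class GlycanNode:
    residue: Residue
    linkage: Optional[Linkage] = None  # linkage to parent; None at the root
    children: list["GlycanNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["GlycanNode"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class Glycan:
    root: GlycanNode
    context: GlycanContext = GlycanContext.FREE

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        for node in self.root.walk():
            if node is not self.root and node.residue.alditol:
                raise GlycanParseError("alditol residue on a non-root position")
            if node is not self.root and node.linkage is None:
                raise GlycanParseError("non-root node without a linkage")
            if node.residue.identity == "Neu5Ac" and node.linkage is not None:
                if node.linkage.child_position not in (None, 2):
                    raise GlycanParseError("Neu5Ac links only via position 2")
            occupied: set[int] = set()
            for child in node.children:
                pos = child.linkage.parent_position if child.linkage else None
                if pos is not None:
                    if pos in occupied:
                        raise GlycanParseError(
                            f"duplicate occupied position {pos} on "
                            f"{node.residue.identity}"
                        )
                    occupied.add(pos)
        if self.context is GlycanContext.O_GLYCAN:
            if self.root.residue.identity != "GalNAc" or not self.root.residue.alditol:
                raise GlycanParseError("O-glycan root must be GalNAc-ol")
        elif self.context is GlycanContext.GSL:
            if self.root.residue.identity not in ("Glc", "Gal") or not (
                self.root.residue.alditol
            ):
                raise GlycanParseError("GSL root must be Glc-ol or Gal-ol")

    # -- convenience -----------------------------------------------------
    def nodes(self) -> list[GlycanNode]:
        return list(self.root.walk())

    def __len__(self) -> int:
        return sum(1 for _ in self.root.walk())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Glycan):
            return NotImplemented
        return (
            self.context is other.context
            and serialize_glycan(self) == serialize_glycan(other)
        )

    def __hash__(self) -> int:
        return hash((self.context, serialize_glycan(self)))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Glycan({serialize_glycan(self)!r}, {self.context.value})"


GlycanComposition = dict  # {"Hex": int, "HexNAc": int, "dHex": int, "Neu5Ac": int}


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

# longest residue names first so Gal does not shadow GalNAc
_RESIDUE_RE = "|".join(sorted(RESIDUE_CLASS, key=len, reverse=True))
_UNIT_RE = re.compile(
    rf"(?P<res>{_RESIDUE_RE})"
    r"(?:(?P<anomer>[abαβ?])(?P<cpos>[12?])-(?P<ppos>[2-8?])?)?"
)


_ANOMER_MAP = {
    "a": Anomer.alpha, "α": Anomer.alpha,
    "b": Anomer.beta, "β": Anomer.beta,
    "?": Anomer.unknown,
}


def _parse_chain(text: str, original: str) -> tuple[GlycanNode, Optional[Linkage]]:
    """Parse one chain (branches at any depth) into its last residue.

    Returns the node for the chain's final residue together with that
    residue's trailing linkage (present inside a branch, absent at the
    root of the whole glycan).
    """
    pending: list[GlycanNode] = []  # branch children awaiting the next residue
    prev: Optional[GlycanNode] = None  # chain child of the next residue
    prev_link: Optional[Linkage] = None
    i, n = 0, len(text)
    while True:
        # branch groups attach to the residue that follows them
        while i < n and text[i] == "(":
            depth, j = 1, i + 1
            while j < n and depth:
                if text[j] == "(":
                    depth += 1
                elif text[j] == ")":
                    depth -= 1
                j += 1
            if depth:
                raise GlycanParseError(f"unbalanced parenthesis in {original!r}")
            branch, branch_link = _parse_chain(text[i + 1 : j - 1], original)
            if branch_link is None:
                raise GlycanParseError(
                    f"branch without a linkage to its parent in {original!r}"
                )
            branch.linkage = branch_link
            pending.append(branch)
            i = j
        m = _UNIT_RE.match(text, i)
        if not m or m.end() == i:
            raise GlycanParseError(
                f"cannot parse residue at {text[i:]!r} in {original!r}"
            )
        i = m.end()
        alditol = False
        if text.startswith("-ol", i):
            alditol = True
            i += 3
        link: Optional[Linkage] = None
        anomer = Anomer.unknown
        if m.group("anomer") is not None:
            anomer = _ANOMER_MAP[m.group("anomer")]
            cpos = None if m.group("cpos") == "?" else int(m.group("cpos"))
            raw_ppos = m.group("ppos")
            if raw_ppos is None:
                raise GlycanParseError(f"dangling linkage in {original!r}")
            ppos = None if raw_ppos == "?" else int(raw_ppos)
            link = Linkage(cpos, ppos)
        node = GlycanNode(Residue(m.group("res"), anomer, alditol))
        if prev is not None:
            prev.linkage = prev_link
            node.children.append(prev)
        node.children.extend(pending)
        pending = []
        if i >= n:
            return node, link
        if link is None:
            raise GlycanParseError(
                f"residue {m.group('res')!r} lacks a linkage in {original!r}"
            )
        prev, prev_link = node, link


def parse_glycan(text: str, context: GlycanContext | str = GlycanContext.FREE) -> Glycan:
    """Parse condensed notation into a :class:`Glycan`.

    ``parse_glycan(serialize_glycan(g), g.context) == g`` for every valid
    glycan, and ``serialize_glycan(parse_glycan(s)) == s`` on canonical text.
    """
    context = GlycanContext(context)
    text = text.strip()
    if not text:
        raise GlycanParseError("empty glycan text")
    if text.endswith("-"):
        raise GlycanParseError(f"dangling linkage at end of {text!r}")
    root, trailing = _parse_chain(text, text)
    if trailing is not None:
        raise GlycanParseError(f"dangling linkage at end of {text!r}")
    return Glycan(root, context)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _child_sort_key(child: GlycanNode):
    pos = child.linkage.parent_position if child.linkage else None
    # descending known parent position, unknown last, ties by residue name
    # then by full canonical subtree text (total order)
    return (pos is None, -(pos or 0), child.residue.identity, _serialize_node(child))


def _serialize_node(node: GlycanNode) -> str:
    children = sorted(node.children, key=_child_sort_key)
    backbone = children[-1:] if children else []
    branches = children[:-1]
    parts = []
    if backbone:
        parts.append(_serialize_node(backbone[0]))
    for branch in branches:
        parts.append("(" + _serialize_node(branch) + ")")
    token = node.residue.identity
    if node.linkage is not None:
        cpos = "?" if node.linkage.child_position is None else node.linkage.child_position
        ppos = "?" if node.linkage.parent_position is None else node.linkage.parent_position
        token += f"{node.residue.anomer.value}{cpos}-{ppos}"
    if node.residue.alditol:
        token += "-ol"
    return "".join(parts) + token


def serialize_glycan(g: Glycan) -> str:
    """Canonical condensed notation: branches ordered by descending parent
    position (unknown last, ties by residue name); the lowest-position child
    continues the backbone, the rest are parenthesised."""
    return _serialize_node(g.root)


# ---------------------------------------------------------------------------
# composition and mass
# ---------------------------------------------------------------------------

def compute_composition(g: Glycan) -> GlycanComposition:
    """Collapse residue identities to the generic classes used for
    composition matching: Gal/Glc -> Hex, GalNAc/GlcNAc -> HexNAc,
    Fuc -> dHex."""
    counts = {"Hex": 0, "HexNAc": 0, "dHex": 0, "Neu5Ac": 0}
    for node in g.root.walk():
        counts[RESIDUE_CLASS[node.residue.identity]] += 1
    return counts


def compute_mass(
    composition: GlycanComposition,
    reduced: bool = True,
    ion: str = "neutral",
) -> float:
    """Monoisotopic mass of a glycan composition in Da.

    mass = sum(count * residue) + water (+ 2H if the reducing end is an
    alditol) (- one proton for the [M-H]- ion).
    """
    if ion not in ("neutral", "deprotonated"):
        raise ValueError(f"unknown ion mode {ion!r}")
    total_count = sum(composition.get(k, 0) for k in RESIDUE_MASS)
    if total_count <= 0:
        raise ValueError("empty composition has no mass")
    mass = sum(RESIDUE_MASS[k] * composition.get(k, 0) for k in RESIDUE_MASS)
    mass += WATER
    if reduced:
        mass += REDUCTION
    if ion == "deprotonated":
        mass -= PROTON
    return mass


def match_compositions(
    observed_mass: float,
    tolerance: float,
    reduced: bool = True,
    ion: str = "deprotonated",
    bounds: Optional[dict] = None,
) -> list[GlycanComposition]:
    """All compositions within ``bounds`` whose mass lies within
    ±``tolerance`` of ``observed_mass``, sorted by absolute mass error
    (Glycomod-style exhaustive decomposition)."""
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if bounds is None:
        bounds = {k: 8 for k in RESIDUE_MASS}
    for key, bound in bounds.items():
        if key not in RESIDUE_MASS:
            raise ValueError(f"unknown composition class {key!r}")
        if bound < 0:
            raise ValueError("bounds must be nonnegative")
    classes = list(RESIDUE_MASS)
    hits = []
    ranges = [range(bounds.get(k, 0) + 1) for k in classes]
    for counts in itertools.product(*ranges):
        if sum(counts) == 0:
            continue
        comp = dict(zip(classes, counts))
        err = compute_mass(comp, reduced=reduced, ion=ion) - observed_mass
        if abs(err) <= tolerance:
            hits.append((abs(err), comp))
    hits.sort(key=lambda pair: (pair[0], sorted(pair[1].items())))
    return [comp for _, comp in hits]
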