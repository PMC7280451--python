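"""Rule-based epitope counting and class assignment on glycan trees.

An epitope motif is a small glycan-shaped pattern.  A motif occurrence is an
injective, edge-preserving mapping of the pattern into a target glycan that
respects residue identities, anomeric configurations and linkage positions.
Occurrences are counted as distinct images of the pattern root, so symmetric
internal mappings are not double counted.  An explicit position in a motif
never matches an unknown (``?``) linkage in the target: structures with
unresolved linkages contribute 0 to linkage-specific traits rather than
being guessed.

The built-in trait library (``data/trait_library.tsv``) covers the mucin-type
O-glycan and glycosphingolipid (GSL) derived traits reported for the
PaTu-8988 panel: core 2/4 membership, sTn, T antigen, terminal HexNAc,
linkage-specific sialylation and fucosylation, Lewis-type and blood-group
antigens, and the globo/ganglio/(neo)lacto GSL series partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional

import pandas as pd

from .glycan import (
    Anomer,
    Glycan,
    GlycanContext,
    GlycanNode,
    parse_glycan,
    serialize_glycan,
)

__all__ = [
    "Motif",
    "TraitDefinition",
    "count_motif",
    "classify_o_core",
    "classify_gsl_series",
    "compute_epitope_table",
    "apply_exoglycosidase",
    "builtin_traits",
    "load_trait_library",
]


# ---------------------------------------------------------------------------
# motifs and subtree matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Motif:
    """A glycan pattern plus matching constraints.

    ``pattern`` is a glycan tree (wildcard anomers/positions written ``?``
    act as wildcards on the motif side only).  ``terminal_leaves`` requires
    every childless pattern node to map onto a leaf of the target.
    ``forbidden`` lists (residue identity, parent position) pairs that must
    be unoccupied on the image of the pattern node with that identity.
    ``allow_alditol`` controls whether pattern nodes may map onto the
    reducing-end alditol (the open-ring root residue).
    """

    pattern: Glycan
    anchor: str = "anywhere"  # or "at_root"
    terminal_leaves: bool = False
    forbidden: tuple[tuple[str, int], ...] = ()
    allow_alditol: bool = True

    def __post_init__(self) -> None:
        if self.anchor not in ("anywhere", "at_root"):
            raise ValueError(f"unknown anchor {self.anchor!r}")
        identities = {n.residue.identity for n in self.pattern.root.walk()}
        for identity, _pos in self.forbidden:
            if identity not in identities:
                raise ValueError(
                    f"forbidden constraint names {identity!r}, absent from pattern"
                )


def _node_matches(motif: Motif, pnode: GlycanNode, tnode: GlycanNode) -> bool:
    res = tnode.residue
    if res.alditol and not motif.allow_alditol:
        return False
    p = pnode.residue
    if p.identity != res.identity:
        return False
    if p.alditol and not res.alditol:
        return False
    if motif.terminal_leaves and pnode.is_leaf() and not tnode.is_leaf():
        return False
    # forbidden substituents on this pattern node's image
    for identity, pos in motif.forbidden:
        if identity != p.identity:
            continue
        for child in tnode.children:
            if child.linkage and child.linkage.parent_position == pos:
                return False
    return True


def _linkage_matches(pnode: GlycanNode, tnode: GlycanNode) -> bool:
    """Pattern wildcards match anything; explicit pattern values never
    match an unknown target value."""
    plink, tlink = pnode.linkage, tnode.linkage
    if plink is None:
        return True
    if tlink is None:
        return False
    if plink.child_position is not None and plink.child_position != tlink.child_position:
        return False
    if plink.parent_position is not None and plink.parent_position != tlink.parent_position:
        return False
    if pnode.residue.anomer is not Anomer.unknown:
        if tnode.residue.anomer is not pnode.residue.anomer:
            return False
    return True


def _embeds(motif: Motif, pnode: GlycanNode, tnode: GlycanNode) -> bool:
    """Can the pattern subtree at ``pnode`` map onto the target subtree at
    ``tnode`` (with ``pnode`` -> ``tnode``)?"""
    if not _node_matches(motif, pnode, tnode):
        return False
    if not pnode.children:
        return True
    # assign pattern children injectively to target children (backtracking;
    # patterns are tiny, <= 4 nodes in the built-in library)
    pchildren = pnode.children
    tchildren = tnode.children

    def assign(idx: int, used: set[int]) -> bool:
        if idx == len(pchildren):
            return True
        pc = pchildren[idx]
        for j, tc in enumerate(tchildren):
            if j in used:
                continue
            if _linkage_matches(pc, tc) and _embeds(motif, pc, tc):
                if assign(idx + 1, used | {j}):
                    return True
        return False

    return assign(0, set())


def count_motif(g: Glycan, m: Motif) -> int:
    """Number of distinct target nodes that can serve as the image of the
    motif root under an injective edge-preserving mapping."""
    candidates: Iterable[GlycanNode]
    if m.anchor == "at_root":
        candidates = [g.root]
    else:
        candidates = g.root.walk()
    return sum(1 for t in candidates if _embeds(m, m.pattern.root, t))


# ---------------------------------------------------------------------------
# core / series classification
# ---------------------------------------------------------------------------

def _root_children(g: Glycan) -> list[tuple[str, Optional[Anomer], Optional[int]]]:
    out = []
    for child in g.root.children:
        pos = child.linkage.parent_position if child.linkage else None
        out.append((child.residue.identity, child.residue.anomer, pos))
    return out


def classify_o_core(g: Glycan) -> str:
    """Mucin-type O-glycan core class from the reducing-end GalNAc-ol
    substituents: Tn, sTn, core1 (T backbone), core2, core3, core4, other."""
    if g.context is not GlycanContext.O_GLYCAN:
        raise ValueError("classify_o_core requires an O-glycan (GalNAc-ol root)")
    kids = _root_children(g)
    if not kids:
        return "Tn"
    keyed = {(identity, anomer, pos) for identity, anomer, pos in kids}
    gal_b3 = ("Gal", Anomer.beta, 3) in keyed
    glcnac_b3 = ("GlcNAc", Anomer.beta, 3) in keyed
    glcnac_b6 = ("GlcNAc", Anomer.beta, 6) in keyed
    sia_a6 = ("Neu5Ac", Anomer.alpha, 6) in keyed
    if keyed == {("Neu5Ac", Anomer.alpha, 6)}:
        return "sTn"
    if gal_b3 and glcnac_b6 and len(keyed) == 2:
        return "core2"
    if gal_b3 and (len(keyed) == 1 or (sia_a6 and len(keyed) == 2)):
        # position 6 empty or sialylated
        return "core1"
    if glcnac_b3 and glcnac_b6 and len(keyed) == 2:
        return "core4"
    if keyed == {("GlcNAc", Anomer.beta, 3)}:
        return "core3"
    return "other"


def classify_gsl_series(g: Glycan) -> str:
    """GSL series from the residue extending the lactose-core Gal:
    Galα1-4 -> globo, GlcNAcβ1-3 -> neolacto (regardless of capping),
    Neu5Ac and/or GalNAcβ1-4 without GlcNAc extension -> ganglio,
    bare lactose -> core_only, anything else -> other.  Total on every
    valid GSL glycan."""
    if g.context is not GlycanContext.GSL:
        raise ValueError("classify_gsl_series requires a GSL glycan")
    root = g.root
    if root.residue.identity != "Glc":
        return "other"  # galactosylceramide-type cores fall outside the 3 series
    core_gal = None
    for child in root.children:
        pos = child.linkage.parent_position if child.linkage else None
        if child.residue.identity == "Gal" and child.residue.anomer is Anomer.beta and pos == 4:
            core_gal = child
            break
    if core_gal is None:
        return "other"
    exts = []
    for child in core_gal.children:
        pos = child.linkage.parent_position if child.linkage else None
        exts.append((child.residue.identity, child.residue.anomer, pos))
    if any(i == "Gal" and a is Anomer.alpha and p == 4 for i, a, p in exts):
        return "globo"
    if any(i == "GlcNAc" and a is Anomer.beta and p == 3 for i, a, p in exts):
        return "neolacto"
    has_ganglio = any(
        i == "Neu5Ac" or (i == "GalNAc" and a is Anomer.beta and p == 4)
        for i, a, p in exts
    )
    if has_ganglio and all(
        i == "Neu5Ac" or (i == "GalNAc" and a is Anomer.beta and p == 4)
        for i, a, p in exts
    ):
        return "ganglio"
    if not exts:
        return "core_only"
    return "other"


GSL_SERIES = ("globo", "ganglio", "neolacto", "core_only", "other")


# ---------------------------------------------------------------------------
# in-silico exoglycosidase digestion
# ---------------------------------------------------------------------------

def apply_exoglycosidase(g: Glycan, enzyme: str = "neuraminidase_a23") -> Glycan:
    """Digest in silico; ``neuraminidase_a23`` removes every terminal
    Neu5Ac attached at position 3 of its parent, iterating to a fixed
    point.  Mirrors the wet-lab annotation-confirmation digest."""
    if enzyme != "neuraminidase_a23":
        raise ValueError(f"unknown enzyme {enzyme!r}")

    def prune(node: GlycanNode) -> GlycanNode:
        kept = []
        for child in node.children:
            if (
                child.residue.identity == "Neu5Ac"
                and child.is_leaf()
                and child.linkage is not None
                and child.linkage.parent_position == 3
            ):
                continue
            kept.append(prune(child))
        return GlycanNode(node.residue, node.linkage, kept)

    root = g.root
    while True:
        new_root = prune(root)
        if sum(1 for _ in new_root.walk()) == sum(1 for _ in root.walk()):
            break
        root = new_root
    return Glycan(root, g.context)


# ---------------------------------------------------------------------------
# trait definitions and the built-in library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitDefinition:
    """A named derived trait.

    ``mode`` is one of ``epitope_weighted`` (sum of motif occurrences),
    ``membership`` (0/1 per glycan) and ``class_partition`` (0/1, the
    partition traits of one scope are mutually exclusive and exhaustive).
    ``rule`` selects classifier-backed membership: ``("o_core", classes)``
    or ``("gsl_series", classes)``; motif-backed traits leave it None.
    """

    name: str
    scope: str  # "O" or "GSL"
    mode: str
    motifs: tuple[Motif, ...] = ()
    rule: Optional[tuple[str, tuple[str, ...]]] = None
    panel: str = ""

    def count(self, g: Glycan) -> int:
        if self.rule is not None:
            kind, classes = self.rule
            label = classify_o_core(g) if kind == "o_core" else classify_gsl_series(g)
            return int(label in classes)
        total = sum(count_motif(g, m) for m in self.motifs)
        if self.mode in ("membership", "class_partition"):
            return int(total > 0)
        return total


def _parse_forbidden(spec: str) -> tuple[tuple[str, int], ...]:
    out = []
    for item in spec.split(";"):
        identity, positions = item.split(":")
        for pos in positions.split(","):
            out.append((identity, int(pos)))
    return tuple(out)


def load_trait_library(path_or_buffer) -> list[TraitDefinition]:
    """Read a trait-library TSV (columns: name, scope, mode, definition,
    anchor, terminal, forbidden, allow_alditol, panel).  ``definition`` is
    either ``;``-separated motif notation or ``o_core:...`` /
    ``gsl_series:...`` classifier rules."""
    table = pd.read_csv(path_or_buffer, sep="\t", dtype=str, comment="#").fillna("-")
    traits = []
    for row in table.itertuples(index=False):
        rule = None
        motifs: tuple[Motif, ...] = ()
        definition = row.definition.strip()
        if definition.startswith(("o_core:", "gsl_series:")):
            kind, classes = definition.split(":", 1)
            rule = (kind, tuple(c.strip() for c in classes.split(",")))
        else:
            forbidden = () if row.forbidden == "-" else _parse_forbidden(row.forbidden)
            motifs = tuple(
                Motif(
                    pattern=parse_glycan(text.strip(), GlycanContext.FREE),
                    anchor=row.anchor,
                    terminal_leaves=(row.terminal == "leaves"),
                    forbidden=forbidden,
                    allow_alditol=(row.allow_alditol != "no"),
                )
                for text in definition.split(";")
            )
        traits.append(
            TraitDefinition(
                name=row.name,
                scope=row.scope,
                mode=row.mode,
                motifs=motifs,
                rule=rule,
                panel=row.panel,
            )
        )
    _validate_partitions(traits)
    return traits


def _validate_partitions(traits: list[TraitDefinition]) -> None:
    for scope in ("O", "GSL"):
        partition = [t for t in traits if t.scope == scope and t.mode == "class_partition"]
        if not partition:
            continue
        classes: list[str] = []
        for t in partition:
            if t.rule is None:
                raise ValueError("class_partition traits must be classifier-backed")
            classes.extend(t.rule[1])
        if len(classes) != len(set(classes)):
            raise ValueError(f"{scope} partition classes overlap: {classes}")
        if scope == "GSL" and set(classes) != set(GSL_SERIES):
            raise ValueError(
                f"GSL partition must be exhaustive over {GSL_SERIES}, got {classes}"
            )


def builtin_traits() -> list[TraitDefinition]:
    """The shipped trait library behind the Fig 4/5-style panels."""
    ref = resources.files("glycotrait").joinpath("data/trait_library.tsv")
    with resources.as_file(ref) as path:
        return load_trait_library(path)


# ---------------------------------------------------------------------------
# epitope table
# ---------------------------------------------------------------------------

_SCOPE_FOR_CONTEXT = {GlycanContext.O_GLYCAN: "O", GlycanContext.GSL: "GSL"}


def compute_epitope_table(
    glycans: Iterable[Glycan],
    traits: Optional[Iterable[TraitDefinition]] = None,
) -> pd.DataFrame:
    """Long-format epitope counts: one row per (glycan, trait) whose scope
    matches the glycan's context; columns glycan_id, trait, scope, mode,
    count."""
    traits = list(traits) if traits is not None else builtin_traits()
    rows = []
    for g in glycans:
        scope = _SCOPE_FOR_CONTEXT.get(g.context)
        if scope is None:
            continue
        gid = serialize_glycan(g)
        for trait in traits:
            if trait.scope != scope:
                continue
            count = trait.count(g)
            if trait.mode in ("membership", "class_partition") and count not in (0, 1):
                raise AssertionError("membership counts must be 0/1")
            rows.append((gid, trait.name, scope, trait.mode, count))
    return pd.DataFrame(
        rows, columns=["glycan_id", "trait", "scope", "mode", "count"]
    )
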