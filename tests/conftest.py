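"""Shared fixtures: seeded random glycan trees and an exhaustive
injective-mapping oracle for motif counting (kept deliberately independent
of the package's tree-recursive matcher)."""

from __future__ import annotations

import itertools
import random

import pytest

from glycotrait.glycan import (
    Anomer,
    Glycan,
    GlycanContext,
    GlycanNode,
    Linkage,
    Residue,
)
from glycotrait.motifs import Motif

RESIDUES = ["Gal", "Glc", "GalNAc", "GlcNAc", "Fuc", "Neu5Ac"]


def random_glycan(rng: random.Random, max_nodes: int = 12,
                  context: GlycanContext = GlycanContext.FREE) -> Glycan:
    """A random valid glycan tree with unknown anomers/positions mixed in."""
    if context is GlycanContext.O_GLYCAN:
        root_res = Residue("GalNAc", Anomer.unknown, alditol=True)
    elif context is GlycanContext.GSL:
        root_res = Residue(rng.choice(["Glc", "Gal"]), Anomer.unknown, alditol=True)
    else:
        identity = rng.choice(RESIDUES)
        alditol = identity != "Neu5Ac" and rng.random() < 0.5
        root_res = Residue(identity, Anomer.unknown, alditol=alditol)
    root = GlycanNode(root_res)
    nodes = [root]
    n_nodes = rng.randint(1, max_nodes)
    while len(nodes) < n_nodes:
        parent = rng.choice(nodes)
        identity = rng.choice(RESIDUES)
        anomer = rng.choice([Anomer.alpha, Anomer.beta, Anomer.unknown])
        cpos = 2 if identity == "Neu5Ac" else 1
        if rng.random() < 0.1:
            cpos = None
        taken = {
            c.linkage.parent_position
            for c in parent.children
            if c.linkage and c.linkage.parent_position is not None
        }
        open_pos = [p for p in range(2, 9) if p not in taken]
        if not open_pos:
            continue
        ppos = None if rng.random() < 0.15 else rng.choice(open_pos)
        child = GlycanNode(Residue(identity, anomer), Linkage(cpos, ppos))
        parent.children.append(child)
        nodes.append(child)
    return Glycan(root, context)


def random_motif(rng: random.Random, max_nodes: int = 4) -> Motif:
    pattern = random_glycan(rng, max_nodes=max_nodes)
    identities = {n.residue.identity for n in pattern.root.walk()}
    forbidden = []
    if rng.random() < 0.3:
        forbidden.append((rng.choice(sorted(identities)), rng.randint(2, 8)))
    return Motif(
        pattern=pattern,
        anchor=rng.choice(["anywhere", "at_root"]),
        terminal_leaves=rng.random() < 0.4,
        forbidden=tuple(forbidden),
        allow_alditol=rng.random() < 0.7,
    )


# ---------------------------------------------------------------------------
# exhaustive oracle: enumerate complete injective node maps and check every
# constraint on the finished map
# ---------------------------------------------------------------------------

def _flatten(glycan: Glycan):
    """(node, parent) pairs in walk order."""
    out = []

    def rec(node, parent):
        out.append((node, parent))
        for c in node.children:
            rec(c, node)

    rec(glycan.root, None)
    return out


def _map_is_valid(motif: Motif, pairs, target_pairs, assignment) -> bool:
    parent_of = {id(n): p for n, p in target_pairs}
    for (pnode, pparent), tnode in zip(pairs, assignment):
        p, t = pnode.residue, tnode.residue
        if p.identity != t.identity:
            return False
        if t.alditol and not motif.allow_alditol:
            return False
        if p.alditol and not t.alditol:
            return False
        if motif.terminal_leaves and not pnode.children and tnode.children:
            return False
        for identity, pos in motif.forbidden:
            if identity == p.identity:
                for child in tnode.children:
                    if child.linkage and child.linkage.parent_position == pos:
                        return False
        if pparent is not None:
            # edge preservation: the image of the pattern parent must be the
            # target parent of this node's image
            pidx = [n for n, _ in pairs].index(pparent)
            if parent_of[id(tnode)] is not assignment[pidx]:
                return False
            plink, tlink = pnode.linkage, tnode.linkage
            if plink is not None:
                if tlink is None:
                    return False
                if plink.child_position is not None and plink.child_position != tlink.child_position:
                    return False
                if plink.parent_position is not None and plink.parent_position != tlink.parent_position:
                    return False
                if p.anomer is not Anomer.unknown and t.anomer is not p.anomer:
                    return False
    return True


def oracle_count_motif(glycan: Glycan, motif: Motif) -> int:
    """Count distinct images of the motif root over all complete injective
    mappings, by brute-force enumeration."""
    pairs = _flatten(motif.pattern)
    target_pairs = _flatten(glycan)
    target_nodes = [n for n, _ in target_pairs]
    root_images = set()
    # cheap identity prefilter; the full constraint check runs on each map
    candidates = [
        [t for t in target_nodes if t.residue.identity == pnode.residue.identity]
        for pnode, _ in pairs
    ]
    for assignment in itertools.product(*candidates):
        if len({id(t) for t in assignment}) != len(assignment):
            continue
        if motif.anchor == "at_root" and assignment[0] is not glycan.root:
            continue
        if _map_is_valid(motif, pairs, target_pairs, assignment):
            root_images.add(id(assignment[0]))
    return len(root_images)


@pytest.fixture(scope="session")
def reference_panel():
    from glycotrait.simulate import build_reference_panel

    return build_reference_panel()
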