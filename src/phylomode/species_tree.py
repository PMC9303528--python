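"""Rooted species phylogeny with labelled internal clade nodes.

The species tree is the reference frame for every inference step: gene-origin
(phylostratigraphic) assignment, duplication mapping and mode classification
all resolve to its nodes. Newick I/O goes through dendropy; the algorithms
(LCA queries, subtree scans, restriction) run on a lightweight indexed node
structure so that exhaustive enumeration over presence patterns stays fast.

A packaged 14-taxon plant backbone is provided (:data:`BACKBONE_NEWICK`). It
spans the clades the inference cares about — Viridiplantae, Streptophyta,
Embryophyta (land plants), Tracheophyta (vascular plants), Euphyllophyta
(plants with true leaves) and Spermatophyta (seed plants) — with one or two
exemplar lineages per major group.
"""

from __future__ import annotations

import io
from typing import Iterable, Mapping, Sequence

import dendropy

__all__ = ["Node", "SpeciesTree", "BACKBONE_NEWICK", "backbone_tree"]

#: 14-taxon plant backbone. Tips: RHO rhodophyte, GLA glaucophyte,
#: CHL chlorophyte, CHA charophyte, LIV liverwort, MOS moss, HORN hornwort,
#: LYC lycophyte, FERN fern, CON conifer, AMB Amborella-like angiosperm,
#: MON1/MON2 monocots, EUD eudicot. Internal labels name the standard clades.
BACKBONE_NEWICK = (
    "(RHO,(GLA,(CHL,(CHA,((HORN,(LIV,MOS)Setaphyta)Bryophyta,"
    "(LYC,(FERN,(CON,(AMB,((MON1,MON2)Monocots,EUD)Mesangiospermae)"
    "Angiospermae)Spermatophyta)Euphyllophyta)Tracheophyta)Embryophyta)"
    "Streptophyta)Viridiplantae))Archaeplastida;"
)


class Node:
    """One node of a :class:`SpeciesTree`.

    ``label`` is the species code for tips and the (optional) clade name for
    internal nodes. ``index`` is the node's position in preorder and is used
    as a stable identifier.
    """

    __slots__ = ("label", "parent", "children", "index", "depth", "_tip_set")

    def __init__(self, label: str | None = None):
        self.label = label
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.index: int = -1
        self.depth: int = 0
        self._tip_set: frozenset[str] = frozenset()

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def tip_set(self) -> frozenset[str]:
        """Species codes of all tips descending from (or equal to) this node."""
        return self._tip_set

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else "clade"
        return f"<Node {self.label or self.index} ({kind})>"


class SpeciesTree:
    """Rooted, possibly multifurcating species tree with unique tip labels.

    Parameters
    ----------
    root:
        Root :class:`Node` of an already-built node structure.

    Use :meth:`from_newick` to construct from a Newick string or file. Tip
    labels must be unique; duplicate internal labels are rejected (strict
    parse).
    """

    def __init__(self, root: Node):
        self.root = root
        self._index()

    # ------------------------------------------------------------------ build
    @classmethod
    def from_newick(cls, source: str) -> "SpeciesTree":
        """Parse a Newick string (or path ending in .nwk/.newick/.tre)."""
        if source.lstrip().startswith("("):
            data = source
        else:
            with open(source) as fh:
                data = fh.read()
        dtree = dendropy.Tree.get(
            data=data,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        root = cls._convert(dtree.seed_node)
        return cls(root)

    @staticmethod
    def _convert(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
            return Node(label)
        node = Node(dnode.label)
        for child in dnode.child_nodes():
            cnode = SpeciesTree._convert(child)
            cnode.parent = node
            node.children.append(cnode)
        return node

    def _index(self) -> None:
        self._nodes: list[Node] = []
        self._by_label: dict[str, Node] = {}
        seen_tips: set[str] = set()
        stack = [(self.root, 0)]
        order: list[Node] = []
        while stack:
            node, depth = stack.pop()
            node.depth = depth
            node.index = len(order)
            order.append(node)
            if node.label is not None:
                if node.label in self._by_label:
                    raise ValueError(f"duplicate node label: {node.label!r}")
                self._by_label[node.label] = node
            if node.is_tip:
                if node.label is None:
                    raise ValueError("tip without a label")
                seen_tips.add(node.label)
            for child in reversed(node.children):
                stack.append((child, depth + 1))
        self._nodes = order
        # postorder pass for tip sets
        for node in self.postorder():
            if node.is_tip:
                node._tip_set = frozenset([node.label])
            else:
                acc: set[str] = set()
                for child in node.children:
                    acc.update(child._tip_set)
                node._tip_set = frozenset(acc)
        self.tips: list[str] = [n.label for n in self.preorder() if n.is_tip]

    # ------------------------------------------------------------- traversal
    def preorder(self) -> Iterable[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterable[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    @property
    def nodes(self) -> Sequence[Node]:
        return self._nodes

    def node(self, label: str) -> Node:
        """Node carrying ``label`` (tip code or clade name)."""
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"no node labelled {label!r} in species tree") from None

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    # ------------------------------------------------------------- relations
    def ancestors(self, node: Node, include_self: bool = True) -> list[Node]:
        out = [node] if include_self else []
        cur = node.parent
        while cur is not None:
            out.append(cur)
            cur = cur.parent
        return out

    def is_ancestor(self, anc: Node, desc: Node, strict: bool = False) -> bool:
        """True if ``anc`` lies on the root path of ``desc``."""
        if anc is desc:
            return not strict
        cur = desc.parent
        while cur is not None:
            if cur is anc:
                return True
            cur = cur.parent
        return False

    def lca(self, labels: Iterable[str]) -> Node:
        """Last common ancestor of a set of tip (or clade) labels."""
        nodes = [self.node(lab) for lab in labels]
        if not nodes:
            raise ValueError("lca of an empty label set")
        cur = nodes[0]
        for other in nodes[1:]:
            a, b = cur, other
            while a.depth > b.depth:
                a = a.parent
            while b.depth > a.depth:
                b = b.parent
            while a is not b:
                a, b = a.parent, b.parent
            cur = a
        return cur

    # ------------------------------------------------------------- utilities
    def restrict(self, keep_tips: Iterable[str]) -> "SpeciesTree":
        """Subtree induced by ``keep_tips`` with unary nodes suppressed.

        Internal labels are kept on the surviving nodes (the label follows
        the node, so a clade label may end up naming a smaller clade in the
        restricted tree).
        """
        keep = set(keep_tips)
        missing = keep - set(self.tips)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")

        def build(node: Node) -> Node | None:
            if node.is_tip:
                return Node(node.label) if node.label in keep else None
            kids = [c for c in (build(ch) for ch in node.children) if c is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            new = Node(node.label)
            for k in kids:
                k.parent = new
                new.children.append(k)
            return new

        root = build(self.root)
        if root is None:
            raise ValueError("restriction removed every tip")
        return SpeciesTree(root)

    def outgroup_rank(self) -> list[str]:
        """Tips ordered most-outgroup-first along the root-ward ladder.

        Rank is divergence depth from the root (ties broken alphabetically),
        which on a ladderized backbone lists the successive outgroups before
        any ingroup tip.
        """
        return sorted(self.tips, key=lambda t: (self.node(t).depth, t))

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_tip:
                return node.label
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}){node.label or ''}"

        return fmt(self.root) + ";"

    def __len__(self) -> int:
        return len(self._nodes)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<SpeciesTree {len(self.tips)} tips, {len(self)} nodes>"


def backbone_tree() -> SpeciesTree:
    """The packaged 14-taxon plant backbone (fresh instance)."""
    return SpeciesTree.from_newick(BACKBONE_NEWICK)
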