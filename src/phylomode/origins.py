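"""Gene-origin (phylostratigraphic) assignment by single-gain parsimony.

Each homology group's presence/absence pattern across species is explained
by a single gain on the species tree followed by any number of independent
losses (Dollo parsimony). Under that model the minimum-loss gain node is
exactly the last common ancestor of all species with evidence for the
group, and the implied losses are the maximal all-absent subtrees hanging
below that node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

from .occupancy import ABSENT, PARTIAL, PRESENT
from .species_tree import Node, SpeciesTree

logger = logging.getLogger(__name__)

__all__ = ["OriginCall", "infer_origin_node", "implied_losses"]


@dataclass(frozen=True)
class OriginCall:
    """Origin placement for one homology group.

    ``origin_label`` is the species-tree node label when the node carries
    one, otherwise its preorder index as a string. ``presence_tips`` are the
    species counted as evidence for the placement.
    """

    hg_id: str
    origin: Node
    origin_label: str
    implied_losses: int
    presence_tips: frozenset[str]


def _label(node: Node) -> str:
    return node.label if node.label is not None else str(node.index)


def infer_origin_node(
    row: Mapping[str, int],
    tree: SpeciesTree,
    partial_counts: bool = True,
    hg_id: str | None = None,
) -> OriginCall | None:
    """Place the single gain explaining an occupancy row.

    Parameters
    ----------
    row:
        Mapping species code -> state (0 absent, 1 partial, 2 present); a
        pandas Series with its ``name`` set to the HG id works directly.
    partial_counts:
        Whether transcriptome-only (partial) evidence counts as presence.
        On by default: the expanded transcriptome sampling exists precisely
        to detect presence in lineages without a sequenced genome.

    Returns
    -------
    OriginCall, or None for an all-absent row (logged, excluded downstream).
    """
    if hg_id is None:
        hg_id = str(getattr(row, "name", "?"))
    states = (PRESENT, PARTIAL) if partial_counts else (PRESENT,)
    presence = frozenset(sp for sp, state in _items(row) if state in states)
    if not presence:
        logger.warning("%s: no presence evidence, skipping origin inference", hg_id)
        return None
    missing = [sp for sp in presence if sp not in tree]
    if missing:
        raise KeyError(f"{hg_id}: species not in tree: {sorted(missing)}")
    origin = tree.lca(presence)
    losses = implied_losses(origin, row, tree, partial_counts=partial_counts)
    return OriginCall(
        hg_id=hg_id,
        origin=origin,
        origin_label=_label(origin),
        implied_losses=losses,
        presence_tips=presence,
    )


def implied_losses(
    origin: Node,
    row: Mapping[str, int],
    tree: SpeciesTree,
    partial_counts: bool = True,
) -> int:
    """Minimum loss events given one gain at ``origin``.

    Counts maximal subtrees below ``origin`` whose tips are all absent;
    each such subtree is one heritable loss. Tips missing from ``row`` are
    treated as absent. Raises if ``origin`` is not ancestral to every
    presence tip.
    """
    states = (PRESENT, PARTIAL) if partial_counts else (PRESENT,)
    present = set(sp for sp, state in _items(row) if state in states)
    if not present <= origin.tip_set:
        stray = sorted(present - origin.tip_set)
        raise ValueError(f"origin node does not cover presence tips {stray}")
    losses = 0
    stack = list(origin.children)
    while stack:
        node = stack.pop()
        if node.tip_set & present:
            stack.extend(node.children)
        else:
            losses += 1
    return losses


def _items(row: Mapping[str, int]):
    # works for both dict and pandas Series
    if hasattr(row, "items"):
        return row.items()
    return row.iteritems()  # pragma: no cover
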