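"""Branch-length statistics on rooted phylogenies.

Two summaries of where a designated tip set (e.g. the genomes recovered from a
single spring) sits in a reference phylogeny:

* root-to-tip distance for every tip (sum of branch lengths along the path
  from the root), and
* the fraction of the tree's total branch length attributable to the tip set.

Because "attributable" admits more than one reading, ``branch_fraction``
implements two modes: ``exclusive`` counts every edge whose entire descendant
tip set lies inside the designated set (clade-exclusive branch length), while
``tip_only`` counts only the terminal branches of the designated tips.  The
exclusive fraction is always at least the tip-only fraction.

Trees are handled through dendropy; this module adds validation (unique tip
labels, defaulting of missing branch lengths) and the metrics themselves.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable

import dendropy

from .exceptions import InvalidInputError, NewickParseError

logger = logging.getLogger(__name__)


class PhyloTree:
    """A rooted tree with branch lengths and uniquely labeled tips.

    Thin wrapper over a dendropy Tree; the seed node acts as the root (an
    unrooted newick's basal trifurcation becomes the root, with a warning).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        dupes = [lab for lab, c in Counter(labels).items() if c > 1]
        if dupes:
            raise NewickParseError(f"duplicate tip labels: {sorted(dupes)}")
        missing = 0
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                edge.length = 0.0
                missing += 1
            elif edge.length < 0:
                raise InvalidInputError(f"negative branch length {edge.length}")
        if missing:
            logger.warning("parse_newick: %d missing branch lengths defaulted to 0", missing)
        if not tree.seed_node.is_leaf() and len(tree.seed_node.child_nodes()) > 2:
            logger.warning(
                "parse_newick: basal multifurcation treated as the root (distRoot semantics)"
            )
        self._tips = labels

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return list(self._tips)

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    def total_branch_length(self) -> float:
        seed = self._tree.seed_node
        total = sum(
            e.length or 0.0
            for e in self._tree.preorder_edge_iter()
            if e.head_node is not seed
        )
        if seed.is_leaf():  # single-tip tree: its only branch hangs off the root
            total += seed.edge.length or 0.0
        return total

    def write_newick(self) -> str:
        return (
            self._tree.as_string(schema="newick", suppress_rooting=True).strip()
        )


def parse_newick(text: str) -> PhyloTree:
    """Parse a newick string into a validated PhyloTree.

    Missing branch lengths default to 0 (warned); duplicate tip labels or
    malformed newick raise NewickParseError with position information where
    dendropy provides it.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several tokenizer/parse classes
        raise NewickParseError(f"malformed newick: {exc}") from exc
    if tree.seed_node is None or (
        tree.seed_node.is_leaf() and tree.seed_node.taxon is None
    ):
        raise NewickParseError("newick contains no labeled tips")
    return PhyloTree(tree)


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def root_to_tip(tree: PhyloTree) -> dict[str, float]:
    """Sum of branch lengths on the unique root-to-tip path, per tip."""
    dt = tree.dendropy_tree
    distances: dict[str, float] = {}
    # accumulate depth down the tree in one preorder pass
    depth: dict[int, float] = {id(dt.seed_node): 0.0}
    for node in dt.preorder_node_iter():
        if node is dt.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
        if node.is_leaf():
            distances[node.taxon.label] = depth[id(node)]
    if dt.seed_node.is_leaf():
        distances[dt.seed_node.taxon.label] = dt.seed_node.edge.length or 0.0
    return distances


def branch_fraction(tree: PhyloTree, tips: Iterable[str], mode: str = "exclusive") -> float:
    """Fraction of total branch length attributable to ``tips``.

    mode "exclusive": edges whose entire descendant tip set is inside ``tips``
    (terminal branches of the tips plus internal branches of clades composed
    only of them).  mode "tip_only": terminal branches of the tips alone.
    """
    tips = set(tips)
    known = set(tree.tip_labels)
    unknown = tips - known
    if unknown:
        raise InvalidInputError(f"unknown tip label(s): {sorted(unknown)}")
    if mode not in ("exclusive", "tip_only"):
        raise InvalidInputError(f"mode must be 'exclusive' or 'tip_only', got {mode!r}")
    total = tree.total_branch_length()
    if total == 0:
        return 0.0
    if not tips:
        return 0.0
    dt = tree.dendropy_tree
    contributed = 0.0
    # postorder: leaf-set containment propagates upward
    inside: dict[int, bool] = {}
    for node in dt.postorder_node_iter():
        if node.is_leaf():
            inside[id(node)] = node.taxon.label in tips
        else:
            inside[id(node)] = all(inside[id(c)] for c in node.child_nodes())
        if node is dt.seed_node:
            if node.is_leaf() and node.taxon.label in tips:
                contributed += node.edge.length or 0.0
            continue
        length = node.edge.length or 0.0
        if mode == "exclusive":
            if inside[id(node)]:
                contributed += length
        else:
            if node.is_leaf() and node.taxon.label in tips:
                contributed += length
    return contributed / total
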