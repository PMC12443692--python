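"""OT interval indexing of base suffixes.

A post-order traversal of the OSHR tree appends each node's base suffixes
(ascending) to one global list; every internal node then owns a contiguous
inclusive slice ``[left, right]`` of that list whose values are exactly
``SU(x)``.  The root's slice is the whole list, so the n base suffixes are
a permutation of 0..n-1 and any node's suffix set is recovered in O(|SU|)
without descending the suffix tree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from .base_suffixes import BaseSuffixTable
from .errors import ContractViolation, IntegrityError
from .oshr import OSHRView
from .suffix_core import STNode, SuffixTree, locate_node_by_label, su_set

__all__ = [
    "OTSuffixIndex",
    "OTReport",
    "build_ot_suffix_index",
    "suffixes_under_via_ot",
    "pattern_occurrences",
    "verify_ot_invariants",
]


class OTSuffixIndex:
    """The global OT list plus per-node inclusive offset pairs.

    ``left[node_id] > right[node_id]`` is the (defensive) empty-interval
    marker; it cannot arise for suffix sets because an OSHR leaf always has
    base suffixes.
    """

    def __init__(self, tree: SuffixTree, subtree_root: Optional[STNode] = None):
        self.tree = tree
        self.subtree_root = subtree_root if subtree_root is not None else tree.root
        self.ot_list: list = []
        self.left: dict = {}
        self.right: dict = {}

    @property
    def whole_tree(self) -> bool:
        return self.subtree_root is self.tree.root

    def covers(self, x: STNode) -> bool:
        return x.node_id in self.left

    def offsets(self, x: STNode) -> tuple:
        return (self.left[x.node_id], self.right[x.node_id])

    def to_json(self, fh) -> None:
        json.dump(
            {
                "n": self.tree.n,
                "subtree_root": self.subtree_root.node_id,
                "ot_list": self.ot_list,
                "offsets": {str(nid): [self.left[nid], self.right[nid]] for nid in self.left},
            },
            fh,
        )

    def dump_tsv(self, fh) -> None:
        fh.write("node_id\tleft\tright\n")
        for nid in sorted(self.left):
            fh.write("%d\t%d\t%d\n" % (nid, self.left[nid], self.right[nid]))


def build_ot_suffix_index(
    tree: SuffixTree,
    view: OSHRView,
    table: BaseSuffixTable,
    subtree_root: Optional[STNode] = None,
) -> OTSuffixIndex:
    """Append base suffixes along the OSHR post-order and record offsets.

    ``left`` is the list length on entering the node's OSHR subtree (which
    equals the left offset of its first child, if any); ``right`` is the
    last position appended for the node itself.
    """
    if view.tree is not tree:
        raise IntegrityError("OSHR view was built from a different tree")
    if set(table.by_node) != {v.node_id for v in tree.internal_nodes}:
        raise IntegrityError("base-suffix table does not match the tree's internal nodes")
    index = OTSuffixIndex(tree, subtree_root)
    ot = index.ot_list
    root = index.subtree_root
    if root.is_leaf:
        raise ContractViolation("OT indexing is rooted at an internal node")
    stack = [(root, 0, 0)]  # node, child pointer, left offset at subtree entry
    while stack:
        node, ptr, entry = stack.pop()
        if ptr == 0:
            entry = len(ot)
        kids = view.sls[node.node_id]
        if ptr < len(kids):
            stack.append((node, ptr + 1, entry))
            stack.append((kids[ptr], 0, 0))
        else:
            ot.extend(table.by_node[node.node_id])
            index.left[node.node_id] = entry
            index.right[node.node_id] = len(ot) - 1  # < entry marks empty
    return index


def suffixes_under_via_ot(index: OTSuffixIndex, x: STNode) -> set:
    """Reconstruct SU(x) from the node's OT slice (no tree descent)."""
    if x.is_leaf or not index.covers(x):
        raise ContractViolation("node %d is not covered by this OT index" % x.node_id)
    lo, hi = index.offsets(x)
    return set(index.ot_list[lo : hi + 1])


def pattern_occurrences(tree: SuffixTree, index: OTSuffixIndex, pattern: str) -> set:
    """All start positions of ``pattern`` in the text, answered via OT slices.

    The pattern is walked from the root; ending at or inside the edge above
    internal node x yields {s - Depth(x) : s in the OT slice of x}; ending
    inside a leaf edge yields that leaf's suffix index.
    """
    if not pattern:
        raise ContractViolation("pattern must be non-empty")
    if not index.whole_tree:
        raise ContractViolation("pattern matching requires a whole-tree OT index")
    hit = locate_node_by_label(tree, pattern)
    if hit is None:
        return set()
    x = hit.node
    if x.is_leaf:
        return {x.suffix_index}
    lo, hi = index.offsets(x)
    d = x.string_depth
    return {s - d for s in index.ot_list[lo : hi + 1]}


@dataclass
class OTReport:
    ok: bool = True
    failures: list = field(default_factory=list)  # (node_id or None, message), shallowest first

    @property
    def first_counterexample(self):
        return self.failures[0] if self.failures else None


def verify_ot_invariants(tree: SuffixTree, view: OSHRView, index: OTSuffixIndex) -> OTReport:
    """Check every OT index invariant; failures are ordered shallowest-first."""
    report = OTReport()

    def fail(node_id, msg):
        report.ok = False
        report.failures.append((node_id, msg))

    n = tree.n
    if index.whole_tree:
        if sorted(index.ot_list) != list(range(n)):
            fail(None, "ot_list is not a permutation of 0..n-1")
        r = tree.root.node_id
        if (index.left.get(r), index.right.get(r)) != (0, n - 1):
            fail(r, "root offsets are not (0, n-1)")

    covered = [tree.nodes[nid] for nid in index.left]
    covered.sort(key=lambda v: (v.string_depth, v.node_id))
    for x in covered:
        lo, hi = index.offsets(x)
        if hi - lo + 1 != x.leaf_count:
            fail(x.node_id, "interval size %d != leaf count %d" % (hi - lo + 1, x.leaf_count))
            continue
        if set(index.ot_list[lo : hi + 1]) != su_set(tree, x):
            fail(x.node_id, "interval values do not reconstruct SU")
        # children occupy a disjoint, contiguous prefix of the interval in
        # stored SLS order; the node's own base suffixes fill the tail.
        kids = view.sls[x.node_id]
        pos = lo
        for c in kids:
            clo, chi = index.offsets(c)
            if clo != pos or chi > hi:
                fail(x.node_id, "child %d interval is not the contiguous block at %d" % (c.node_id, pos))
                break
            pos = chi + 1
        else:
            tail = index.ot_list[pos : hi + 1]
            if tail != sorted(tail):
                fail(x.node_id, "own base suffixes are not in ascending order")
    return report
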