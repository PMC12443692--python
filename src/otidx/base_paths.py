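"""Base-path enumeration: top/bottom internal node pairs.

A pair (u, d) with d an internal proper descendant of u is a *base path*
when no preimage pair under the suffix links exists in the same
ancestor/descendant relation — equivalently, when no member of SLS(d) has a
strict internal ancestor of string depth exactly Depth(u) + 1.  Tables map
each top node to its set of bottom base nodes.

Three routes: the defining set expression (:func:`bp_oracle`), the pairwise
descendant test over SLS intervals (:func:`bp_algorithm4`), and a
near-linear covered-depth sweep (:func:`bp_linear`).
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Optional

from .errors import IntegrityError
from .instrument import OpCounter
from .oshr import OSHRView
from .suffix_core import STNode, SuffixTree, pu_set

__all__ = ["BasePathTable", "bp_oracle", "bp_algorithm4", "bp_linear"]


class BasePathTable:
    """Per-top-node sorted bottom base node ids, keyed by node_id."""

    def __init__(self, by_node: dict):
        self.by_node = by_node  # top node_id -> sorted tuple of bottom node_ids

    def of(self, x: STNode) -> tuple:
        return self.by_node[x.node_id]

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.by_node.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, BasePathTable) and self.by_node == other.by_node

    def __ne__(self, other) -> bool:
        return not self.__eq__(other)

    def dump_tsv(self, tree: SuffixTree, fh) -> None:
        fh.write("top_node_id\tbottom_node_id\ttop_depth\tbottom_depth\tpath_label_len\n")
        for v in tree.internal_nodes:
            for bid in self.by_node[v.node_id]:
                b = tree.nodes[bid]
                fh.write(
                    "%d\t%d\t%d\t%d\t%d\n"
                    % (v.node_id, bid, v.string_depth, b.string_depth, b.string_depth - v.string_depth)
                )


def bp_oracle(tree: SuffixTree, view: OSHRView, counter: Optional[OpCounter] = None) -> BasePathTable:
    """Ground truth: PU(v) minus the suffix-link images of the child PUs."""
    by_node = {}
    for v in tree.internal_nodes:
        pu = pu_set(tree, v)
        covered = set()
        for c in view.sls[v.node_id]:
            for y in pu_set(tree, c):
                covered.add(y.suffix_link)
        bottoms = [d.node_id for d in pu if d not in covered]
        bottoms.sort()
        by_node[v.node_id] = tuple(bottoms)
        if counter is not None:
            counter.add("node_visits")
            counter.add("set_ops", len(pu) + len(covered))
    return BasePathTable(by_node)


def bp_algorithm4(tree: SuffixTree, view: OSHRView, counter: Optional[OpCounter] = None) -> BasePathTable:
    """Pairwise test: (v, d) is base unless some member of SLS(d) descends
    from some member of SLS(v); membership is a binary search over the
    sorted SLS(v) DFS intervals."""
    by_node = {}
    for v in tree.internal_nodes:
        kids = view.sls[v.node_id]
        ivals = sorted((c.dfs_in, c.dfs_out) for c in kids)
        starts = [iv[0] for iv in ivals]
        bottoms = []
        for d in pu_set(tree, v):
            if counter is not None:
                counter.add("pair_checks")
            covered = False
            for a in view.sls[d.node_id]:
                j = bisect_right(starts, a.dfs_in) - 1
                if counter is not None:
                    counter.add("bisect_probes")
                if j >= 0 and a.dfs_in <= ivals[j][1]:
                    covered = True
                    break
            if not covered:
                bottoms.append(d.node_id)
        bottoms.sort()
        by_node[v.node_id] = tuple(bottoms)
    return BasePathTable(by_node)


def bp_linear(
    tree: SuffixTree,
    view: OSHRView,
    annotation=None,
    counter: Optional[OpCounter] = None,
) -> BasePathTable:
    """Covered-depth sweep with memoized ancestor-depth sets.

    For bottom node d the covered top depths are the union over a in SLS(d)
    of {Depth(P) - 1 : P strict internal ancestor of a}.  Ancestor-depth
    sets are memoized per node as bitmasks built incrementally from the
    parent (shared path segments are never rescanned), so each bottom node
    costs one mask merge per SLS child plus one O(1) step per emitted base
    path.  ``annotation`` is accepted for interface parity with the
    base-suffix linear route and is not needed by this strategy.
    """
    internal = tree.internal_nodes
    # ancmask[node_id]: bit k set iff the node has a strict ancestor of depth k.
    ancmask: dict = {}
    for v in internal:
        p = v.parent
        if p is None:
            ancmask[v.node_id] = 0
        else:
            ancmask[v.node_id] = ancmask[p.node_id] | (1 << p.string_depth)
        if counter is not None:
            counter.add("mask_builds")

    by_node: dict = {v.node_id: [] for v in internal}
    depth_to_node: dict = {}  # current root path: string depth -> node
    stack: list = []
    for d in internal:  # node_id order is preorder
        while stack and not (stack[-1].dfs_in < d.dfs_in <= stack[-1].dfs_out):
            gone = stack.pop()
            del depth_to_node[gone.string_depth]
        cov = 0
        for a in view.sls[d.node_id]:
            cov |= ancmask[a.node_id] >> 1
            if counter is not None:
                counter.add("mask_merges")
        tops = ancmask[d.node_id] & ~cov
        nid = d.node_id
        while tops:
            low = tops & -tops
            tops ^= low
            k = low.bit_length() - 1
            by_node[depth_to_node[k].node_id].append(nid)
            if counter is not None:
                counter.add("emissions")
        stack.append(d)
        depth_to_node[d.string_depth] = d
        if counter is not None:
            counter.add("node_visits")
    return BasePathTable({nid: tuple(sorted(v)) for nid, v in by_node.items()})
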