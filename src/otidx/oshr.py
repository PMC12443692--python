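"""The OSHR view: reversed suffix links over the suffix tree's internal nodes.

Each internal non-root node hangs below its suffix-link target, so the
structure is a rooted tree whose root is the suffix tree root.  Child lists
(``SLS``) are ordered by ascending first character of the child's path
label, which fixes every downstream traversal order.
"""

from __future__ import annotations

from typing import Optional

from .errors import ContractViolation, IntegrityError
from .suffix_core import STNode, SuffixTree

__all__ = ["OSHRView", "build_oshr", "oshr_classify", "oshr_post_order", "oshr_ancestors"]


class OSHRView:
    """Reversed-suffix-link tree over the internal nodes of ``tree``.

    ``sls[node_id]`` lists the internal nodes whose suffix link points to the
    node; ``oshr_parent[node_id]`` is the suffix-link target; ``post_order``
    is the canonical whole-tree post-order.
    """

    def __init__(self, tree: SuffixTree):
        self.tree = tree
        self.sls: dict = {}
        self.oshr_parent: dict = {}
        self.post_order: list = []
        self.oshr_leaf_ids: set = set()

    def sls_of(self, x: STNode) -> tuple:
        return self.sls[x.node_id]

    def is_oshr_leaf(self, x: STNode) -> bool:
        return x.node_id in self.oshr_leaf_ids

    def dump_tsv(self, fh) -> None:
        fh.write("node_id\toshr_parent_id\tis_oshr_leaf\n")
        for v in self.tree.internal_nodes:
            pid = "" if v.parent is None else str(self.oshr_parent[v.node_id].node_id)
            fh.write("%d\t%s\t%d\n" % (v.node_id, pid, int(self.is_oshr_leaf(v))))


def build_oshr(tree: SuffixTree) -> OSHRView:
    """Invert the suffix links; O(number of internal nodes)."""
    view = OSHRView(tree)
    lists: dict = {v.node_id: [] for v in tree.internal_nodes}
    for v in tree.internal_nodes:
        if v.parent is None:
            continue
        sl = v.suffix_link
        if sl is None:
            raise IntegrityError("internal node %d is missing its suffix link" % v.node_id)
        lists[sl.node_id].append(v)
        view.oshr_parent[v.node_id] = sl
    for nid, kids in lists.items():
        kids.sort(key=lambda c: c.first_char)
        view.sls[nid] = tuple(kids)
        if not kids:
            view.oshr_leaf_ids.add(nid)
    view.post_order = oshr_post_order(view, None)
    return view


def oshr_classify(view: OSHRView):
    """Partition internal nodes into (OSHR leaves, OSHR internals)."""
    leaves = set()
    internals = set()
    for v in view.tree.internal_nodes:
        (leaves if view.is_oshr_leaf(v) else internals).add(v)
    return leaves, internals


def oshr_post_order(view: OSHRView, subtree_root: Optional[STNode] = None) -> list:
    """Deterministic iterative post-order; SLS children in stored order."""
    root = subtree_root if subtree_root is not None else view.tree.root
    if root.is_leaf:
        raise ContractViolation("OSHR traversal requires an internal node")
    out: list = []
    stack = [(root, 0)]
    while stack:
        node, ptr = stack.pop()
        kids = view.sls[node.node_id]
        if ptr < len(kids):
            stack.append((node, ptr + 1))
            stack.append((kids[ptr], 0))
        else:
            out.append(node)
    return out


def oshr_ancestors(view: OSHRView, x: STNode, include_self: bool = False) -> list:
    """Suffix-link chain x, SL(x), ..., root (proper by default)."""
    if x.is_leaf:
        raise ContractViolation("OSHR ancestry is defined for internal nodes")
    chain = []
    v = x
    if include_self:
        chain.append(v)
    while v.parent is not None:
        v = view.oshr_parent[v.node_id]
        chain.append(v)
    return chain
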