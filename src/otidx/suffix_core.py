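"""Suffix tree construction and per-node annotations.

Builds the suffix tree of a sentinel-terminated text with Ukkonen's online
algorithm, then freezes it into an annotated, immutable structure: canonical
preorder node ids, string depths, suffix links, leaf suffix indexes, DFS
intervals, and per-node leaf ranges.  All traversals use explicit stacks so
degenerate inputs (e.g. ``"AAAA...$"``) never hit the recursion limit.

Conventions
-----------
* Suffix indexes are 0-based; edge spans are half-open ``[start, end)``
  intervals into the text.
* The sentinel is a single character occurring exactly once, at the end.
* ``node_id`` is the preorder rank of a DFS that visits children in
  ascending order of first edge character, which makes every derived
  artifact reproducible across runs.
* The root counts as an internal node.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Optional, Union

from .errors import ContractViolation, IntegrityError, TextFormatError

DEFAULT_SENTINEL = "$"

__all__ = [
    "DEFAULT_SENTINEL",
    "Text",
    "STNode",
    "SuffixTree",
    "LabelHit",
    "build_suffix_tree",
    "locate_node_by_label",
    "node_by_label",
    "su_set",
    "s_set",
    "pu_set",
    "is_descendant",
]


@dataclass(frozen=True)
class Text:
    """A sentinel-terminated text.

    ``symbols`` includes the sentinel as its final character.  ``n`` is the
    length including the sentinel; ``sigma`` counts distinct characters
    including the sentinel.
    """

    symbols: str
    sentinel: str = DEFAULT_SENTINEL

    def __post_init__(self) -> None:
        if len(self.sentinel) != 1:
            raise TextFormatError("sentinel must be a single character")
        if len(self.symbols) < 2:
            raise TextFormatError("text must have length >= 2 (content plus sentinel)")
        if self.symbols.count(self.sentinel) != 1 or self.symbols[-1] != self.sentinel:
            raise TextFormatError(
                "sentinel %r must occur exactly once, at the final position" % self.sentinel
            )

    @classmethod
    def from_raw(cls, raw: str, sentinel: str = DEFAULT_SENTINEL) -> "Text":
        """Append the sentinel to raw content, rejecting collisions."""
        if not raw:
            raise TextFormatError("empty text")
        if sentinel in raw:
            raise TextFormatError("input already contains the sentinel character %r" % sentinel)
        return cls(raw + sentinel, sentinel)

    @property
    def n(self) -> int:
        return len(self.symbols)

    @property
    def sigma(self) -> int:
        return len(set(self.symbols))


class STNode:
    """A suffix tree node (internal or leaf)."""

    __slots__ = (
        "node_id",
        "parent",
        "start",
        "end",
        "children",
        "suffix_link",
        "string_depth",
        "suffix_index",
        "dfs_in",
        "dfs_out",
        "leaf_count",
        "leaf_lo",
        "leaf_hi",
        "first_char",
    )

    def __init__(self) -> None:
        self.node_id: int = -1
        self.parent: Optional[STNode] = None
        self.start: int = 0
        self.end: int = 0
        self.children: Optional[dict] = None  # char -> STNode; None for leaves
        self.suffix_link: Optional[STNode] = None
        self.string_depth: int = 0
        self.suffix_index: int = -1  # leaves only
        self.dfs_in: int = -1
        self.dfs_out: int = -1
        self.leaf_count: int = 0
        self.leaf_lo: int = -1  # rank of first/last leaf of the subtree in DFS order
        self.leaf_hi: int = -1
        self.first_char: Optional[str] = None  # first char of the root-path label

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    @property
    def is_internal(self) -> bool:
        return self.children is not None

    @property
    def is_root(self) -> bool:
        return self.parent is None

    @property
    def edge_span(self) -> tuple:
        """Half-open interval labeling the edge from the parent."""
        return (self.start, self.end)

    def edge_label(self, text: Text) -> str:
        return text.symbols[self.start : self.end]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else "internal"
        return "<STNode %d %s depth=%d>" % (self.node_id, kind, self.string_depth)


class SuffixTree:
    """Annotated suffix tree over a :class:`Text`.

    ``nodes[i]`` is the node with ``node_id == i`` (preorder).  ``leaves``
    lists leaves in DFS order (i.e. lexicographic suffix order), and
    ``leaf_by_suffix[i]`` is the leaf carrying suffix index ``i``.
    """

    def __init__(self, text: Text):
        self.text = text
        self.root: STNode = None  # type: ignore[assignment]
        self.nodes: list = []
        self.internal_nodes: list = []
        self.leaves: list = []
        self.leaf_suffixes: list = []  # suffix index per leaf, DFS order
        self.leaf_by_suffix: list = []
        self.height: int = 0  # max node count on a root-to-internal-node path
        self._internal_ids: list = []

    @property
    def n(self) -> int:
        return self.text.n

    @property
    def sigma(self) -> int:
        return self.text.sigma

    @property
    def num_leaves(self) -> int:
        return len(self.leaves)

    @property
    def num_internal(self) -> int:
        return len(self.internal_nodes)

    def path_label(self, node: STNode) -> str:
        """Concatenated edge labels from the root down to ``node``."""
        parts = []
        v = node
        while v.parent is not None:
            parts.append(self.text.symbols[v.start : v.end])
            v = v.parent
        return "".join(reversed(parts))

    def dump_tsv(self, fh) -> None:
        """Debug dump: node_id, parent_id, edge label, depth, slink id, suffix index."""
        fh.write("node_id\tparent_id\tedge_label\tdepth\tsuffix_link_id\tsuffix_index\n")
        for v in self.nodes:
            pid = "" if v.parent is None else str(v.parent.node_id)
            sl = "" if v.suffix_link is None else str(v.suffix_link.node_id)
            si = "" if v.is_internal else str(v.suffix_index)
            fh.write(
                "%d\t%s\t%s\t%d\t%s\t%s\n"
                % (v.node_id, pid, v.edge_label(self.text), v.string_depth, sl, si)
            )


def _ukkonen_raw(s: str):
    """Ukkonen's algorithm over raw parallel arrays.

    Returns (start, end, child, slink) where ``end == -1`` marks a leaf whose
    edge is open-ended, ``child`` holds a char->index dict per internal node
    and ``None`` per leaf, and node 0 is the root.
    """
    n = len(s)
    start = [0]
    end = [0]
    child: list = [{}]
    slink = [0]

    an = 0  # active node
    ae = 0  # active edge (index into s of its first character)
    al = 0  # active length
    remainder = 0

    for i in range(n):
        ci = s[i]
        last = 0
        remainder += 1
        while remainder > 0:
            if al == 0:
                ae = i
            ec = s[ae]
            nxt = child[an].get(ec)
            if nxt is None:
                start.append(i)
                end.append(-1)
                child.append(None)
                slink.append(0)
                child[an][ec] = len(start) - 1
                if last:
                    slink[last] = an
                    last = 0
            else:
                en = end[nxt]
                elen = (i + 1 if en == -1 else en) - start[nxt]
                if al >= elen:
                    an = nxt
                    al -= elen
                    ae += elen
                    continue
                if s[start[nxt] + al] == ci:
                    al += 1
                    if last:
                        slink[last] = an
                    break
                # split the edge into (an)--sp--(nxt) and hang a new leaf off sp
                start.append(start[nxt])
                end.append(start[nxt] + al)
                child.append({})
                slink.append(0)
                sp = len(start) - 1
                child[an][ec] = sp
                start.append(i)
                end.append(-1)
                child.append(None)
                slink.append(0)
                child[sp][ci] = len(start) - 1
                start[nxt] += al
                child[sp][s[start[nxt]]] = nxt
                if last:
                    slink[last] = sp
                last = sp
            remainder -= 1
            if an == 0 and al > 0:
                al -= 1
                ae = i - remainder + 1
            elif an != 0:
                an = slink[an]
    return start, end, child, slink


def _walk_down(tree: SuffixTree, origin: STNode, lo: int, hi: int) -> STNode:
    """Skip/count walk from ``origin`` along text[lo:hi]; must end at a node."""
    s = tree.text.symbols
    v = origin
    while lo < hi:
        v = v.children[s[lo]]  # type: ignore[index]
        step = v.end - v.start
        lo += step
    if lo != hi:
        raise IntegrityError("suffix link repair walk did not land on a node")
    return v


def build_suffix_tree(text: Union[Text, str]) -> SuffixTree:
    """Build the fully annotated suffix tree of ``text``.

    Accepts a :class:`Text` or a string already carrying a final sentinel.
    Construction is O(n * sigma) time/memory and uses no recursion.
    """
    if isinstance(text, str):
        text = Text(text)
    s = text.symbols
    n = len(s)
    start, end, rawchild, rawslink = _ukkonen_raw(s)

    tree = SuffixTree(text)
    nodes: list = [None] * len(start)

    # Iterative DFS: children in ascending first-char order; preorder node ids.
    root = STNode()
    root.start = root.end = 0
    root.children = {}
    nodes[0] = root
    tree.root = root

    order: list = []  # nodes in preorder
    # frame: [raw_id, stnode, sorted raw child ids, next child ptr]
    stack = [[0, root, sorted(rawchild[0].items()), 0]]
    leaf_rank = 0
    height = 1
    path_len = [1]  # parallel to stack: node count root..frame node
    while stack:
        frame = stack[-1]
        raw_id, node, kids, ptr = frame
        if node.node_id == -1:
            node.node_id = len(order)
            node.dfs_in = node.node_id
            node.leaf_lo = leaf_rank
            order.append(node)
        if ptr < len(kids):
            frame[3] += 1
            ch, raw_kid = kids[ptr]
            kid = STNode()
            nodes[raw_kid] = kid
            kid.parent = node
            kid.start = start[raw_kid]
            kid.end = n if end[raw_kid] == -1 else end[raw_kid]
            kid.string_depth = node.string_depth + (kid.end - kid.start)
            kid.first_char = ch if node is root else node.first_char
            if rawchild[raw_kid] is None:
                kid.node_id = len(order)
                kid.dfs_in = kid.node_id
                kid.dfs_out = kid.node_id
                kid.suffix_index = n - kid.string_depth
                kid.leaf_count = 1
                kid.leaf_lo = kid.leaf_hi = leaf_rank
                leaf_rank += 1
                order.append(kid)
                tree.leaves.append(kid)
                node.children[ch] = kid
            else:
                kid.children = {}
                node.children[ch] = kid
                stack.append([raw_kid, kid, sorted(rawchild[raw_kid].items()), 0])
                plen = path_len[-1] + 1
                path_len.append(plen)
                if plen > height:
                    height = plen
        else:
            node.dfs_out = len(order) - 1
            node.leaf_hi = leaf_rank - 1
            node.leaf_count = node.leaf_hi - node.leaf_lo + 1
            tree.internal_nodes.append(node)
            stack.pop()
            path_len.pop()

    tree.nodes = order
    tree.internal_nodes.sort(key=lambda v: v.node_id)
    tree._internal_ids = [v.node_id for v in tree.internal_nodes]
    tree.height = height
    tree.leaf_suffixes = [l.suffix_index for l in tree.leaves]
    tree.leaf_by_suffix = [None] * n
    for l in tree.leaves:
        tree.leaf_by_suffix[l.suffix_index] = l

    if len(tree.leaves) != n:
        raise IntegrityError("leaf count %d != n %d" % (len(tree.leaves), n))
    if any(l is None for l in tree.leaf_by_suffix):
        raise IntegrityError("leaf suffix indexes are not a permutation of 0..n-1")

    # Materialize suffix links on the frozen nodes; repair any the online
    # construction left unset (cheap depth check, walk-down fallback).
    for raw_id, node in enumerate(nodes):
        if node is None or node.is_leaf or node.parent is None:
            continue
        sl = nodes[rawslink[raw_id]]
        if sl is None or sl.is_leaf or sl is node or sl.string_depth != node.string_depth - 1:
            sl = None
        node.suffix_link = sl
    for node in tree.internal_nodes:
        if node.parent is None or node.suffix_link is not None:
            continue
        p = node.parent
        origin = tree.root if p.parent is None else p.suffix_link
        if origin is None:
            raise IntegrityError("cannot repair suffix link of node %d" % node.node_id)
        lo = node.start + (1 if p.parent is None else 0)
        node.suffix_link = _walk_down(tree, origin, lo, node.end)
    for node in tree.internal_nodes:
        if node.parent is not None and node.suffix_link is None:
            raise IntegrityError("internal node %d has no suffix link" % node.node_id)
    return tree


@dataclass(frozen=True)
class LabelHit:
    """Result of locating a label: the node at/below the endpoint.

    ``edge_offset == 0`` means the label ends exactly at ``node``; otherwise
    it ends after consuming ``edge_offset`` characters of the edge entering
    ``node``.
    """

    node: STNode
    edge_offset: int

    @property
    def at_node(self) -> bool:
        return self.edge_offset == 0


def locate_node_by_label(tree: SuffixTree, label: str) -> Optional[LabelHit]:
    """Walk ``label`` from the root; ``None`` when it does not occur."""
    if not label:
        raise ContractViolation("label must be non-empty")
    s = tree.text.symbols
    v = tree.root
    i = 0
    while i < len(label):
        nxt = v.children.get(label[i]) if v.children is not None else None
        if nxt is None:
            return None
        span = nxt.end - nxt.start
        take = min(span, len(label) - i)
        if s[nxt.start : nxt.start + take] != label[i : i + take]:
            return None
        i += take
        v = nxt
        if take < span:
            return LabelHit(v, take)
    return LabelHit(v, 0)


def node_by_label(tree: SuffixTree, label: str) -> STNode:
    """The node whose root-path label is exactly ``label`` (KeyError otherwise)."""
    hit = locate_node_by_label(tree, label)
    if hit is None or not hit.at_node:
        raise KeyError("no node with path label %r" % label)
    return hit.node


def _require_internal(x: STNode) -> None:
    if x.is_leaf:
        raise ContractViolation("operation requires an internal node, got leaf %d" % x.node_id)


def su_set(tree: SuffixTree, x: STNode) -> set:
    """Start positions in T of the suffix tails hanging below ``x``."""
    _require_internal(x)
    d = x.string_depth
    ls = tree.leaf_suffixes
    return {d + ls[i] for i in range(x.leaf_lo, x.leaf_hi + 1)}


def s_set(tree: SuffixTree, x: STNode) -> set:
    """Suffix indexes of the leaves below ``x``."""
    _require_internal(x)
    ls = tree.leaf_suffixes
    return {ls[i] for i in range(x.leaf_lo, x.leaf_hi + 1)}


def pu_set(tree: SuffixTree, x: STNode) -> set:
    """All proper internal descendants of ``x``."""
    _require_internal(x)
    ids = tree._internal_ids
    lo = bisect_right(ids, x.node_id)
    hi = bisect_right(ids, x.dfs_out)
    return set(tree.internal_nodes[lo:hi])


def is_descendant(tree: SuffixTree, a: STNode, b: STNode, strict: bool = False) -> bool:
    """True iff ``a`` lies in ``b``'s subtree (O(1) via DFS intervals)."""
    if a is b:
        return not strict
    return b.dfs_in < a.dfs_in <= b.dfs_out
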