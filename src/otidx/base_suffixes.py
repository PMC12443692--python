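"""Base-suffix enumeration under every internal node.

A suffix position ``s`` is *base* at internal node ``x`` when ``s`` lies in
``SU(x)`` but in no ``SU(c)`` for ``c`` in ``SLS(x)``.  Four interchangeable
routes are provided:

* :func:`bs_oracle` — the defining set difference (ground truth);
* :func:`bs_algorithm1` — one global membership structure filled during an
  OSHR post-order (O(n*h) membership tests);
* :func:`bs_algorithm2` — per-leaf predecessor containment checks against
  the SLS DFS intervals (binary search over <= sigma intervals);
* :func:`bs_linear` — constant amortized work per base suffix, driven by
  reference leaves / reference internal nodes and their inbetween chains.

All four return identical tables; the linear route additionally asserts that
no (node, suffix) pair is ever emitted twice.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Optional

from .errors import IntegrityError
from .instrument import OpCounter
from .oshr import OSHRView
from .suffix_core import STNode, SuffixTree

__all__ = [
    "BaseSuffixTable",
    "RefRecord",
    "ReferenceAnnotation",
    "bs_oracle",
    "bs_algorithm1",
    "bs_algorithm2",
    "find_reference_annotation",
    "bs_linear",
]


class BaseSuffixTable:
    """Per-internal-node sorted base suffixes, keyed by node_id."""

    def __init__(self, by_node: dict):
        self.by_node = by_node  # node_id -> sorted tuple of ints

    def of(self, x: STNode) -> tuple:
        return self.by_node[x.node_id]

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.by_node.values())

    def global_union(self) -> set:
        out: set = set()
        for v in self.by_node.values():
            out.update(v)
        return out

    def __eq__(self, other) -> bool:
        return isinstance(other, BaseSuffixTable) and self.by_node == other.by_node

    def __ne__(self, other) -> bool:
        return not self.__eq__(other)

    def dump_tsv(self, tree: SuffixTree, fh, max_set_size: Optional[int] = None) -> None:
        fh.write("node_id\tdepth\tcount\tbase_suffixes\n")
        for v in tree.internal_nodes:
            bs = self.by_node[v.node_id]
            shown = "" if (max_set_size is not None and len(bs) > max_set_size) else ",".join(map(str, bs))
            fh.write("%d\t%d\t%d\t%s\n" % (v.node_id, v.string_depth, len(bs), shown))


def _su_values(tree: SuffixTree, x: STNode) -> list:
    d = x.string_depth
    ls = tree.leaf_suffixes
    return [d + ls[i] for i in range(x.leaf_lo, x.leaf_hi + 1)]


def bs_oracle(tree: SuffixTree, view: OSHRView, counter: Optional[OpCounter] = None) -> BaseSuffixTable:
    """Ground truth by explicit set difference: SU(v) - union of child SUs."""
    by_node = {}
    for v in view.post_order:
        su = set(_su_values(tree, v))
        covered: set = set()
        for c in view.sls[v.node_id]:
            covered.update(_su_values(tree, c))
        base = su - covered
        by_node[v.node_id] = tuple(sorted(base))
        if counter is not None:
            counter.add("node_visits")
            counter.add("set_ops", len(su) + len(covered))
    return BaseSuffixTable(by_node)


def bs_algorithm1(tree: SuffixTree, view: OSHRView, counter: Optional[OpCounter] = None) -> BaseSuffixTable:
    """Global seen-set filled during the OSHR post-order.

    A suffix of SU(v) absent from H is base for v and is then inserted, so
    every membership test after the first hit is saved for ancestors.
    """
    n = tree.n
    seen = bytearray(n)
    by_node = {}
    for v in view.post_order:
        su = _su_values(tree, v)
        base = []
        for s in su:
            if not seen[s]:
                seen[s] = 1
                base.append(s)
        base.sort()
        by_node[v.node_id] = tuple(base)
        if counter is not None:
            counter.add("node_visits")
            counter.add("membership_tests", len(su))
    return BaseSuffixTable(by_node)


def bs_algorithm2(tree: SuffixTree, view: OSHRView, counter: Optional[OpCounter] = None) -> BaseSuffixTable:
    """Per-leaf predecessor check against the SLS DFS intervals.

    Suffix Depth(v)+z is base at v iff z == 0 or the leaf carrying suffix
    index z-1 is under no node of SLS(v); the containment test is a binary
    search over the <= sigma sorted child intervals.
    """
    ls = tree.leaf_suffixes
    leaf_by_suffix = tree.leaf_by_suffix
    by_node = {}
    for v in tree.internal_nodes:
        kids = view.sls[v.node_id]
        ivals = sorted((c.dfs_in, c.dfs_out) for c in kids)
        starts = [iv[0] for iv in ivals]
        d = v.string_depth
        base = []
        for i in range(v.leaf_lo, v.leaf_hi + 1):
            z = ls[i]
            if counter is not None:
                counter.add("leaf_checks")
            if z == 0:
                base.append(d)
                continue
            p = leaf_by_suffix[z - 1].dfs_in
            j = bisect_right(starts, p) - 1
            if counter is not None:
                counter.add("bisect_probes")
            if j >= 0 and p <= ivals[j][1]:
                continue  # predecessor leaf covered by an SLS child
            base.append(d + z)
        base.sort()
        by_node[v.node_id] = tuple(base)
    return BaseSuffixTable(by_node)


@dataclass(frozen=True)
class RefRecord:
    """One reference record and its inbetween chain.

    For a leaf record, ``a`` is the leaf with suffix index ``x`` whose
    successor leaf's parent chain opens a gap; for an internal record ``a``
    is the internal node.  ``chain`` lists the inbetween nodes deepest-first;
    each entry is the parent of the previous one.
    """

    kind: str  # "leaf" | "internal"
    a: STNode
    b: STNode
    c: STNode
    d: STNode
    chain: tuple


@dataclass
class ReferenceAnnotation:
    reference_leaves: list = field(default_factory=list)
    reference_internals: list = field(default_factory=list)
    inbetween_of: dict = field(default_factory=dict)  # node_id -> [(kind, record idx)]

    def _register(self, kind: str, idx: int, rec: RefRecord) -> None:
        for w in rec.chain:
            self.inbetween_of.setdefault(w.node_id, []).append((kind, idx))


def _gap_chain(c_parent: STNode, stop: Optional[STNode]) -> tuple:
    """Ancestors of C strictly below ``stop`` (deepest first), starting at C's parent.

    ``stop is None`` encodes the virtual super-root convention: the chain
    then extends up to and including the root.
    """
    chain = []
    w = c_parent
    while w is not None and w is not stop:
        chain.append(w)
        w = w.parent
    return tuple(chain)


def find_reference_annotation(tree: SuffixTree, view: OSHRView, counter: Optional[OpCounter] = None) -> ReferenceAnnotation:
    """Materialize all reference leaf/internal records and inbetween chains.

    A leaf record exists for the leaf with suffix index x <= n-2 iff
    SL(parent) differs from the parent of leaf x+1 (with SL(root) read as a
    virtual super-root).  Internal records are the analogue with C = SL(A).
    Total chain length is bounded by the global base-suffix budget.
    """
    ann = ReferenceAnnotation()
    n = tree.n
    leaf_by_suffix = tree.leaf_by_suffix
    for x in range(n - 1):
        a = leaf_by_suffix[x]
        b = a.parent
        c = leaf_by_suffix[x + 1]
        d = c.parent
        slb = b.suffix_link if b.parent is not None else None
        if counter is not None:
            counter.add("record_scans")
        if slb is d:
            continue
        chain = _gap_chain(d, slb)
        if not chain:
            raise IntegrityError("empty inbetween chain for reference leaf %d" % x)
        rec = RefRecord("leaf", a, b, c, d, chain)
        ann._register("leaf", len(ann.reference_leaves), rec)
        ann.reference_leaves.append(rec)
        if counter is not None:
            counter.add("chain_steps", len(chain))
    for a in tree.internal_nodes:
        if a.parent is None:
            continue
        if counter is not None:
            counter.add("record_scans")
        c = a.suffix_link
        if c.parent is None:  # SL(a) is the root: no proper ancestors, no gap
            continue
        b = a.parent
        d = c.parent
        slb = b.suffix_link if b.parent is not None else None
        if slb is d:
            continue
        chain = _gap_chain(d, slb)
        if not chain:
            raise IntegrityError("empty inbetween chain for reference internal %d" % a.node_id)
        rec = RefRecord("internal", a, b, c, d, chain)
        ann._register("internal", len(ann.reference_internals), rec)
        ann.reference_internals.append(rec)
        if counter is not None:
            counter.add("chain_steps", len(chain))
    return ann


def bs_linear(
    tree: SuffixTree,
    view: OSHRView,
    annotation: ReferenceAnnotation,
    counter: Optional[OpCounter] = None,
) -> BaseSuffixTable:
    """Derive each base suffix in O(1) from the reference annotation.

    Contribution rules (each guarded by a global duplicate check, since the
    n base suffixes partition 0..n-1):

    * the leaf with suffix index 0 is base at every internal ancestor u,
      contributing Depth(u);
    * a reference leaf with suffix index x contributes Depth(w) + x + 1 to
      every inbetween node w of its chain;
    * a reference internal node A contributes Depth(w) + z + 1 to every
      inbetween node w, for every leaf suffix index z under A.
    """
    n = tree.n
    seen = bytearray(n)
    emitted = 0
    by_node: dict = {v.node_id: [] for v in tree.internal_nodes}

    def emit(node_id: int, s: int) -> None:
        nonlocal emitted
        if seen[s]:
            raise IntegrityError("base suffix %d emitted twice (at node %d)" % (s, node_id))
        seen[s] = 1
        emitted += 1
        by_node[node_id].append(s)

    # Suffix 0 has no predecessor: base at every internal ancestor.
    u = tree.leaf_by_suffix[0].parent
    while u is not None:
        emit(u.node_id, u.string_depth)
        u = u.parent

    ls = tree.leaf_suffixes
    for rec in annotation.reference_leaves:
        x = rec.a.suffix_index
        for w in rec.chain:
            emit(w.node_id, w.string_depth + x + 1)
    for rec in annotation.reference_internals:
        a = rec.a
        for w in rec.chain:
            wd = w.string_depth + 1
            for i in range(a.leaf_lo, a.leaf_hi + 1):
                emit(w.node_id, wd + ls[i])

    if emitted != n:
        raise IntegrityError("linear pass emitted %d base suffixes, expected %d" % (emitted, n))
    if counter is not None:
        counter.add("node_visits", len(tree.internal_nodes))
        counter.add("emissions", emitted)
        counter.add(
            "record_scans",
            len(annotation.reference_leaves) + len(annotation.reference_internals),
        )
    return BaseSuffixTable({nid: tuple(sorted(v)) for nid, v in by_node.items()})
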