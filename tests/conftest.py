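"""Shared fixtures and independent brute-force oracles.

The oracles work purely on strings (substring scans and right-maximality
enumeration) and never touch the tree structures they are used to check.
"""

from __future__ import annotations

import random

import pytest

import otidx as ox

WORKED = "AGCATAATTTAACTAAG$"


# ---------------------------------------------------------------------------
# brute-force oracles (string-only; independent of the package internals)


def brute_internal_labels(T: str) -> set:
    """Labels of internal nodes: the empty string plus every right-maximal substring."""
    ext: dict = {}
    n = len(T)
    for i in range(n):
        for j in range(i + 1, n):
            ext.setdefault(T[i:j], set()).add(T[j])
    return {""} | {w for w, chars in ext.items() if len(chars) >= 2}


def brute_su(T: str, label: str) -> set:
    """Depth + suffix index over the leaves below the node labeled ``label``."""
    return {i + len(label) for i in range(len(T)) if T.startswith(label, i)}


def brute_sls(T: str, labels: set, label: str) -> set:
    """Labels whose suffix link points at ``label``."""
    return {m for m in labels if len(m) == len(label) + 1 and m[1:] == label}


def brute_bs(T: str) -> dict:
    """label -> sorted base suffixes, by the defining set difference."""
    labels = brute_internal_labels(T)
    out = {}
    for x in labels:
        su = brute_su(T, x)
        for c in brute_sls(T, labels, x):
            su -= brute_su(T, c)
        out[x] = tuple(sorted(su))
    return out


def brute_bp(T: str) -> dict:
    """label -> sorted bottom base labels, by the defining set difference."""
    labels = brute_internal_labels(T)
    out = {}
    for x in labels:
        pu = {w for w in labels if w != x and w.startswith(x)}
        covered = set()
        for c in brute_sls(T, labels, x):
            for y in {w for w in labels if w != c and w.startswith(c)}:
                covered.add(y[1:])
        out[x] = tuple(sorted(pu - covered))
    return out


def naive_occurrences(T: str, pattern: str) -> set:
    return {i for i in range(len(T)) if T.startswith(pattern, i)}


# ---------------------------------------------------------------------------
# built structures


def build_stack(T: str):
    """(tree, view, annotation) for a sentinel-terminated string."""
    tree = ox.build_suffix_tree(ox.Text(T))
    view = ox.build_oshr(tree)
    ann = ox.find_reference_annotation(tree, view)
    return tree, view, ann


@pytest.fixture(scope="session")
def worked():
    return build_stack(WORKED)


@pytest.fixture(scope="session")
def run_stack():
    return build_stack("AAAA$")


def label_node(tree, label):
    return tree.root if label == "" else ox.node_by_label(tree, label)


def bs_by_label(tree, table):
    return {tree.path_label(v): table.of(v) for v in tree.internal_nodes}


def bp_by_label(tree, table):
    return {
        tree.path_label(v): tuple(sorted(tree.path_label(tree.nodes[i]) for i in table.of(v)))
        for v in tree.internal_nodes
    }


def random_strings(count: int, seed: int, max_len: int = 200, alphabets=("ACGT", "AB")):
    rng = random.Random(seed)
    out = []
    for _ in range(count):
        alpha = rng.choice(alphabets)
        L = rng.randint(1, max_len)
        out.append("".join(rng.choice(alpha) for _ in range(L)) + "$")
    return out


ADVERSARIAL = (
    ["A" * k + "$" for k in (1, 2, 3, 5, 20, 100)]
    + ["AB" * k + "$" for k in (1, 3, 10, 50)]
)


def _fib(min_len):
    a, b = "A", "AB"
    while len(b) < min_len:
        a, b = b, b + a
    return b


ADVERSARIAL.append(_fib(233) + "$")
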