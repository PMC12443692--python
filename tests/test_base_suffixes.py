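import pytest

import otidx as ox
from otidx.errors import IntegrityError
from otidx.instrument import OpCounter

from conftest import (
    ADVERSARIAL,
    brute_bs,
    bs_by_label,
    build_stack,
    label_node,
    random_strings,
)

ALGOS = {
    "oracle": lambda t, v, a: ox.bs_oracle(t, v),
    "a1": lambda t, v, a: ox.bs_algorithm1(t, v),
    "a2": lambda t, v, a: ox.bs_algorithm2(t, v),
    "linear": lambda t, v, a: ox.bs_linear(t, v, a),
}


@pytest.fixture(scope="module", params=sorted(ALGOS))
def algo(request):
    return ALGOS[request.param]


class TestWorkedValues:
    def test_oracle_worked_sets(self, worked):
        tree, view, _ = worked
        table = bs_by_label(tree, ox.bs_oracle(tree, view))
        assert table["A"] == (1, 4, 6, 11, 15)
        assert table["AA"] == ()
        assert table["TAA"] == (7, 12, 16)

    def test_any_algo_worked_sets(self, worked, algo):
        tree, view, ann = worked
        table = bs_by_label(tree, algo(tree, view, ann))
        assert table["T"] == (14,)
        assert table["AT"] == (5, 8)

    def test_algorithm2_predecessor_logic(self, worked):
        tree, view, _ = worked
        # predecessor of leaf 13 (leaf 12) is under no SLS(T) member -> 14 base at T
        t_node = label_node(tree, "T")
        sls = view.sls_of(t_node)
        leaf12 = tree.leaf_by_suffix[12]
        assert not any(ox.is_descendant(tree, leaf12, c) for c in sls)
        # both G-leaves' predecessors sit under AG in SLS(G) -> BS(G) empty
        table = bs_by_label(tree, ox.bs_algorithm2(tree, view))
        assert table["G"] == ()


class TestEquivalence:
    @pytest.mark.parametrize("T", ADVERSARIAL)
    def test_adversarial(self, T):
        tree, view, ann = build_stack(T)
        ref = ox.bs_oracle(tree, view)
        for fn in ALGOS.values():
            assert fn(tree, view, ann) == ref

    def test_random_battery_matches_brute_force(self):
        for T in random_strings(40, seed=51, max_len=120):
            tree, view, ann = build_stack(T)
            ref = ox.bs_oracle(tree, view)
            assert bs_by_label(tree, ref) == brute_bs(T)
            for fn in ALGOS.values():
                assert fn(tree, view, ann) == ref

    def test_conservation(self, algo):
        for T in random_strings(25, seed=52, max_len=150) + ADVERSARIAL[:6]:
            tree, view, ann = build_stack(T)
            table = algo(tree, view, ann)
            assert table.total == tree.n
            assert table.global_union() == set(range(tree.n))

    def test_bs_subset_of_su_and_oshr_leaf_equality(self):
        for T in random_strings(20, seed=53, max_len=120):
            tree, view, ann = build_stack(T)
            table = ox.bs_linear(tree, view, ann)
            for v in tree.internal_nodes:
                bs = set(table.of(v))
                su = ox.su_set(tree, v)
                assert bs <= su
                if view.is_oshr_leaf(v):
                    assert bs == su

    def test_extended_suffix_property(self):
        # every base suffix reappears in SU at every OSHR ancestor
        for T in random_strings(12, seed=54, max_len=100):
            tree, view, ann = build_stack(T)
            table = ox.bs_linear(tree, view, ann)
            for v in tree.internal_nodes:
                for a in ox.oshr_ancestors(view, v):
                    su_a = ox.su_set(tree, a)
                    for s in table.of(v):
                        assert s in su_a

    def test_coverage_characterization(self):
        # depth(u)+z is base at ancestor u of leaf z iff z==0 or leaf z-1
        # has no internal ancestor of depth exactly depth(u)+1
        for T in random_strings(12, seed=55, max_len=80):
            tree, view, ann = build_stack(T)
            table = ox.bs_linear(tree, view, ann)
            for z in range(tree.n):
                leaf = tree.leaf_by_suffix[z]
                anc_depths_prev = set()
                if z > 0:
                    w = tree.leaf_by_suffix[z - 1].parent
                    while w is not None:
                        anc_depths_prev.add(w.string_depth)
                        w = w.parent
                u = leaf.parent
                while u is not None:
                    expected = z == 0 or (u.string_depth + 1) not in anc_depths_prev
                    assert ((u.string_depth + z) in table.of(u)) == expected
                    u = u.parent


class TestReferenceAnnotation:
    def test_worked_reference_leaf(self, worked):
        tree, view, ann = worked
        recs = [r for r in ann.reference_leaves if r.a.suffix_index == 6]
        assert len(recs) == 1
        assert [tree.path_label(w) for w in recs[0].chain] == ["TT"]

    def test_worked_reference_internal(self, worked):
        tree, view, ann = worked
        recs = [r for r in ann.reference_internals if tree.path_label(r.a) == "TAA"]
        assert len(recs) == 1
        assert [tree.path_label(w) for w in recs[0].chain] == ["A"]

    def test_run_string_single_record(self, run_stack):
        # every SL(parent) equals the next parent except at the deepest leaf
        # pair, whose gap record is what makes suffix 4 base at node AAA
        tree, view, ann = run_stack
        assert len(ann.reference_internals) == 0
        assert len(ann.reference_leaves) == 1
        rec = ann.reference_leaves[0]
        assert rec.a.suffix_index == 0
        assert [tree.path_label(w) for w in rec.chain] == ["AAA"]

    def test_record_existence_condition(self):
        for T in random_strings(15, seed=56, max_len=100):
            tree, view, ann = build_stack(T)
            have = {r.a.suffix_index for r in ann.reference_leaves}
            for x in range(tree.n - 1):
                b = tree.leaf_by_suffix[x].parent
                d = tree.leaf_by_suffix[x + 1].parent
                slb = b.suffix_link if b.parent is not None else None
                assert (x in have) == (slb is not d)

    def test_chains_are_contiguous_parent_segments(self):
        for T in random_strings(15, seed=57, max_len=100):
            tree, view, ann = build_stack(T)
            for rec in ann.reference_leaves + ann.reference_internals:
                for prev, nxt in zip(rec.chain, rec.chain[1:]):
                    assert prev.parent is nxt

    def test_sentinel_leaf_never_reference(self):
        for T in random_strings(10, seed=58, max_len=60):
            tree, view, ann = build_stack(T)
            assert all(r.a.suffix_index != tree.n - 1 for r in ann.reference_leaves)


class TestLinearDetails:
    def test_contribution_rules_worked(self, worked):
        tree, view, ann = worked
        table = bs_by_label(tree, ox.bs_linear(tree, view, ann))
        assert 9 in table["TT"] and table["TT"] == (9, 10)
        assert {6, 11, 15} <= set(table["A"])
        assert table[""] == (0,)
        assert 1 in table["A"] and 2 in table["AG"]

    def test_duplicate_emission_detected(self, worked):
        tree, view, ann = worked
        rec = ann.reference_leaves[0]
        ann.reference_leaves.append(rec)  # corrupt: same record twice
        with pytest.raises(IntegrityError):
            ox.bs_linear(tree, view, ann)
        ann.reference_leaves.pop()

    def test_linear_op_budget(self):
        for T in random_strings(10, seed=59, max_len=200):
            tree, view, ann = build_stack(T)
            counter = OpCounter(n=tree.n, sigma=tree.sigma)
            ox.bs_linear(tree, view, ann, counter)
            assert counter.total() <= 6 * tree.sigma * tree.n

    def test_algorithm1_counts_su_items(self, worked):
        tree, view, _ = worked
        counter = OpCounter()
        ox.bs_algorithm1(tree, view, counter)
        expected = sum(v.leaf_count for v in tree.internal_nodes)
        assert counter["membership_tests"] == expected
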