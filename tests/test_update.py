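"""In-place insertion, deletion and coordinate updates.

The ground truth throughout is the *rebuild oracle*: after any edit, the
store must be query-equivalent (identical hit multisets on an exhaustive
probe grid) to a store freshly built from the surviving interval set, and
must pass the full structural validator.
"""

import numpy as np
import pytest

from conftest import assert_query_equivalent

from nclistdb import (
    GenomicInterval,
    build,
    query_point,
    delete,
    insert,
    update_coordinates,
    validate_store,
)
from nclistdb.core import ROOT_SUB, NCListStore
from nclistdb.synth import REGIMES, generate_regime_intervals


def iv(start, stop, label="x", chrom="chr1"):
    return GenomicInterval(chrom, start, stop, label)


def label_subs(store):
    return {store.masterkey[n.id]: n.sub for n in store.nodes.values()}


class TestInsertCases:
    def test_disjoint_into_empty_store_root_no_edges(self):
        store = build([])
        nid = insert(store, iv(0, 10, "a"))
        assert store.nodes[nid].sub == ROOT_SUB and store.edges == {}
        validate_store(store)

    def test_root_insert_capturing_root_interval(self):
        # new interval contains an existing root interval: the captured
        # interval moves to a fresh sublist reached by a new edge
        store = build([iv(0, 10, "a")])
        nid = insert(store, iv(0, 50, "big"))
        assert store.nodes[nid].sub == ROOT_SUB
        (captured,) = [i for i in store.nodes if i != nid]
        assert store.edges == {nid: store.nodes[captured].sub}
        assert store.nodes[captured].sub != ROOT_SUB
        validate_store(store)
        assert_query_equivalent(store, [iv(0, 10, "a"), iv(0, 50, "big")])

    def test_internal_insert_takes_sub_of_captured_child(self):
        # inserting between parent and child: new node adopts the child's
        # sublist, the child moves to a fresh sublist under the new node
        store = build([iv(0, 100, "a"), iv(10, 20, "b")])
        b_sub_before = label_subs(store)["b"]
        nid = insert(store, iv(5, 50, "c"))
        subs = label_subs(store)
        assert subs["c"] == b_sub_before
        assert store.edges[nid] == subs["b"] and subs["b"] != b_sub_before
        validate_store(store)
        assert_query_equivalent(
            store, [iv(0, 100, "a"), iv(10, 20, "b"), iv(5, 50, "c")]
        )

    def test_leaf_insert_joins_existing_sublist(self):
        store = build([iv(0, 100, "a"), iv(10, 20, "b")])
        nid = insert(store, iv(40, 50, "d"))
        subs = label_subs(store)
        assert subs["d"] == subs["b"]  # same sublist, no new edge
        assert len(store.edges) == 1
        validate_store(store)

    def test_leaf_insert_under_childless_parent_creates_edge(self):
        store = build([iv(0, 100, "a"), iv(200, 300, "z")])
        nid = insert(store, iv(10, 20, "e"))
        a_id = next(i for i, l in store.masterkey.items() if l == "a")
        assert store.edges == {a_id: store.nodes[nid].sub}
        validate_store(store)

    def test_partial_capture_moves_only_contained_members(self):
        # the new interval contains a proper subset of the root sublist:
        # only the contained members move beneath it
        ivs = [iv(0, 10, "a"), iv(20, 30, "b"), iv(40, 50, "c")]
        store = build(ivs)
        nid = insert(store, iv(15, 35, "cap"))
        subs = label_subs(store)
        assert subs["cap"] == ROOT_SUB and subs["a"] == ROOT_SUB and subs["c"] == ROOT_SUB
        assert subs["b"] != ROOT_SUB and store.edges == {nid: subs["b"]}
        validate_store(store)
        assert_query_equivalent(store, ivs + [iv(15, 35, "cap")])

    def test_invalid_interval_leaves_store_unchanged(self):
        store = build([iv(0, 10, "a")])
        snapshot = (dict(store.nodes), dict(store.edges), store.next_id, store.next_sub)
        with pytest.raises(ValueError):
            insert(store, ("chr1", 9, 3, "bad"))
        assert (dict(store.nodes), dict(store.edges), store.next_id, store.next_sub) == snapshot


class TestDeleteCases:
    def test_delete_only_node_empties_store(self):
        store = build([iv(0, 10, "a")])
        removed = delete(store, 1)
        assert removed == iv(0, 10, "a")
        assert not store.nodes and not store.edges and not store.masterkey
        assert not store.sublists
        validate_store(store)

    def test_delete_root_parent_promotes_children_to_root(self):
        store = build([iv(0, 100, "a"), iv(10, 20, "b")])
        delete(store, 1)
        assert label_subs(store) == {"b": ROOT_SUB}
        assert store.edges == {}
        validate_store(store)

    def test_delete_internal_parent_children_take_its_sub(self):
        store = build([iv(0, 100, "a"), iv(10, 60, "b"), iv(20, 30, "c")])
        b_id = next(i for i, l in store.masterkey.items() if l == "b")
        b_sub = store.nodes[b_id].sub
        delete(store, b_id)
        assert label_subs(store)["c"] == b_sub
        validate_store(store)
        assert_query_equivalent(store, [iv(0, 100, "a"), iv(20, 30, "c")])

    def test_delete_sole_sublist_member_drops_parent_edge(self):
        store = build([iv(0, 100, "a"), iv(10, 20, "b")])
        b_id = next(i for i, l in store.masterkey.items() if l == "b")
        delete(store, b_id)
        assert store.edges == {}
        validate_store(store)

    def test_containment_repair_reattaches_promoted_child(self):
        # c is a child of a; a and b partially overlap and b strictly
        # contains c.  Deleting a must re-attach c beneath b, not leave it
        # nesting inside a root-level sibling.
        ivs = [iv(0, 10, "a"), iv(5, 15, "b"), iv(6, 9, "c")]
        store = build(ivs)  # default rule: c under a
        a_id = next(i for i, l in store.masterkey.items() if l == "a")
        delete(store, a_id)
        b_id = next(i for i, l in store.masterkey.items() if l == "b")
        assert store.parent_of(next(i for i, l in store.masterkey.items() if l == "c")) == b_id
        validate_store(store)
        assert_query_equivalent(store, ivs[1:])

    def test_unknown_id_error_store_unchanged(self):
        store = build([iv(0, 10, "a")])
        with pytest.raises(KeyError):
            delete(store, 99)
        assert set(store.nodes) == {1}


class TestUpdateCoordinates:
    def test_identity_update_is_query_equivalent(self, tiny_nested):
        store = build(tiny_nested)
        update_coordinates(store, 2, 10, 20)
        validate_store(store)
        assert_query_equivalent(store, tiny_nested)

    def test_shrink_parent_promotes_child(self):
        store = build([iv(0, 100, "a"), iv(10, 20, "b")])
        new_id = update_coordinates(store, 1, 0, 5)
        subs = label_subs(store)
        assert subs == {"a": ROOT_SUB, "b": ROOT_SUB}
        assert store.masterkey[new_id] == "a"
        validate_store(store)
        assert_query_equivalent(store, [iv(0, 5, "a"), iv(10, 20, "b")])

    def test_widen_leaf_captures_former_sibling(self):
        store = build([iv(0, 10, "a"), iv(20, 30, "b")])
        new_id = update_coordinates(store, 2, 15, 40)
        a_id = next(i for i, l in store.masterkey.items() if l == "a")
        assert store.parent_of(a_id) is None  # a stays root; b does not contain a
        # now widen b over a
        new_id = update_coordinates(store, new_id, 0, 40)
        a_id = next(i for i, l in store.masterkey.items() if l == "a")
        assert store.parent_of(a_id) == new_id
        validate_store(store)

    def test_invalid_coordinates_leave_store_unchanged(self, tiny_nested):
        store = build(tiny_nested)
        before = (dict(store.nodes), dict(store.edges))
        with pytest.raises(ValueError):
            update_coordinates(store, 2, 30, 30)
        assert (dict(store.nodes), dict(store.edges)) == before


class TestEditScripts:
    """Randomised interleaved edits: incremental must equal batch."""

    def _run_script(self, seed, n_edits=60):
        rng = np.random.default_rng(seed)
        store = build([])
        live: dict[int, GenomicInterval] = {}
        pool = generate_regime_intervals(n_edits, "mixed", seed=seed)
        k = 0
        for step in range(n_edits):
            if live and rng.random() < 0.35:
                victim = int(rng.choice(list(live)))
                delete(store, victim)
                del live[victim]
            elif live and rng.random() < 0.15:
                victim = int(rng.choice(list(live)))
                src = pool[k % len(pool)]
                k += 1
                nid = update_coordinates(store, victim, src.start, src.stop)
                old = live.pop(victim)
                live[nid] = GenomicInterval(old.chrom, src.start, src.stop, old.label)
            else:
                nxt = pool[k % len(pool)]
                k += 1
                nid = insert(store, nxt)
                live[nid] = nxt
            validate_store(store)
        return store, list(live.values())

    @pytest.mark.parametrize("seed", range(12))
    def test_incremental_equals_batch(self, seed):
        store, surviving = self._run_script(seed)
        assert_query_equivalent(store, surviving)
        assert sorted(store.intervals(), key=lambda i: (i.chrom, i.start, i.stop, i.label)) == sorted(
            surviving, key=lambda i: (i.chrom, i.start, i.stop, i.label)
        )

    @pytest.mark.parametrize("regime", REGIMES)
    def test_insert_then_delete_is_reversible(self, regime):
        ivs = generate_regime_intervals(40, regime, seed=77)
        store = build(ivs)
        probes_before = [
            sorted((h.start, h.stop) for h in query_point(store, "chr1", p))
            for p in range(0, 120, 3)
        ]
        nid = insert(store, iv(7, 31, "transient"))
        validate_store(store)
        delete(store, nid)
        validate_store(store)
        probes_after = [
            sorted((h.start, h.stop) for h in query_point(store, "chr1", p))
            for p in range(0, 120, 3)
        ]
        assert probes_after == probes_before

    def test_sub_values_never_recycled(self):
        store = build([iv(0, 100, "a"), iv(10, 20, "b")])
        first_sub = store.nodes[2].sub
        b_id = 2
        delete(store, b_id)
        nid = insert(store, iv(10, 20, "b2"))
        assert store.nodes[nid].sub > first_sub  # fresh, monotone counter
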