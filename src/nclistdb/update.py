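"""In-place insertion and deletion of intervals in an NCList store.

Insertion distinguishes the placement conditions by where the new interval
lands and what it captures:

* root level, captures nothing — appended to sub 0, nothing else changes;
* root level, captures root intervals — the captured intervals move to a
  fresh sublist and an edge from the new node is added;
* nested and captures members of the target sublist — the new node takes
  the sublist of its captured children, the children move to a fresh
  sublist under it;
* nested, captures nothing, parent already has a sublist — appended there;
* nested, captures nothing, parent childless — fresh sublist plus an edge
  from the parent.

When the new interval contains only a *proper subset* of the target
sublist, only the strictly contained members move; the new node joins the
original sublist alongside the untouched members.

Deletion removes the node and promotes its children into its former
sublist (root-level deletions promote to sub 0), dropping the edge.  A
promoted child that is strictly contained by a partially overlapping
member of the receiving sublist cannot legally sit there (it would break
the no-nesting-among-siblings rule), so each promoted child is re-placed
by the same parent-selection logic as insertion, carrying its subtree with
it — the containment repair step.

Every edit is transactional: argument validation happens before any
mutation, so a raised error leaves the store untouched.
"""

from __future__ import annotations

from .bed_io import GenomicInterval
from .core import (
    NCListStore,
    NodeRecord,
    PARENT_RULES,
    ROOT_SUB,
    _choose_parent,
    _contains_coords,
    _minimal_containers,
)

__all__ = ["insert", "delete", "update_coordinates"]


def _strict_containers_of(
    store: NCListStore, chrom: str, start: int, stop: int, exclude: int | None = None
) -> list[int]:
    """All attached nodes strictly containing [start, stop), sorted order.

    A node is *attached* when its ``sub`` is set; nodes queued for
    re-placement during a delete are detached and therefore invisible here
    (none of them could be a container anyway: promoted siblings never nest
    within one another).
    """
    out = [
        nid
        for nid, n in store.nodes.items()
        if nid != exclude
        and n.sub is not None
        and n.chrom == chrom
        and _contains_coords(n.start, n.stop, start, stop)
    ]
    out.sort(key=lambda nid: store.nodes[nid].sort_key())
    return out


def _place_node(store: NCListStore, nid: int) -> None:
    """Attach a detached node (subtree intact) at its correct position.

    Chooses the parent among minimal strict containers per the store's
    parent rule, then captures any members of the target sublist that the
    node strictly contains, recursively re-placing them beneath it.
    """
    node = store.nodes[nid]
    containers = _strict_containers_of(store, node.chrom, node.start, node.stop, exclude=nid)
    parent = _choose_parent(
        _minimal_containers(store, containers), store.parent_rule
    )
    if parent is None:
        sub = ROOT_SUB
    elif parent in store.edges:
        sub = store.edges[parent]
    else:
        sub = store.next_sub
        store.next_sub += 1
        store.edges[parent] = sub

    target = store.sublists.get((node.chrom, sub), [])
    captured = [
        mid
        for mid in target
        if _contains_coords(
            node.start, node.stop,
            store.nodes[mid].start, store.nodes[mid].stop,
        )
    ]
    for mid in captured:
        store._detach_from_sublist(mid)
    store._attach_to_sublist(nid, node.chrom, sub)
    # re-place captured members: each lands beneath nid (or deeper)
    for mid in captured:
        _place_node(store, mid)


def insert(store: NCListStore, interval: GenomicInterval) -> int:
    """Insert an interval in place and return its new node id.

    The store's invariants hold on return; on error the store is unchanged.
    """
    if not isinstance(interval, GenomicInterval):
        interval = GenomicInterval(*interval)  # validates eagerly
    nid = store.next_id
    store.next_id += 1
    store.nodes[nid] = NodeRecord(nid, interval.chrom, interval.start, interval.stop, None)
    store.masterkey[nid] = interval.label
    _place_node(store, nid)
    return nid


def delete(store: NCListStore, node_id: int) -> GenomicInterval:
    """Remove a node in place and return the interval it held.

    Children (if any) are promoted into the deleted node's sublist; the
    edge is dropped; a sole-member sublist disappears along with its edge;
    promoted children are containment-repaired against their new siblings.
    Unknown ids raise KeyError with the store unchanged.
    """
    if node_id not in store.nodes:
        raise KeyError(f"no node with id {node_id}")
    removed = store.interval_of(node_id)
    home_sub = store.nodes[node_id].sub

    child_sub = store.edges.pop(node_id, None)
    promoted: list[int] = []
    if child_sub is not None:
        key = (removed.chrom, child_sub)
        promoted = list(store.sublists.pop(key, []))
        for cid in promoted:
            store.nodes[cid].sub = None

    store._detach_from_sublist(node_id)
    del store.nodes[node_id]
    del store.masterkey[node_id]

    # children take the deleted node's sub value (sub 0 when it was a base
    # interval) — unless a partially overlapping member of the receiving
    # sublist strictly contains one, in which case that child is re-placed
    # beneath its container (containment repair)
    for cid in sorted(promoted, key=lambda i: store.nodes[i].sort_key()):
        c = store.nodes[cid]
        members = store.sublists.get((removed.chrom, home_sub), ())
        if any(
            _contains_coords(
                store.nodes[m].start, store.nodes[m].stop, c.start, c.stop
            )
            for m in members
        ):
            _place_node(store, cid)
        else:
            store._attach_to_sublist(cid, removed.chrom, home_sub)

    # an emptied sublist (sole-member deletion) loses its parent edge
    _drop_dangling_edges(store)
    return removed


def _drop_dangling_edges(store: NCListStore) -> None:
    live_subs = {sub for (_c, sub) in store.sublists}
    dangling = [p for p, s in store.edges.items() if s not in live_subs]
    for p in dangling:
        del store.edges[p]


def update_coordinates(
    store: NCListStore, node_id: int, new_start: int, new_stop: int
) -> int:
    """Move an interval to new coordinates: remove, then reinsert.

    The label is preserved; the returned id is the freshly assigned one.
    Invalid coordinates or an unknown id leave the store unchanged.
    """
    if node_id not in store.nodes:
        raise KeyError(f"no node with id {node_id}")
    old = store.nodes[node_id]
    # validate before mutating (transactional contract)
    replacement = GenomicInterval(old.chrom, new_start, new_stop, store.masterkey[node_id])
    delete(store, node_id)
    return insert(store, replacement)
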