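"""Nested containment list construction and the relational store model.

An NCList organises intervals into *sublists*: every interval points to the
sublist of intervals it completely contains, and no sublist member contains
another member, so each sublist is simultaneously sorted by start and by
stop.  The store keeps the structure as three relational tables —

* **node** (id, chrom, start, stop, sub): every interval and the sublist
  (``sub``) it belongs to; sub 0 is the per-chromosome root.
* **edge** (parent_id, child_sub): links a parent interval to the sublist
  holding its nested children.
* **masterkey** (id, label): numeric id to annotation label.

Construction sorts intervals by (start asc, stop desc) and walks the sorted
list once, tracking the set of still-open intervals; each interval attaches
to a parent chosen among its *minimal* strict containers (containers that do
not themselves contain another container).  With partially overlapping
candidates the choice is configurable: first or last in the sorted order.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .bed_io import GenomicInterval

__all__ = [
    "NodeRecord",
    "EdgeRecord",
    "NCListStore",
    "StoreInvariantError",
    "ParentRule",
    "sort_intervals",
    "contains",
    "build",
    "containment_forest_oracle",
    "validate_store",
]

ParentRule = Literal["first-in-sorted-order", "last-in-sorted-order"]
PARENT_RULES = ("first-in-sorted-order", "last-in-sorted-order")
ROOT_SUB = 0


class StoreInvariantError(AssertionError):
    """A structural invariant of the store does not hold."""


@dataclass(slots=True)
class NodeRecord:
    """An interval as stored: numeric id, coordinates, and its sublist."""

    id: int
    chrom: str
    start: int
    stop: int
    sub: int | None  # None only transiently while a node is being re-placed

    def sort_key(self) -> tuple[int, int, int]:
        # canonical interval order: start asc, stop desc, id asc
        return (self.start, -self.stop, self.id)


@dataclass(frozen=True, slots=True)
class EdgeRecord:
    """Parent interval id -> sublist id of its nested children."""

    parent_id: int
    child_sub: int


def _contains_coords(o_start: int, o_stop: int, i_start: int, i_stop: int) -> bool:
    """Strict containment of [i_start, i_stop) within [o_start, o_stop).

    Coordinate-identical intervals are *not* nested: they are siblings.
    """
    return (
        o_start <= i_start
        and i_stop <= o_stop
        and (o_start, o_stop) != (i_start, i_stop)
    )


def contains(outer: GenomicInterval, inner: GenomicInterval) -> bool:
    """True iff ``inner`` lies strictly within ``outer`` (same chromosome).

    Equal-coordinate intervals are treated as siblings, not as mutually
    nested, so ``contains(x, x)`` is False.
    """
    if outer.chrom != inner.chrom:
        raise ValueError(
            f"cannot compare containment across chromosomes "
            f"({outer.chrom} vs {inner.chrom})"
        )
    return _contains_coords(outer.start, outer.stop, inner.start, inner.stop)


def sort_intervals(
    intervals: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """Canonical construction order.

    Chromosomes lexicographic; within a chromosome start ascending with
    stop *descending* as tie-break (so a containing interval precedes the
    intervals it contains even at equal starts), then label ascending.
    Idempotent and stable.
    """
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, -iv.stop, iv.label))


@dataclass
class NCListStore:
    """In-memory node/edge/masterkey tables with per-sublist sorted order.

    ``sublists`` maps (chrom, sub) to the list of node ids sorted by
    (start, stop, id); because sublist members never nest, this order is
    simultaneously non-decreasing in start and in stop (dual sortedness),
    which is what makes binary search inside a sublist sound.
    """

    nodes: dict[int, NodeRecord] = field(default_factory=dict)
    edges: dict[int, int] = field(default_factory=dict)  # parent_id -> child_sub
    masterkey: dict[int, str] = field(default_factory=dict)
    sublists: dict[tuple[str, int], list[int]] = field(default_factory=dict)
    next_id: int = 1
    next_sub: int = 1
    parent_rule: str = "first-in-sorted-order"

    # -- basic accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def chromosomes(self) -> list[str]:
        return sorted({n.chrom for n in self.nodes.values()})

    def interval_of(self, node_id: int) -> GenomicInterval:
        n = self.nodes[node_id]
        return GenomicInterval(n.chrom, n.start, n.stop, self.masterkey[node_id])

    def intervals(self) -> list[GenomicInterval]:
        """All stored intervals in canonical sorted order."""
        return sort_intervals([self.interval_of(i) for i in self.nodes])

    def sub_parent(self) -> dict[int, int]:
        """Reverse edge map: child_sub -> parent node id."""
        return {s: p for p, s in self.edges.items()}

    def parent_of(self, node_id: int) -> int | None:
        """The parent node id, or None for root-level (sub 0) nodes."""
        sub = self.nodes[node_id].sub
        if sub == ROOT_SUB or sub is None:
            return None
        return self.sub_parent()[sub]

    def parent_map(self) -> dict[int, int | None]:
        rev = self.sub_parent()
        return {
            nid: (rev[n.sub] if n.sub != ROOT_SUB else None)
            for nid, n in self.nodes.items()
        }

    def depth_of(self, node_id: int) -> int:
        """1-based nesting depth (root-level nodes have depth 1)."""
        rev = self.sub_parent()
        depth = 1
        sub = self.nodes[node_id].sub
        while sub != ROOT_SUB:
            depth += 1
            sub = self.nodes[rev[sub]].sub
        return depth

    def max_depth(self) -> int:
        """Maximum nesting depth over all nodes (0 for an empty store)."""
        if not self.nodes:
            return 0
        rev = self.sub_parent()
        depth_of_sub: dict[int, int] = {ROOT_SUB: 1}

        def sub_depth(sub: int) -> int:
            if sub not in depth_of_sub:
                depth_of_sub[sub] = 1 + sub_depth(self.nodes[rev[sub]].sub)
            return depth_of_sub[sub]

        return max(sub_depth(n.sub) for n in self.nodes.values())

    def max_sublist_length(self) -> int:
        return max((len(v) for v in self.sublists.values()), default=0)

    # -- internal mutation helpers (used by build and the update module) --

    def _sublist_sort_key(self, nid: int):
        n = self.nodes[nid]
        return (n.start, n.stop, nid)

    def _attach_to_sublist(self, nid: int, chrom: str, sub: int) -> None:
        lst = self.sublists.setdefault((chrom, sub), [])
        key = self._sublist_sort_key(nid)
        lo, hi = 0, len(lst)
        while lo < hi:
            mid = (lo + hi) // 2
            if self._sublist_sort_key(lst[mid]) < key:
                lo = mid + 1
            else:
                hi = mid
        lst.insert(lo, nid)
        self.nodes[nid].sub = sub

    def _detach_from_sublist(self, nid: int) -> None:
        n = self.nodes[nid]
        key = (n.chrom, n.sub)
        lst = self.sublists[key]
        lst.remove(nid)
        if not lst:
            del self.sublists[key]
        n.sub = None


# ---------------------------------------------------------------------------
# Construction: one pass over the sorted intervals
# ---------------------------------------------------------------------------


def _choose_parent(container_ids: list[int], rule: str) -> int | None:
    """Pick the parent among minimal containers (given in sorted order)."""
    if not container_ids:
        return None
    # container_ids are in canonical sorted order; drop non-minimal ones
    # (containers that strictly contain another container).
    return container_ids[0] if rule == "first-in-sorted-order" else container_ids[-1]


def _minimal_containers(
    store: NCListStore, container_ids: list[int]
) -> list[int]:
    """Containers that do not strictly contain another container.

    Quadratic in the number of containers, which is bounded by the nesting
    depth plus the local partial-overlap multiplicity — small in practice.
    """
    out = []
    for cid in container_ids:
        c = store.nodes[cid]
        if not any(
            oid != cid
            and _contains_coords(
                c.start, c.stop, store.nodes[oid].start, store.nodes[oid].stop
            )
            for oid in container_ids
        ):
            out.append(cid)
    return out


def build(
    intervals: Sequence[GenomicInterval],
    parent_rule: str = "first-in-sorted-order",
) -> NCListStore:
    """Build an NCList store from an interval set in a single sorted pass.

    Ids are assigned 1..n in canonical sorted order; sub values come from a
    monotone counter starting at 1 (0 is the root).  The pass keeps the set
    of still-open intervals (stop beyond the current start); each interval's
    parent is the rule-chosen minimal strict container among them.
    """
    if parent_rule not in PARENT_RULES:
        raise ValueError(f"unknown parent rule: {parent_rule!r}")
    ordered = sort_intervals(intervals)  # validates nothing extra: type enforces

    store = NCListStore(parent_rule=parent_rule)
    nid = 0
    i = 0
    n = len(ordered)
    while i < n:
        chrom = ordered[i].chrom
        j = i
        while j < n and ordered[j].chrom == chrom:
            j += 1
        # open intervals on this chromosome, in processing (= sorted) order
        actives: list[int] = []
        dead: set[int] = set()
        by_stop: list[tuple[int, int]] = []  # (stop, id) min-heap
        for iv in ordered[i:j]:
            nid += 1
            node = NodeRecord(nid, iv.chrom, iv.start, iv.stop, None)
            store.nodes[nid] = node
            store.masterkey[nid] = iv.label
            # retire intervals that end at or before the new start
            while by_stop and by_stop[0][0] <= iv.start:
                dead.add(heapq.heappop(by_stop)[1])
            if len(dead) > len(actives) // 2:
                actives = [a for a in actives if a not in dead]
                dead.clear()
            containers = [
                a
                for a in actives
                if a not in dead
                and _contains_coords(
                    store.nodes[a].start, store.nodes[a].stop, iv.start, iv.stop
                )
            ]
            parent = _choose_parent(
                _minimal_containers(store, containers), parent_rule
            )
            if parent is None:
                sub = ROOT_SUB
            elif parent in store.edges:
                sub = store.edges[parent]
            else:
                sub = store.next_sub
                store.next_sub += 1
                store.edges[parent] = sub
            # processing order is already sublist order, so append
            store.sublists.setdefault((chrom, sub), []).append(nid)
            node.sub = sub
            actives.append(nid)
            heapq.heappush(by_stop, (iv.stop, nid))
        i = j
    store.next_id = nid + 1
    return store


# ---------------------------------------------------------------------------
# Exhaustive O(n^2) oracle — test-only ground truth for the parent relation
# ---------------------------------------------------------------------------


def containment_forest_oracle(
    intervals: Sequence[GenomicInterval],
    parent_rule: str = "first-in-sorted-order",
) -> dict[int, int | None]:
    """Parent assignment by exhaustive pairwise containment checks.

    Ids are assigned 1..n in the same canonical sorted order as ``build``,
    so the returned map {id: parent_id or None} is directly comparable to
    ``build(intervals, rule).parent_map()``.  All-pairs containment is
    evaluated with a vectorised boolean matrix per chromosome; the parent is
    the rule-chosen container among *minimal* containers.  Intended for
    small inputs (<= 10 000 intervals).
    """
    if parent_rule not in PARENT_RULES:
        raise ValueError(f"unknown parent rule: {parent_rule!r}")
    ordered = sort_intervals(intervals)
    if len(ordered) > 10_000:
        raise ValueError("oracle is quadratic; refusing > 10000 intervals")
    parent: dict[int, int | None] = {}
    base = 0
    i = 0
    n = len(ordered)
    while i < n:
        chrom = ordered[i].chrom
        j = i
        while j < n and ordered[j].chrom == chrom:
            j += 1
        group = ordered[i:j]
        m = len(group)
        starts = np.array([iv.start for iv in group])
        stops = np.array([iv.stop for iv in group])
        # C[a, b] true iff interval a strictly contains interval b
        outer_s, inner_s = starts[:, None], starts[None, :]
        outer_e, inner_e = stops[:, None], stops[None, :]
        C = (
            (outer_s <= inner_s)
            & (inner_e <= outer_e)
            & ~((outer_s == inner_s) & (outer_e == inner_e))
        )
        for b in range(m):
            containers = np.flatnonzero(C[:, b])
            # minimal: containers containing no other container of b
            minimal = [
                a for a in containers if not C[a, containers].any()
            ]
            if not minimal:
                parent[base + b + 1] = None
            elif parent_rule == "first-in-sorted-order":
                parent[base + b + 1] = base + int(minimal[0]) + 1
            else:
                parent[base + b + 1] = base + int(minimal[-1]) + 1
        base += m
        i = j
    return parent


# ---------------------------------------------------------------------------
# Store validator
# ---------------------------------------------------------------------------


def validate_store(store: NCListStore) -> None:
    """Check every structural invariant; raise StoreInvariantError if any fails.

    Checks: sublist membership consistency, dual sortedness, absence of
    containment among siblings, edge consistency (one edge per non-root
    sublist, parent strictly contains all members, no orphan sublists),
    masterkey coverage, and counter sanity.
    """
    # node-level sanity and membership
    seen_in_sublists: set[int] = set()
    for (chrom, sub), lst in store.sublists.items():
        if not lst:
            raise StoreInvariantError(f"empty sublist entry ({chrom}, {sub})")
        prev_key = None
        prev_stop = None
        for nid in lst:
            if nid in seen_in_sublists:
                raise StoreInvariantError(f"node {nid} appears in two sublists")
            seen_in_sublists.add(nid)
            node = store.nodes.get(nid)
            if node is None:
                raise StoreInvariantError(f"sublist ({chrom},{sub}) references missing node {nid}")
            if node.chrom != chrom or node.sub != sub:
                raise StoreInvariantError(
                    f"node {nid} tagged ({node.chrom},{node.sub}) but listed in ({chrom},{sub})"
                )
            if node.start >= node.stop:
                raise StoreInvariantError(f"node {nid} has empty interval")
            key = (node.start, node.stop, nid)
            if prev_key is not None and key < prev_key:
                raise StoreInvariantError(
                    f"sublist ({chrom},{sub}) not sorted at node {nid}"
                )
            if prev_stop is not None and node.stop < prev_stop:
                raise StoreInvariantError(
                    f"dual sortedness violated in sublist ({chrom},{sub}) at node {nid}"
                )
            prev_key, prev_stop = key, node.stop
        # sibling containment: with stops non-decreasing the only way one
        # sibling contains another is an equal-stop run with unequal starts
        for a, b in zip(lst, lst[1:]):
            na, nb = store.nodes[a], store.nodes[b]
            if _contains_coords(na.start, na.stop, nb.start, nb.stop) or (
                _contains_coords(nb.start, nb.stop, na.start, na.stop)
            ):
                raise StoreInvariantError(
                    f"siblings {a} and {b} nest within sublist ({chrom},{sub})"
                )
    missing = set(store.nodes) - seen_in_sublists
    if missing:
        raise StoreInvariantError(f"nodes not in any sublist: {sorted(missing)[:5]}")

    # edges
    subs_present = {
        sub for (_c, sub) in store.sublists if sub != ROOT_SUB
    }
    edge_subs = set(store.edges.values())
    if len(edge_subs) != len(store.edges):
        raise StoreInvariantError("two edges point to the same sublist")
    if subs_present - edge_subs:
        raise StoreInvariantError(
            f"sublists without an incoming edge: {sorted(subs_present - edge_subs)[:5]}"
        )
    for parent_id, child_sub in store.edges.items():
        if child_sub == ROOT_SUB:
            raise StoreInvariantError("edge points to the root sublist")
        pnode = store.nodes.get(parent_id)
        if pnode is None:
            raise StoreInvariantError(f"edge from missing parent {parent_id}")
        key = (pnode.chrom, child_sub)
        if key not in store.sublists:
            raise StoreInvariantError(
                f"edge {parent_id}->{child_sub} points to an empty/orphan sublist"
            )
        for cid in store.sublists[key]:
            c = store.nodes[cid]
            if not _contains_coords(pnode.start, pnode.stop, c.start, c.stop):
                raise StoreInvariantError(
                    f"parent {parent_id} does not strictly contain child {cid}"
                )

    # masterkey coverage
    if set(store.masterkey) != set(store.nodes):
        raise StoreInvariantError("masterkey ids do not match node ids")

    # counters
    if store.nodes and store.next_id <= max(store.nodes):
        raise StoreInvariantError("next_id not beyond max node id")
    all_subs = {n.sub for n in store.nodes.values()} - {ROOT_SUB}
    if all_subs and store.next_sub <= max(all_subs):
        raise StoreInvariantError("next_sub not beyond max sub value")
    if store.parent_rule not in PARENT_RULES:
        raise StoreInvariantError(f"unknown parent rule {store.parent_rule!r}")
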