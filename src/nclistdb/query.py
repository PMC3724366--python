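"""Overlap queries against an NCList store and batch position annotation.

Overlap is half-open versus half-open with strict inequalities: interval
``[s, e)`` overlaps query ``[qs, qe)`` iff ``s < qe and e > qs``.  A point
query at ``pos`` is the width-1 range ``[pos, pos+1)``, so a point equal to
an interval's (exclusive) stop coordinate does **not** hit it — biologists
used to 1-based inclusive coordinates should shift their positions down by
one (the CLI offers ``--one-based`` for this).

The search descends the sublist hierarchy: within each sublist the stop
values are sorted, so a binary search finds the first member still open at
``qs``; the scan then walks forward while members start before ``qe``,
emitting hits and recursing into each hit's child sublist.  The work per
sublist is O(log(sublist length) + hits in sublist), giving the
characteristic O(M log N) behaviour for a tree of depth M over N intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .bed_io import GenomicInterval, GenomicPosition
from .core import NCListStore, ROOT_SUB

__all__ = [
    "QueryHit",
    "OpCounter",
    "query_range",
    "query_point",
    "annotate_positions",
    "brute_force_overlap",
    "NULL_LABEL",
]

NULL_LABEL = "."  # BED-style marker for "no overlapping feature"

ANNOTATION_COLUMNS = ["chrom", "pos", "label", "feature_start", "feature_stop", "feature_id"]


@dataclass(frozen=True, slots=True)
class QueryHit:
    """An interval returned by an overlap query."""

    id: int
    chrom: str
    start: int
    stop: int
    label: str


@dataclass(slots=True)
class OpCounter:
    """Work done by a query, for scaling analysis.

    ``nodes_examined`` counts every node whose coordinates were compared —
    binary-search probes plus the linear scan (including the member that
    terminates each scan).  ``sublists_entered`` counts sublists searched.
    """

    nodes_examined: int = 0
    sublists_entered: int = 0


def _search_sublist(
    store: NCListStore,
    chrom: str,
    sub: int,
    q_start: int,
    q_stop: int,
    hits: list[QueryHit],
    counter: OpCounter,
) -> None:
    lst = store.sublists.get((chrom, sub))
    if lst is None:
        return
    counter.sublists_entered += 1
    nodes = store.nodes
    # binary search on the (sorted) stop values: first member with stop > q_start
    lo, hi = 0, len(lst)
    while lo < hi:
        mid = (lo + hi) // 2
        counter.nodes_examined += 1
        if nodes[lst[mid]].stop <= q_start:
            lo = mid + 1
        else:
            hi = mid
    i = lo
    while i < len(lst):
        node = nodes[lst[i]]
        counter.nodes_examined += 1
        if node.start >= q_stop:
            break
        hits.append(
            QueryHit(node.id, node.chrom, node.start, node.stop, store.masterkey[node.id])
        )
        child = store.edges.get(node.id)
        if child is not None:
            _search_sublist(store, chrom, child, q_start, q_stop, hits, counter)
        i += 1


def query_range(
    store: NCListStore,
    chrom: str,
    q_start: int,
    q_stop: int,
    with_counter: bool = False,
):
    """All stored intervals on ``chrom`` overlapping ``[q_start, q_stop)``.

    Hits are ordered by (start asc, stop desc, id asc) for reproducible
    output.  An unknown chromosome yields an empty result, not an error;
    a zero- or negative-width query is an error.

    Returns the hit list, or ``(hits, OpCounter)`` if ``with_counter``.
    """
    if q_start >= q_stop:
        raise ValueError(f"empty query range [{q_start}, {q_stop})")
    hits: list[QueryHit] = []
    counter = OpCounter()
    _search_sublist(store, chrom, ROOT_SUB, q_start, q_stop, hits, counter)
    hits.sort(key=lambda h: (h.start, -h.stop, h.id))
    if with_counter:
        return hits, counter
    return hits


def query_point(
    store: NCListStore, chrom: str, pos: int, with_counter: bool = False
):
    """All intervals covering the single base at ``pos`` (width-1 range)."""
    if pos < 0:
        raise ValueError(f"negative position: {pos}")
    return query_range(store, chrom, pos, pos + 1, with_counter=with_counter)


def annotate_positions(
    store: NCListStore, positions: Sequence[GenomicPosition]
) -> pd.DataFrame:
    """Join each position against the store: one row per (position, hit).

    Positions with no overlapping feature emit a single row with the
    null-label marker ``"."`` and missing feature fields.  Row order is
    input position order, then hit order; duplicated input positions are
    annotated independently.
    """
    rows: list[tuple] = []
    for p in positions:
        hits = query_point(store, p.chrom, p.pos)
        if not hits:
            rows.append((p.chrom, p.pos, NULL_LABEL, pd.NA, pd.NA, pd.NA))
        else:
            for h in hits:
                rows.append((p.chrom, p.pos, h.label, h.start, h.stop, h.id))
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    for col in ("feature_start", "feature_stop", "feature_id"):
        df[col] = df[col].astype("Int64")
    return df


def write_annotation_tsv(df: pd.DataFrame, path) -> None:
    """Write an annotation table as TSV with '.' for missing fields."""
    df.to_csv(path, sep="\t", index=False, na_rep=NULL_LABEL)


def brute_force_overlap(
    intervals: Sequence[GenomicInterval],
    chrom: str,
    q_start: int,
    q_stop: int,
) -> list[GenomicInterval]:
    """Linear scan of every interval — the ground-truth overlap oracle.

    Same overlap semantics as :func:`query_range`; preserves input order.
    """
    return [
        iv
        for iv in intervals
        if iv.chrom == chrom and iv.start < q_stop and iv.stop > q_start
    ]
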