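"""Shared fixtures and oracle helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from nclistdb import GenomicInterval, query_point
from nclistdb.core import NCListStore


def probe_points(intervals) -> list[tuple[str, int]]:
    """An exhaustive probe grid: every interval endpoint +/- 1 per chrom.

    Covers every distinct overlap configuration the interval set admits,
    including the half-open boundary positions.
    """
    by_chrom: dict[str, set[int]] = {}
    for iv in intervals:
        pts = by_chrom.setdefault(iv.chrom, set())
        pts.update((iv.start - 1, iv.start, iv.stop - 1, iv.stop))
    return [
        (chrom, p)
        for chrom, pts in sorted(by_chrom.items())
        for p in sorted(pts)
        if p >= 0
    ]


def brute_force_point_hits(intervals, probes):
    """Vectorised ground-truth join: per probe, the sorted hit multiset."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    arrays = {
        c: (
            np.array([iv.start for iv in ivs]),
            np.array([iv.stop for iv in ivs]),
            ivs,
        )
        for c, ivs in by_chrom.items()
    }
    result = []
    for chrom, pos in probes:
        if chrom not in arrays:
            result.append([])
            continue
        starts, stops, ivs = arrays[chrom]
        idx = np.flatnonzero((starts <= pos) & (stops > pos))
        result.append(
            sorted((ivs[i].chrom, ivs[i].start, ivs[i].stop, ivs[i].label) for i in idx)
        )
    return result


def store_point_hits(store: NCListStore, probes):
    """The store's answer on the same probe grid, same normal form."""
    return [
        sorted((h.chrom, h.start, h.stop, h.label) for h in query_point(store, c, p))
        for c, p in probes
    ]


def assert_query_equivalent(store: NCListStore, intervals) -> None:
    """The store must answer every probe exactly like the brute-force scan."""
    probes = probe_points(intervals)
    assert store_point_hits(store, probes) == brute_force_point_hits(intervals, probes)


@pytest.fixture
def tiny_nested():
    """A three-level nested chain plus a disjoint neighbour."""
    return [
        GenomicInterval("chr1", 0, 100, "outer"),
        GenomicInterval("chr1", 10, 20, "middle"),
        GenomicInterval("chr1", 12, 15, "inner"),
        GenomicInterval("chr1", 200, 300, "apart"),
    ]
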