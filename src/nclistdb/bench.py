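"""Scaling benchmark: NCList vs naive scan vs start-sorted index.

Three strategies answer the same batch of point queries:

* ``nclist`` — this library's sublist search;
* ``naive-scan`` — a full table scan per query (every interval examined);
* ``start-sorted`` — intervals sorted by start; a binary search finds the
  last interval starting at or before the query, then *every* earlier
  interval must still be scanned and its stop tested, because nesting
  destroys any ordering guarantee on stops.  This is exactly the failure
  mode that motivates the NCList: the index prunes nothing on the stop
  side.

The primary metric is ``nodes_examined`` (coordinate comparisons), which
is hardware-independent; wall time is recorded but is not a test
quantity.  Hit multisets must be identical across strategies before any
numbers are reported — correctness gates the timing.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bed_io import GenomicInterval, GenomicPosition, read_bed
from .core import NCListStore, build
from .query import OpCounter, query_point

__all__ = ["STRATEGIES", "BenchResult", "run_benchmark", "run_strategy"]

STRATEGIES = ("nclist", "naive-scan", "start-sorted")

BENCH_COLUMNS = ["strategy", "db_size", "n_queries", "wall_s", "nodes_examined", "hits"]


@dataclass(frozen=True, slots=True)
class BenchResult:
    strategy: str
    db_size: int
    n_queries: int
    wall_s: float
    nodes_examined: int
    hits: int


def _hit_key(chrom: str, start: int, stop: int, label: str) -> tuple:
    return (chrom, start, stop, label)


class _ChromArrays:
    """Per-chromosome coordinate arrays shared by the array strategies."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self.n_total = len(intervals)
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list]] = {}
        grouped: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            grouped.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in grouped.items():
            order = sorted(range(len(ivs)), key=lambda i: (ivs[i].start, ivs[i].stop))
            starts = np.array([ivs[i].start for i in order], dtype=np.int64)
            stops = np.array([ivs[i].stop for i in order], dtype=np.int64)
            meta = [ivs[i] for i in order]
            self.by_chrom[chrom] = (starts, stops, meta)


def _run_naive(arrays: _ChromArrays, positions, hits_out) -> tuple[int, int]:
    examined = 0
    total_hits = 0
    for p in positions:
        examined += arrays.n_total  # a table scan touches every row
        entry = arrays.by_chrom.get(p.chrom)
        hits = []
        if entry is not None:
            starts, stops, meta = entry
            idx = np.flatnonzero((starts <= p.pos) & (stops > p.pos))
            hits = [meta[i] for i in idx]
        total_hits += len(hits)
        hits_out.append(sorted(_hit_key(h.chrom, h.start, h.stop, h.label) for h in hits))
    return examined, total_hits


def _run_start_sorted(arrays: _ChromArrays, positions, hits_out) -> tuple[int, int]:
    examined = 0
    total_hits = 0
    for p in positions:
        entry = arrays.by_chrom.get(p.chrom)
        hits = []
        if entry is not None:
            starts, stops, meta = entry
            # all intervals starting at or before pos are candidates; with
            # nesting none of them can be pruned by stop order
            k = int(np.searchsorted(starts, p.pos, side="right"))
            examined += k
            idx = np.flatnonzero(stops[:k] > p.pos)
            hits = [meta[i] for i in idx]
        total_hits += len(hits)
        hits_out.append(sorted(_hit_key(h.chrom, h.start, h.stop, h.label) for h in hits))
    return examined, total_hits


def _run_nclist(store: NCListStore, positions, hits_out) -> tuple[int, int]:
    examined = 0
    total_hits = 0
    for p in positions:
        hits, counter = query_point(store, p.chrom, p.pos, with_counter=True)
        examined += counter.nodes_examined
        total_hits += len(hits)
        hits_out.append(sorted(_hit_key(h.chrom, h.start, h.stop, h.label) for h in hits))
    return examined, total_hits


def run_strategy(
    strategy: str,
    intervals: Sequence[GenomicInterval],
    positions: Sequence[GenomicPosition],
    store: NCListStore | None = None,
    arrays: _ChromArrays | None = None,
):
    """Run one strategy; returns (BenchResult, per-query hit multisets).

    Index construction (store build / array sort) is excluded from the
    reported wall time, matching a pre-built database being queried.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy: {strategy!r}")
    hits_out: list[list[tuple]] = []
    if strategy == "nclist":
        if store is None:
            store = build(intervals)
        t0 = time.perf_counter()
        examined, total_hits = _run_nclist(store, positions, hits_out)
        wall = time.perf_counter() - t0
    else:
        if arrays is None:
            arrays = _ChromArrays(intervals)
        t0 = time.perf_counter()
        if strategy == "naive-scan":
            examined, total_hits = _run_naive(arrays, positions, hits_out)
        else:
            examined, total_hits = _run_start_sorted(arrays, positions, hits_out)
        wall = time.perf_counter() - t0
    result = BenchResult(
        strategy, len(intervals), len(positions), wall, examined, total_hits
    )
    return result, hits_out


def run_benchmark(
    interval_db,
    position_sets: Sequence[Sequence[GenomicPosition]],
    strategies: Sequence[str] = STRATEGIES,
) -> pd.DataFrame:
    """Benchmark the strategies over one interval database.

    ``interval_db`` is a BED path or an interval sequence; each entry of
    ``position_sets`` is a batch of point queries.  Raises if any two
    strategies disagree on any query's hit multiset.
    """
    if isinstance(interval_db, (str, bytes)) or hasattr(interval_db, "__fspath__"):
        intervals = read_bed(interval_db)
    else:
        intervals = list(interval_db)
    for s in strategies:
        if s not in STRATEGIES:
            raise ValueError(f"unknown strategy: {s!r}")

    store = build(intervals) if "nclist" in strategies else None
    arrays = (
        _ChromArrays(intervals)
        if any(s != "nclist" for s in strategies)
        else None
    )
    rows = []
    for positions in position_sets:
        reference: list[list[tuple]] | None = None
        ref_strategy = None
        for s in strategies:
            result, hits = run_strategy(s, intervals, positions, store=store, arrays=arrays)
            if reference is None:
                reference, ref_strategy = hits, s
            elif hits != reference:
                raise AssertionError(
                    f"strategy {s!r} disagrees with {ref_strategy!r} on hit multisets"
                )
            rows.append(result)
    return pd.DataFrame(
        [
            (r.strategy, r.db_size, r.n_queries, r.wall_s, r.nodes_examined, r.hits)
            for r in rows
        ],
        columns=BENCH_COLUMNS,
    )


def plot_benchmark(df: pd.DataFrame, path) -> None:
    """Log-log plot of nodes examined vs database size, one line per strategy."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for strategy, g in df.groupby("strategy"):
        g = g.sort_values("db_size")
        ax.plot(g["db_size"], g["nodes_examined"], marker="o", label=strategy)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("database size (intervals)")
    ax.set_ylabel("total nodes examined")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
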