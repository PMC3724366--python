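# Methods

## The structure

An NCList over a set of half-open intervals is a forest per chromosome:
every interval belongs to exactly one *sublist*, identified by an integer
`sub` value, and an interval with nested children carries an edge to the
sublist holding them. `sub 0` is the per-chromosome root (intervals
contained by no other). Because no sublist member strictly contains
another, ordering a sublist by start also orders it by stop ("dual
sortedness"), which is what makes binary search within a sublist sound.

Containment is **strict**: `outer` contains `inner` iff
`outer.start ≤ inner.start`, `inner.stop ≤ outer.stop`, and the coordinate
pairs differ. Coordinate-identical intervals are therefore siblings in the
same sublist, never mutually nested — mutual containment would make the
parent choice arbitrary and break the tree, while siblings preserve dual
sortedness (identity is the numeric node id, not the coordinates or the
label, so duplicates are fully supported).

All coordinates are BED-convention 0-based half-open `[start, stop)`, and
overlap is strict on both sides (`start < q_stop and stop > q_start`).
A point query is the width-1 range `[pos, pos+1)`; consequently a point
equal to a stored stop coordinate does not hit — users with 1-based
inclusive positions should pass `--one-based`, which shifts inputs down by
one.

## Construction

Intervals are sorted per chromosome by (start ascending, stop
*descending*, label ascending). The stop-descending tie-break is essential:
at equal starts it places a containing interval before the intervals it
contains, so a single forward pass sees every parent before its children.
The pass maintains the set of *open* intervals (stop beyond the current
start, retired lazily via a min-heap on stop). For each interval the
candidate parents are the open intervals that strictly contain it; among
the **minimal** candidates (those containing no other candidate) the parent
is chosen by a configurable rule — `first-in-sorted-order` (default) or
`last-in-sorted-order`. With pure nesting the minimal container is unique
(the innermost enclosing interval) and the rule is irrelevant; it matters
only when partially overlapping intervals both contain the newcomer.

Node ids are assigned 1..n in sorted order; sub values come from a
monotone counter starting at 1 and are never recycled, which avoids
aliasing after long edit histories. The same minimal-container-plus-rule
definition is implemented independently as an exhaustive O(n²) oracle
(vectorised all-pairs containment matrix) used only in tests.

## Queries

`query_range` descends from the root sublist: binary search on the sorted
stops finds the first member still open at `q_start`; a forward scan emits
members starting before `q_stop` and recurses into each hit's child
sublist. Per sublist the work is O(log length + hits), so a query costs
O(hits + M log N) for nesting depth M. The `OpCounter` instrumentation
counts every node whose coordinates are compared — binary-search probes
plus the scan including its terminating member — and the number of
sublists entered; operation counts, not wall-clock, are the scaling
metric throughout, because timings are hardware-bound while comparison
counts are not.

Hits are ordered (start asc, stop desc, id asc) so output is
byte-reproducible. Querying an unknown chromosome returns an empty result
rather than an error: annotation workloads routinely probe contigs absent
from a track. The annotation join emits one row per (position, hit), with
a single `.`-labelled row for uncovered positions.

## In-place edits

Insertion first selects the parent exactly as construction would — the
rule-chosen minimal strict container among **all** stored intervals — then
resolves what the new interval captures in the target sublist:

* nothing captured → append to the parent's existing sublist, or to a
  fresh sublist with a new edge when the parent was childless (at the
  root: simply append to sub 0);
* members captured → the new node joins the target sublist in their
  place, the captured members move beneath it. When the captured members
  are a *proper subset* of the sublist, only the strictly contained
  members move — the untouched members remain siblings of the new node.
  Captured members are re-placed recursively, which handles the corner
  where a captured member must itself descend beneath an existing child
  of the new node.

Deletion removes the node and promotes its children into its former
sublist — to sub 0 when a base interval is deleted, otherwise to the
deleted node's own sub value — dropping the edge; a sublist emptied by the
deletion loses the edge that pointed to it. One configuration needs
repair: a promoted child may be strictly contained by a *partially
overlapping* member of the receiving sublist (possible because the child's
original parent overlapped that member without containment). Leaving it
there would break the no-nesting-among-siblings rule, so such children are
re-attached beneath their container by the same global placement logic.
This repair is an inference required for query correctness; the promotion
rule alone does not address it.

Coordinate update is deletion followed by reinsertion under a fresh id
with the label preserved. All edits validate their arguments before any
mutation, so a raised error leaves the store untouched.

The ground truth for all of this is the *rebuild oracle*: after any edit
sequence the store must be query-equivalent — identical hit multisets on
an exhaustive probe grid of every interval endpoint ±1 — to a store built
from scratch on the surviving intervals. Tree shapes may legitimately
differ between incremental and batch histories when partial overlap makes
the parent choice path-dependent; query behaviour may not.

## Persistence

The default backend is a single SQLite file holding the three tables plus
a manifest (format version, row counts, chromosome list, parent rule,
id/sub counters, SHA-256 over the sorted row dumps). Two composite indices
are declared on the node table — (sub, start, stop) and (start, stop) —
and the edge table carries a composite (parent_id, child_sub) index plus a
single-column index on child_sub; the edge indexing is declared as one
composite plus one single because the requirement "indexed by interval id
and the sub values" is ambiguous between the two readings, and this covers
both access paths. Indices are a performance device, not logical state; the
plain-TSV export mode rebuilds sublist order on load instead.

Loading verifies counts, checksum and format version, then runs the full
structural validator before returning the store. On-disk edits run against
an in-memory image first; only on success are the changed rows written
back in one transaction (diff-based, no full rewrite), so any failure
leaves the file byte-identical. Checksums make silent row tampering a
load-time error.

## Synthetic data

The generator emulates an exon-like annotation track: base intervals
uniform over a 10-chromosome genome with exponential lengths (mean
1000 bp), each interval spawning one or two disjoint, strictly contained
children with probability 0.3 up to depth 3, and 10% of adjacent siblings
shifted into partial overlap. Defaults keep coverage near 1×, i.e. a
random position hits a handful of features at most — the sparse, mildly
nested regime of real pooled-exon databases. Base lengths are floored at
2^depth so a full-depth lineage always fits; a genome too short for that
floor is rejected as infeasible. Positions are uniform over the genome,
emulating variant sites. Everything is deterministic per seed.

A second, deliberately dense generator produces small sets in named
overlap regimes — disjoint, nested chains, partial-overlap staircases,
exact duplicates, and a mixture — so randomized tests constantly exercise
the configurations where interval indexing goes wrong.

What the generators do *not* emulate: chromosome length heterogeneity,
clustering of features along the genome, realistic exon length and
spacing distributions, or strand. Passing tests therefore demonstrate
algorithmic correctness and scaling shape on controlled structure, not
biological realism of any particular track.

## Benchmark and scaling

Three strategies answer identical point-query batches: the NCList search;
a naive scan examining every row per query; and a start-sorted index that
binary-searches the last interval starting at or before the query but must
then test every earlier interval's stop, because nesting removes any
ordering guarantee on stops — the precise failure the structure exists to
fix. Hit multisets must agree exactly across strategies before any numbers
are reported.

The scaling experiment uses databases of 10³/10⁴/10⁵ intervals with the
genome scaled proportionally (constant feature density, as when a growing
annotation set covers more of the genome) and 10³ fixed queries. Under
these conditions naive-scan work grows exactly 10× per decade by
construction, while NCList work — hits plus logarithmic search overhead —
grows by well under 3× per decade (measured ≈1.45×). Each individual query
is also checked against the operational work bound
`nodes_examined ≤ hits + depth × (⌈log₂(max sublist length)⌉ + 2)`.
These sizes keep the full campaign in seconds on one CPU while spanning
two decades, enough to separate logarithmic from linear growth cleanly.

## Known limitations

* Construction and edits hold the full interval set in memory; streaming
  construction is out of scope.
* Parent selection during an edit scans the stored intervals of the
  affected chromosome (O(n) per edit rather than O(log n)); edit
  throughput therefore degrades linearly with store size, though queries
  do not.
* The worst case for construction — very many mutually overlapping
  intervals at one locus — degrades the open-set scan toward O(n²).
* Single writer; no concurrent edit support.
* No stranded overlap, nearest-feature queries, or reciprocal-overlap
  fractions.
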