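"""Persistence of the node/edge/masterkey tables.

The default backend is a single-file embedded SQL store (stdlib
``sqlite3``), mirroring the relational table design: ``node(id, chrom,
start, stop, sub)``, ``edge(parent_id, child_sub)``, ``masterkey(id,
label)`` plus a ``manifest`` of key/value metadata.  Two composite indices
are declared on the node table — (sub, start, stop) and (start, stop) —
and the edge table carries a composite (parent_id, child_sub) index plus a
single-column index on child_sub.  The indices are a performance device;
logical state is the three tables plus the manifest counters.

A ``plain`` mode writes the same tables as a directory of TSVs for
inspection; sublist order and indices are rebuilt on load.

The manifest records a format version, row counts, the chromosome list,
the parent rule, the id/sub counters and a checksum over the sorted table
rows; all of these are verified on load, and the reloaded store must pass
the full structural validator before it is returned.

On-disk edits (`apply_edit`) are transactional: the edit is first applied
to an in-memory copy of the store; only if it succeeds are the changed
rows written back in a single transaction.  A failed edit therefore leaves
the file byte-identical.
"""

from __future__ import annotations

import hashlib
import os
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

from .bed_io import GenomicInterval
from .core import NCListStore, NodeRecord, validate_store, StoreInvariantError
from . import update as _update

__all__ = [
    "FORMAT_VERSION",
    "StoreIOError",
    "EditRequest",
    "EditReceipt",
    "save",
    "load",
    "apply_edit",
]

FORMAT_VERSION = 1


class StoreIOError(RuntimeError):
    """A persisted store is missing, corrupt, or from another version."""


# ---------------------------------------------------------------------------
# canonical row dumps and checksum
# ---------------------------------------------------------------------------


def _node_rows(store: NCListStore) -> list[tuple[int, str, int, int, int]]:
    return sorted(
        (n.id, n.chrom, n.start, n.stop, n.sub) for n in store.nodes.values()
    )


def _edge_rows(store: NCListStore) -> list[tuple[int, int]]:
    return sorted(store.edges.items())


def _masterkey_rows(store: NCListStore) -> list[tuple[int, str]]:
    return sorted(store.masterkey.items())


def checksum(store: NCListStore) -> str:
    """SHA-256 over the sorted row dumps of all three tables."""
    h = hashlib.sha256()
    for row in _node_rows(store):
        h.update(("N|" + "|".join(map(str, row)) + "\n").encode())
    for row in _edge_rows(store):
        h.update(("E|" + "|".join(map(str, row)) + "\n").encode())
    for row in _masterkey_rows(store):
        h.update(("M|" + "|".join(map(str, row)) + "\n").encode())
    return h.hexdigest()


def _manifest(store: NCListStore) -> dict[str, str]:
    return {
        "format_version": str(FORMAT_VERSION),
        "interval_count": str(len(store.nodes)),
        "edge_count": str(len(store.edges)),
        "chromosomes": ",".join(store.chromosomes()),
        "parent_rule": store.parent_rule,
        "next_id": str(store.next_id),
        "next_sub": str(store.next_sub),
        "checksum": checksum(store),
    }


# ---------------------------------------------------------------------------
# save / load — sqlite and plain-TSV
# ---------------------------------------------------------------------------

_SCHEMA = """
CREATE TABLE node (
    id INTEGER PRIMARY KEY,
    chrom TEXT NOT NULL,
    start INTEGER NOT NULL,
    stop INTEGER NOT NULL,
    sub INTEGER NOT NULL
);
CREATE TABLE edge (
    parent_id INTEGER PRIMARY KEY,
    child_sub INTEGER NOT NULL
);
CREATE TABLE masterkey (
    id INTEGER PRIMARY KEY,
    label TEXT NOT NULL
);
CREATE TABLE manifest (k TEXT PRIMARY KEY, v TEXT NOT NULL);
CREATE INDEX idx_node_sub_pos ON node (sub, start, stop);
CREATE INDEX idx_node_pos ON node (start, stop);
CREATE INDEX idx_edge_parent_sub ON edge (parent_id, child_sub);
CREATE INDEX idx_edge_sub ON edge (child_sub);
"""


def save(store: NCListStore, path: str | os.PathLike, plain: bool = False) -> None:
    """Persist a store to ``path`` (sqlite file, or TSV directory if plain).

    Writes to a temporary location and renames into place, so a failed
    save leaves no partial store behind.
    """
    path = Path(path)
    if plain:
        _save_plain(store, path)
        return
    tmp = path.with_name(path.name + ".tmp")
    if tmp.exists():
        tmp.unlink()
    try:
        con = sqlite3.connect(tmp)
        with con:
            con.executescript(_SCHEMA)
            con.executemany("INSERT INTO node VALUES (?,?,?,?,?)", _node_rows(store))
            con.executemany("INSERT INTO edge VALUES (?,?)", _edge_rows(store))
            con.executemany(
                "INSERT INTO masterkey VALUES (?,?)", _masterkey_rows(store)
            )
            con.executemany(
                "INSERT INTO manifest VALUES (?,?)", sorted(_manifest(store).items())
            )
        con.close()
        os.replace(tmp, path)
    finally:
        if tmp.exists():
            tmp.unlink()


def _save_plain(store: NCListStore, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    for name, rows in (
        ("node.tsv", _node_rows(store)),
        ("edge.tsv", _edge_rows(store)),
        ("masterkey.tsv", _masterkey_rows(store)),
        ("manifest.tsv", sorted(_manifest(store).items())),
    ):
        tmp = path / (name + ".tmp")
        with open(tmp, "wt", encoding="utf-8") as fh:
            for row in rows:
                fh.write("\t".join(map(str, row)) + "\n")
        os.replace(tmp, path / name)


def _assemble(
    node_rows, edge_rows, mk_rows, manifest: dict[str, str]
) -> NCListStore:
    try:
        version = int(manifest["format_version"])
    except KeyError:
        raise StoreIOError("corrupt store: manifest lacks format_version")
    if version != FORMAT_VERSION:
        raise StoreIOError(
            f"store format version {version} unsupported (expected {FORMAT_VERSION})"
        )
    store = NCListStore(
        parent_rule=manifest.get("parent_rule", "first-in-sorted-order"),
        next_id=int(manifest.get("next_id", 1)),
        next_sub=int(manifest.get("next_sub", 1)),
    )
    for nid, chrom, start, stop, sub in node_rows:
        store.nodes[nid] = NodeRecord(nid, chrom, start, stop, sub)
    for parent_id, child_sub in edge_rows:
        store.edges[parent_id] = child_sub
    for nid, label in mk_rows:
        store.masterkey[nid] = label
    # rebuild per-sublist sorted order from the node table
    for nid in sorted(
        store.nodes, key=lambda i: (store.nodes[i].start, store.nodes[i].stop, i)
    ):
        n = store.nodes[nid]
        store.sublists.setdefault((n.chrom, n.sub), []).append(nid)

    if int(manifest.get("interval_count", -1)) != len(store.nodes):
        raise StoreIOError(
            "corrupt store: manifest interval_count does not match node rows"
        )
    if int(manifest.get("edge_count", -1)) != len(store.edges):
        raise StoreIOError("corrupt store: manifest edge_count does not match edge rows")
    if manifest.get("checksum") != checksum(store):
        raise StoreIOError("corrupt store: table checksum mismatch")
    try:
        validate_store(store)
    except StoreInvariantError as exc:
        raise StoreIOError(f"corrupt store: {exc}") from exc
    return store


def load(path: str | os.PathLike) -> NCListStore:
    """Reload a persisted store; verifies manifest, checksum and invariants."""
    path = Path(path)
    if path.is_dir():
        return _load_plain(path)
    if not path.exists():
        raise StoreIOError(f"no store at {path}")
    try:
        con = sqlite3.connect(f"file:{path}?mode=ro", uri=True)
        try:
            node_rows = con.execute(
                "SELECT id, chrom, start, stop, sub FROM node"
            ).fetchall()
            edge_rows = con.execute(
                "SELECT parent_id, child_sub FROM edge"
            ).fetchall()
            mk_rows = con.execute("SELECT id, label FROM masterkey").fetchall()
            manifest = dict(con.execute("SELECT k, v FROM manifest").fetchall())
        finally:
            con.close()
    except sqlite3.Error as exc:
        raise StoreIOError(f"corrupt store at {path}: {exc}") from exc
    return _assemble(node_rows, edge_rows, mk_rows, manifest)


def _load_plain(path: Path) -> NCListStore:
    def read_tsv(name: str) -> list[list[str]]:
        f = path / name
        if not f.exists():
            raise StoreIOError(f"corrupt store: missing table file {name}")
        with open(f, "rt", encoding="utf-8") as fh:
            return [line.rstrip("\n").split("\t") for line in fh if line.strip()]

    try:
        node_rows = [
            (int(r[0]), r[1], int(r[2]), int(r[3]), int(r[4]))
            for r in read_tsv("node.tsv")
        ]
        edge_rows = [(int(r[0]), int(r[1])) for r in read_tsv("edge.tsv")]
        mk_rows = [(int(r[0]), r[1]) for r in read_tsv("masterkey.tsv")]
        manifest = {r[0]: r[1] for r in read_tsv("manifest.tsv")}
    except (IndexError, ValueError) as exc:
        raise StoreIOError(f"corrupt store: malformed table row ({exc})") from exc
    return _assemble(node_rows, edge_rows, mk_rows, manifest)


# ---------------------------------------------------------------------------
# in-place on-disk edits
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class EditRequest:
    """One edit against a persisted store.

    kind "insert" uses ``interval``; "delete" uses ``node_id``; "update"
    uses ``node_id`` plus ``new_start``/``new_stop``.
    """

    kind: Literal["insert", "delete", "update"]
    interval: GenomicInterval | None = None
    node_id: int | None = None
    new_start: int | None = None
    new_stop: int | None = None


@dataclass(frozen=True, slots=True)
class EditReceipt:
    """What an edit touched: node ids and sublist values affected."""

    kind: str
    node_ids: tuple[int, ...]
    subs: tuple[int, ...]


def apply_edit(path: str | os.PathLike, edit: EditRequest) -> EditReceipt:
    """Apply one edit to a persisted store without a full rewrite.

    The edit runs against an in-memory image first; only on success are the
    changed rows written back (single transaction for the sqlite backend,
    atomic file replacement for plain TSV).  Any failure leaves the
    persisted store byte-identical.
    """
    path = Path(path)
    store = load(path)
    before_nodes = {r[0]: r for r in _node_rows(store)}
    before_edges = dict(store.edges)
    before_mk = dict(store.masterkey)

    if edit.kind == "insert":
        if edit.interval is None:
            raise ValueError("insert edit requires an interval")
        _update.insert(store, edit.interval)
    elif edit.kind == "delete":
        if edit.node_id is None:
            raise ValueError("delete edit requires a node id")
        _update.delete(store, edit.node_id)
    elif edit.kind == "update":
        if edit.node_id is None or edit.new_start is None or edit.new_stop is None:
            raise ValueError("update edit requires node id and new coordinates")
        _update.update_coordinates(store, edit.node_id, edit.new_start, edit.new_stop)
    else:
        raise ValueError(f"unknown edit kind: {edit.kind!r}")
    validate_store(store)

    after_nodes = {r[0]: r for r in _node_rows(store)}
    node_del = [i for i in before_nodes if i not in after_nodes]
    node_upsert = [
        after_nodes[i]
        for i in after_nodes
        if before_nodes.get(i) != after_nodes[i]
    ]
    edge_del = [p for p in before_edges if p not in store.edges]
    edge_upsert = [
        (p, s) for p, s in store.edges.items() if before_edges.get(p) != s
    ]
    mk_del = [i for i in before_mk if i not in store.masterkey]
    mk_upsert = [
        (i, l) for i, l in store.masterkey.items() if before_mk.get(i) != l
    ]

    if path.is_dir():
        _save_plain(store, path)
    else:
        con = sqlite3.connect(path)
        try:
            with con:
                con.executemany("DELETE FROM node WHERE id = ?", [(i,) for i in node_del])
                con.executemany(
                    "INSERT OR REPLACE INTO node VALUES (?,?,?,?,?)", node_upsert
                )
                con.executemany(
                    "DELETE FROM edge WHERE parent_id = ?", [(p,) for p in edge_del]
                )
                con.executemany("INSERT OR REPLACE INTO edge VALUES (?,?)", edge_upsert)
                con.executemany(
                    "DELETE FROM masterkey WHERE id = ?", [(i,) for i in mk_del]
                )
                con.executemany(
                    "INSERT OR REPLACE INTO masterkey VALUES (?,?)", mk_upsert
                )
                con.executemany(
                    "INSERT OR REPLACE INTO manifest VALUES (?,?)",
                    sorted(_manifest(store).items()),
                )
        finally:
            con.close()

    touched_nodes = sorted(
        set(node_del)
        | {r[0] for r in node_upsert}
        | set(mk_del)
        | {i for i, _ in mk_upsert}
    )
    touched_subs = sorted(
        {r[4] for r in node_upsert}
        | {before_nodes[i][4] for i in node_del}
        | set(edge_del and [before_edges[p] for p in edge_del] or [])
        | {s for _, s in edge_upsert}
    )
    return EditReceipt(edit.kind, tuple(touched_nodes), tuple(touched_subs))
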