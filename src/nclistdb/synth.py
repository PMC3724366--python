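"""Synthetic interval databases and uniform random genomic positions.

The interval generator emulates an exon-like annotation track: base
intervals scattered uniformly over a multi-chromosome genome, each
recursively spawning strictly contained children (nesting, as in
overlapping transcript/exon structures) with a controllable probability
and depth, plus a controllable fraction of partially overlapping
neighbours.  Positions emulate variant sites drawn uniformly across the
genome.  Both are fully deterministic per (config, seed).

Defaults: 10 chromosomes over a 10^8 bp genome, mean interval length
1000 bp, child probability 0.3, max depth 3, partial-overlap fraction
0.1 — a desk-scale track that is sparse (coverage near 1x), mildly nested
and mildly overlapping, the regime in which a real annotation database
such as pooled gene exons sits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .bed_io import GenomicInterval, GenomicPosition

__all__ = [
    "SynthConfig",
    "generate_intervals",
    "generate_positions",
    "generate_regime_intervals",
    "REGIMES",
]


@dataclass(frozen=True, slots=True)
class SynthConfig:
    """Parameters of the synthetic interval database."""

    n_base_intervals: int = 1000
    genome_length: int = 100_000_000
    n_chroms: int = 10
    mean_length: int = 1000
    child_prob: float = 0.3
    max_depth: int = 3
    partial_overlap_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_base_intervals <= 0 or self.genome_length <= 0 or self.n_chroms <= 0:
            raise ValueError("counts and lengths must be positive")
        if self.mean_length <= 0 or self.max_depth < 1:
            raise ValueError("mean_length must be positive and max_depth >= 1")
        for p in (self.child_prob, self.partial_overlap_frac):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.chrom_length < self.min_base_length:
            raise ValueError(
                "infeasible config: chromosomes too short to host an interval "
                "deep enough for max_depth (child would be longer than parent)"
            )

    @property
    def chrom_length(self) -> int:
        return self.genome_length // self.n_chroms

    @property
    def min_base_length(self) -> int:
        # halving the length per generation must keep every non-leaf level
        # at length >= 2 so a strictly contained child always fits
        return max(2, 2 ** self.max_depth)


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def generate_intervals(config: SynthConfig) -> list[GenomicInterval]:
    """Generate a nested, partially overlapping interval database.

    Base intervals are uniform over the genome with exponential lengths
    (floored so that a full-depth lineage always fits).  Every interval
    above the maximum depth spawns, with probability ``child_prob``, one or
    two disjoint children strictly inside itself; disjoint placement keeps
    the realized nesting depth equal to the generation depth.  A
    ``partial_overlap_frac`` fraction of later siblings (at every level)
    have their start pulled inside the preceding sibling, creating partial
    overlap without containment.  Labels are unique synthetic tokens.
    """
    rng = np.random.default_rng(config.seed)
    counter = 0
    out: list[GenomicInterval] = []

    def fresh_label() -> str:
        nonlocal counter
        counter += 1
        return f"iv{counter:06d}"

    def overlap_shift(sibs: list[list[int]]) -> None:
        # pull a fraction of later siblings into their predecessor
        for k in range(1, len(sibs)):
            if rng.random() >= config.partial_overlap_frac:
                continue
            prev, cur = sibs[k - 1], sibs[k]
            # partial overlap only: keep cur.stop beyond prev.stop
            if cur[1] > prev[1] and prev[1] - prev[0] >= 2:
                cur[0] = int(rng.integers(prev[0] + 1, prev[1]))

    def spawn(ps: int, pe: int, depth: int) -> None:
        if depth >= config.max_depth:
            return
        if rng.random() >= config.child_prob:
            return
        plen = pe - ps
        if plen < 2:
            return
        k = 2 if (plen >= 4 and rng.random() < 0.5) else 1
        seg = plen // k
        children: list[list[int]] = []
        last_level = depth + 1 >= config.max_depth
        for c in range(k):
            seg_s, seg_e = ps + c * seg, ps + (c + 1) * seg
            min_len = 1 if last_level else 2
            clen = max(min_len, seg // 2)
            if clen > seg_e - seg_s:
                continue
            cs = int(rng.integers(seg_s, seg_e - clen + 1))
            children.append([cs, cs + clen])
        # a child spanning the whole parent would not be *strictly* inside
        children = [c for c in children if (c[0], c[1]) != (ps, pe)]
        overlap_shift(children)
        for cs, ce in children:
            out.append(GenomicInterval(chrom, cs, ce, fresh_label()))
            spawn(cs, ce, depth + 1)

    clen_chrom = config.chrom_length
    chrom_ids = rng.integers(0, config.n_chroms, config.n_base_intervals)
    raw_lengths = rng.exponential(config.mean_length, config.n_base_intervals)
    bases_by_chrom: dict[int, list[list[int]]] = {}
    for ci, raw in zip(chrom_ids, raw_lengths):
        length = min(clen_chrom, max(config.min_base_length, int(round(raw))))
        start = int(rng.integers(0, clen_chrom - length + 1))
        bases_by_chrom.setdefault(int(ci), []).append([start, start + length])

    for ci in sorted(bases_by_chrom):
        chrom = _chrom_name(ci)
        sibs = sorted(bases_by_chrom[ci])
        overlap_shift(sibs)
        for bs, be in sibs:
            out.append(GenomicInterval(chrom, bs, be, fresh_label()))
            spawn(bs, be, 1)
    return out


REGIMES = ("disjoint", "nested", "partial", "duplicates", "mixed")


def generate_regime_intervals(
    n: int, regime: str, seed: int
) -> list[GenomicInterval]:
    """Small dense interval sets exercising one overlap regime.

    Unlike :func:`generate_intervals` (genome-scale, sparse), these sets
    are deliberately compact so that queries, containment and edits hit
    the interesting configurations constantly: ``disjoint`` intervals,
    deeply ``nested`` chains, ``partial`` staircase overlaps, exact
    coordinate ``duplicates``, and a ``mixed`` blend of all four.
    Deterministic per (n, regime, seed); labels are unique.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    if n <= 0:
        return []
    rng = np.random.default_rng(seed)
    out: list[GenomicInterval] = []

    def emit(chrom: str, s: int, e: int) -> None:
        out.append(GenomicInterval(chrom, s, e, f"r{len(out) + 1:05d}"))

    def make(regime: str, chrom: str, count: int) -> None:
        if count <= 0:
            return
        if regime == "disjoint":
            cursor = int(rng.integers(0, 20))
            for _ in range(count):
                length = int(rng.integers(1, 12))
                emit(chrom, cursor, cursor + length)
                cursor += length + int(rng.integers(1, 10))
        elif regime == "nested":
            left = count
            cursor = int(rng.integers(0, 20))
            while left > 0:
                depth = int(min(left, rng.integers(2, 7)))
                span = 4 * depth + int(rng.integers(0, 20))
                s, e = cursor, cursor + span
                for _ in range(depth):
                    emit(chrom, s, e)
                    if e - s < 3:
                        break
                    s += int(rng.integers(1, max(2, (e - s) // 3)))
                    e -= int(rng.integers(0, max(1, (e - s) // 3))) or 0
                    if s >= e:
                        break
                cursor += span + int(rng.integers(2, 10))
                left -= depth
        elif regime == "partial":
            s = int(rng.integers(0, 20))
            length = int(rng.integers(6, 20))
            for _ in range(count):
                emit(chrom, s, s + length)
                s += int(rng.integers(1, length))  # step < length => overlap
                length = int(rng.integers(6, 20))
        elif regime == "duplicates":
            base = max(1, count // 2)
            make("partial" if rng.random() < 0.5 else "disjoint", chrom, base)
            pool = [iv for iv in out if iv.chrom == chrom]
            for _ in range(count - base):
                src = pool[int(rng.integers(0, len(pool)))]
                emit(chrom, src.start, src.stop)
        else:  # mixed
            while count > 0:
                sub = REGIMES[int(rng.integers(0, 4))]
                chunk = int(min(count, rng.integers(2, 12)))
                make(sub, chrom, chunk)
                count -= chunk

    n_chr1 = n if n < 4 else int(rng.integers(n // 2, n + 1))
    make(regime, "chr1", n_chr1)
    make(regime, "chr2", n - n_chr1)
    return out


def generate_positions(
    n: int, genome_length: int, n_chroms: int = 10, seed: int = 0
) -> list[GenomicPosition]:
    """``n`` base-pair positions uniform over a genome of equal chromosomes."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    clen = genome_length // n_chroms
    g = rng.integers(0, clen * n_chroms, n)
    return [
        GenomicPosition(_chrom_name(int(x // clen)), int(x % clen)) for x in g
    ]
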