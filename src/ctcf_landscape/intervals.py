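"""Genome-interval arithmetic shared by all pipeline stages.

Overlap semantics are half-open with a >=1 bp shared-base default, matching
standard BED interval tooling.  Control regions are sampled exactly
uniformly over valid non-overlapping, N-free placements (see
``sample_control_regions``), so a fixed seed yields a fixed region set and
tight-capacity genomes are still filled whenever a placement exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import lgamma
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from ctcf_landscape.formats import GenomeSequence, PeakRecord, RepeatCopy

logger = logging.getLogger(__name__)


class CapacityError(RuntimeError):
    """Raised when a genome cannot host the requested control regions."""


class IntervalSet:
    """Per-chromosome interval container with overlap queries.

    Query results are independent of insertion order.  Backed by interval
    trees; the brute-force pairwise check is kept as the test oracle.
    """

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        s = cls()
        for chrom, start, end in tuples:
            s.add(chrom, start, end)
        return s

    @classmethod
    def from_peaks(cls, peaks: Iterable[PeakRecord]) -> "IntervalSet":
        s = cls()
        for p in peaks:
            s.add(p.chrom, p.start, p.end, p)
        return s

    def add(self, chrom: str, start: int, end: int, payload=None) -> None:
        if start >= end:
            raise ValueError(f"empty interval [{start},{end})")
        # tag with an insertion index so duplicate intervals are preserved
        # (the backing tree has set semantics)
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end, (self._n, payload))
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def query(self, chrom: str, start: int, end: int, min_overlap_bp: int = 1):
        """Return (start, end, payload) triples overlapping by >= min_overlap_bp."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = []
        for iv in tree.overlap(start, end):
            if min(iv.end, end) - max(iv.begin, start) >= min_overlap_bp:
                hits.append((iv.begin, iv.end) + iv.data)
        hits.sort(key=lambda t: (t[0], t[1], t[2]))
        return [(s, e, payload) for s, e, _, payload in hits]

    def overlaps_any(self, chrom: str, start: int, end: int, min_overlap_bp: int = 1) -> bool:
        return bool(self.query(chrom, start, end, min_overlap_bp))

    def items(self):
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                yield chrom, iv.begin, iv.end, iv.data[1]


def count_family_overlaps(
    windows: IntervalSet,
    repeats: Sequence[RepeatCopy],
    min_overlap_bp: int = 1,
) -> dict[str, int]:
    """Count, per repeat family, copies overlapping at least one window.

    Each copy contributes at most once to its family regardless of how many
    windows it touches.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    counts: dict[str, int] = {}
    for copy in repeats:
        counts.setdefault(copy.family_id, 0)
        if windows.overlaps_any(copy.chrom, copy.start, copy.end, min_overlap_bp):
            counts[copy.family_id] += 1
    return counts


def summit_windows(
    peaks: Sequence[PeakRecord],
    flank: int,
    chrom_lengths: dict[str, int],
) -> IntervalSet:
    """Build summit +/- flank windows, clipped to chromosome bounds."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    out = IntervalSet()
    n_clipped = 0
    for p in peaks:
        if p.chrom not in chrom_lengths:
            raise ValueError(f"peak {p.name}: unknown chromosome {p.chrom!r}")
        lo = p.summit - flank
        hi = p.summit + flank
        start, end = max(0, lo), min(chrom_lengths[p.chrom], hi)
        if (start, end) != (lo, hi):
            n_clipped += 1
        out.add(p.chrom, start, end, p)
    if n_clipped:
        logger.warning("summit_windows: %d windows clipped at chromosome bounds", n_clipped)
    return out


# ---------------------------------------------------------------------------
# control-region sampling
# ---------------------------------------------------------------------------


@dataclass
class ControlRegionSet:
    """Non-overlapping, N-free control regions of fixed length."""

    n_regions: int
    region_length: int
    regions: list[tuple[str, int, int]]
    seed: int

    def as_interval_set(self) -> IntervalSet:
        return IntervalSet.from_tuples(self.regions)

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, (chrom, start, end) in enumerate(self.regions):
                fh.write(f"{chrom}\t{start}\t{end}\tcontrol_{i}\t0\t.\n")


def _nfree_blocks(genome: GenomeSequence, length: int) -> list[tuple[str, int, int]]:
    """Maximal N-free runs of at least ``length`` bp, per chromosome."""
    blocks = []
    for chrom in genome.records:
        arr = np.frombuffer(genome.records[chrom].encode("ascii"), dtype=np.uint8)
        ok = arr != ord("N")
        edges = np.diff(ok.view(np.int8))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1) + 1
        if ok[0]:
            starts = np.concatenate(([0], starts))
        if ok[-1]:
            ends = np.concatenate((ends, [len(arr)]))
        for s, e in zip(starts, ends):
            if e - s >= length:
                blocks.append((chrom, int(s), int(e)))
    return blocks


def _log_placements(block_len: int, k: int, length: int) -> float:
    """log of the number of ways to place k non-overlapping length-L
    intervals in a block: C(M - kL + k, k)."""
    top = block_len - k * length + k
    if k < 0 or top < k:
        return -np.inf
    return lgamma(top + 1) - lgamma(k + 1) - lgamma(top - k + 1)


def _sample_block_placement(rng, block_len: int, k: int, length: int) -> list[int]:
    """Uniformly sample k sorted non-overlapping starts within [0, block_len).

    Bijection: starts x_1 < ... < x_k with x_{j+1} >= x_j + L correspond to
    k distinct integers y_j = x_j - (j-1)(L-1) drawn from
    [0, block_len - L - (k-1)(L-1)].
    """
    if k == 0:
        return []
    t = block_len - length + 1 - (k - 1) * (length - 1)
    ys = np.sort(rng.choice(t, size=k, replace=False))
    return [int(y + j * (length - 1)) for j, y in enumerate(ys)]


def sample_control_regions(
    genome: GenomeSequence,
    n: int,
    length: int,
    seed: int,
    exclude: IntervalSet | None = None,
) -> ControlRegionSet:
    """Sample ``n`` non-overlapping, N-free regions of ``length`` bp.

    The sampler is exactly uniform over all valid placements: N-free blocks
    are enumerated (split further around ``exclude`` intervals when given),
    the per-block allocation of region counts is drawn proportional to the
    number of placements (log-binomial dynamic programme over blocks), and
    the within-block placement uses the stars-and-bars bijection.  Identical
    seeds therefore yield identical region sets and a tight genome (e.g. a
    200 bp chromosome with n=2, length=100) is tiled deterministically.
    """
    if n < 1 or length < 1:
        raise ValueError("n and length must be positive")
    blocks = _nfree_blocks(genome, length)
    if exclude is not None:
        blocks = _subtract_excluded(blocks, exclude, length)
    eligible = sum(e - s for _, s, e in blocks)
    if eligible < n * length:
        raise CapacityError(
            f"genome cannot host {n} x {length} bp control regions: "
            f"only {eligible} eligible bp (need {n * length})"
        )

    rng = np.random.default_rng(seed)
    caps = [(e - s) // length for _, s, e in blocks]
    n_blocks = len(blocks)

    # suffix DP over blocks: logz[i][j] = log #configs for blocks i.. with j regions
    logz = np.full((n_blocks + 1, n + 1), -np.inf)
    logz[n_blocks, 0] = 0.0
    for i in range(n_blocks - 1, -1, -1):
        m = blocks[i][2] - blocks[i][1]
        kmax = min(caps[i], n)
        lp = np.array([_log_placements(m, k, length) for k in range(kmax + 1)])
        for j in range(n + 1):
            ks = np.arange(0, min(kmax, j) + 1)
            vals = lp[ks] + logz[i + 1, j - ks]
            mx = np.max(vals)
            logz[i, j] = mx + np.log(np.sum(np.exp(vals - mx))) if np.isfinite(mx) else -np.inf
    if not np.isfinite(logz[0, n]):
        raise CapacityError(
            f"no placement of {n} x {length} bp regions exists in the eligible blocks"
        )

    regions: list[tuple[str, int, int]] = []
    remaining = n
    for i, (chrom, bstart, bend) in enumerate(blocks):
        m = bend - bstart
        kmax = min(caps[i], remaining)
        logw = np.array(
            [_log_placements(m, k, length) + logz[i + 1, remaining - k] for k in range(kmax + 1)]
        )
        w = np.exp(logw - np.max(logw))
        w /= w.sum()
        k = int(rng.choice(kmax + 1, p=w))
        for x in _sample_block_placement(rng, m, k, length):
            regions.append((chrom, bstart + x, bstart + x + length))
        remaining -= k
    assert remaining == 0
    regions.sort()
    return ControlRegionSet(n_regions=n, region_length=length, regions=regions, seed=seed)


def _subtract_excluded(
    blocks: list[tuple[str, int, int]], exclude: IntervalSet, length: int
) -> list[tuple[str, int, int]]:
    out = []
    for chrom, bstart, bend in blocks:
        cuts = sorted(
            (max(s, bstart), min(e, bend)) for s, e, _ in exclude.query(chrom, bstart, bend)
        )
        pos = bstart
        for s, e in cuts:
            if s - pos >= length:
                out.append((chrom, pos, s))
            pos = max(pos, e)
        if bend - pos >= length:
            out.append((chrom, pos, bend))
    return out
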