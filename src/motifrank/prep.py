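"""ChIP-seq preprocessing: read filters, peak normalization, region sets.

Consumes per-peak kernel-density scores (e.g. from F-seq); density
estimation itself is not reimplemented here, though
:func:`gaussian_kernel_density` offers a simple fallback for building
fixtures.  Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

MIN_PEAK_WIDTH = 100
MAX_PEAK_WIDTH = 1000


@dataclass(frozen=True)
class Peak:
    """A called peak with its maximum kernel-density score and summit."""

    chrom: str
    start: int
    end: int
    score: float
    summit: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty peak interval [{self.start}, {self.end})")
        if self.score < 0:
            raise ValueError("peak score must be >= 0")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


# Alignment record: (read_id, chrom, pos, strand, n_hits)
Alignment = Tuple[str, str, int, str, int]

_PILEUP_WINDOW = 30
_PILEUP_MIN_READS = 10  # "more than 10" -> window count must exceed this
_PILEUP_FRACTION = 0.70
_MAX_HITS = 4
_MAX_TAGS_PER_LOCATION = 5


def filter_alignments(alignments: Sequence[Alignment]) -> List[Alignment]:
    """Read-level filters applied in order.

    1. Keep reads aligned to at most four genomic locations.
    2. Remove single-base pile-ups: if a 30-bp window holds more than 10
       reads of which at least 70% start at one base, drop that base's reads.
    3. Cap the tag count at any remaining location at five.

    Input must be sorted by (chrom, pos).
    """
    coords = [(a[1], a[2]) for a in alignments]
    if coords != sorted(coords):
        raise ValueError("alignments must be coordinate-sorted")

    kept = [a for a in alignments if a[4] <= _MAX_HITS]

    counts: Dict[Tuple[str, int], int] = {}
    for a in kept:
        counts[(a[1], a[2])] = counts.get((a[1], a[2]), 0) + 1
    by_chrom: Dict[str, List[int]] = {}
    for chrom, pos in counts:
        by_chrom.setdefault(chrom, []).append(pos)
    half = _PILEUP_WINDOW // 2
    removed = set()
    for chrom, positions in by_chrom.items():
        positions.sort()
        arr = np.asarray(positions)
        cnt = np.asarray([counts[(chrom, p)] for p in positions])
        csum = np.concatenate([[0], np.cumsum(cnt)])
        for i, p in enumerate(positions):
            lo = np.searchsorted(arr, p - half, side="left")
            hi = np.searchsorted(arr, p + half, side="right")
            window_total = csum[hi] - csum[lo]
            if window_total > _PILEUP_MIN_READS and cnt[i] >= _PILEUP_FRACTION * window_total:
                removed.add((chrom, p))
    kept = [a for a in kept if (a[1], a[2]) not in removed]

    out: List[Alignment] = []
    tag_count: Dict[Tuple[str, int], int] = {}
    for a in kept:
        key = (a[1], a[2])
        tag_count[key] = tag_count.get(key, 0) + 1
        if tag_count[key] <= _MAX_TAGS_PER_LOCATION:
            out.append(a)
    return out


def normalize_peaks(
    peaks: Sequence[Peak],
    *,
    discard_percentile: float = 99.9,
    score_cutoff: float = None,
) -> List[Peak]:
    """Clamp peak widths to [100, 1000] bp and drop extreme-score peaks.

    Resizing keeps each flank proportional to its distance from the summit,
    so a summit one quarter of the way in stays one quarter of the way in.
    Peaks with scores above ``score_cutoff`` (default: the 99.9th percentile
    of the input scores) are discarded first; these typically correspond to
    collapsed repeats, rDNA and mitochondrial pile-ups.  Idempotent.
    """
    peaks = list(peaks)
    for p in peaks:
        if not p.start <= p.summit < p.end:
            raise ValueError(f"summit {p.summit} outside peak [{p.start}, {p.end})")
    if peaks:
        if score_cutoff is None:
            score_cutoff = float(np.percentile([p.score for p in peaks], discard_percentile))
        peaks = [p for p in peaks if p.score <= score_cutoff]

    out: List[Peak] = []
    for p in peaks:
        width = p.width
        if MIN_PEAK_WIDTH <= width <= MAX_PEAK_WIDTH:
            out.append(p)
            continue
        target = MIN_PEAK_WIDTH if width < MIN_PEAK_WIDTH else MAX_PEAK_WIDTH
        left = p.summit - p.start
        right = p.end - p.summit
        new_left = int(round(left * target / width))
        new_right = target - new_left
        start = p.summit - new_left
        end = p.summit + new_right
        if start < 0:
            end -= start
            start = 0
        out.append(replace(p, start=start, end=end))
    return out


def define_regions_ensemble(
    peak_sets: Mapping[str, Sequence[Peak]], top_n: int = 5000
) -> List[GenomicInterval]:
    """Union of each factor's top peaks, with overlapping intervals merged.

    Pools the ``top_n`` highest-scoring peaks per factor (a panel of
    ChIP-seq experiments approximating open chromatin), merges overlaps,
    and names regions ``chrom:start-end``.
    """
    pool: List[Peak] = []
    for factor, peaks in peak_sets.items():
        ranked = sorted(peaks, key=lambda p: -p.score)[:top_n]
        pool.extend(ranked)
    if not pool:
        raise ValueError("no peaks to pool")
    by_chrom: Dict[str, List[Peak]] = {}
    for p in pool:
        by_chrom.setdefault(p.chrom, []).append(p)
    merged: List[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted((p.start, p.end) for p in by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def assign_evidence(
    regions: Sequence[GenomicInterval], peaks: Sequence[Peak]
) -> Dict[str, float]:
    """Max overlapping factor-peak score per region; 0 with no overlap.

    The raw scores are meant to be transformed downstream (log-odds against
    a background percentile).  Chromosomes present in the regions but absent
    from the peak set are reported once.
    """
    trees: Dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p.score)
    missing = sorted({r.chrom for r in regions} - trees.keys())
    if missing:
        warnings.warn(f"no peaks on chromosomes {missing}; their regions score 0", stacklevel=2)
    out: Dict[str, float] = {}
    for r in regions:
        tree = trees.get(r.chrom)
        hits = tree.overlap(r.start, r.end) if tree is not None else ()
        out[r.id] = max((iv.data for iv in hits), default=0.0)
    return out


def gaussian_kernel_density(
    positions: Sequence[int], grid: Sequence[int], bandwidth: float
) -> np.ndarray:
    """Plain Gaussian-kernel read-density profile, for building fixtures."""
    pos = np.asarray(positions, dtype=float)
    g = np.asarray(grid, dtype=float)
    if pos.size == 0:
        return np.zeros(g.size)
    z = (g[:, None] - pos[None, :]) / bandwidth
    return np.exp(-0.5 * z**2).sum(axis=1) / (bandwidth * np.sqrt(2 * np.pi))
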