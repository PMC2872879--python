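"""Suffix-array index over a set of regulatory regions.

The region sequences are concatenated with sentinel separators (outside the
nucleotide alphabet, so no match can span two regions) and indexed by a
suffix array built with the Manber-Myers prefix-doubling algorithm on numpy.
Occurrence queries for degenerate IUPAC motifs are answered by a branching
descent: the suffix-array interval of matching suffixes is refined one motif
position at a time, splitting into sub-intervals per allowed base.  This
avoids expanding N-heavy motifs into exponentially many literal words.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

import numpy as np

from . import motif as mt

# Separator/sentinel = 0; never member of any motif symbol's allowed set.
_CODE = {"A": 1, "C": 2, "G": 3, "T": 4, "N": 5}

# Allowed text codes per motif symbol.  Sequence N (code 5) is matched only
# by motif N.
_ALLOWED: Dict[str, Tuple[int, ...]] = {
    sym: tuple(sorted(_CODE[b] for b in bases)) for sym, bases in mt.IUPAC_SETS.items()
}
_ALLOWED["N"] = (1, 2, 3, 4, 5)


@dataclass
class Region:
    """One putative regulatory region with optional orthologous sequences."""

    id: str
    sequence: str
    orthologs: Dict[str, str] = field(default_factory=dict)


def _suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling; O(n log n) with numpy lexsort."""
    n = codes.size
    rank = codes.astype(np.int64)
    sa = np.argsort(rank, kind="stable")
    k = 1
    while True:
        second = np.full(n, -1, dtype=np.int64)
        second[: n - k] = rank[k:]
        sa = np.lexsort((second, rank))
        new_rank = np.empty(n, dtype=np.int64)
        prev, curr = sa[:-1], sa[1:]
        diff = (rank[curr] != rank[prev]) | (second[curr] != second[prev])
        new_rank[sa[0]] = 0
        new_rank[curr] = np.cumsum(diff)
        rank = new_rank
        if rank[sa[-1]] == n - 1:
            break
        k *= 2
    return sa


class SuffixIndex:
    """Concatenated-region suffix array answering motif occurrence queries."""

    def __init__(self, regions: Sequence[Region], *, lowercase_to_n: bool = False):
        regions = list(regions)
        if not regions:
            raise ValueError("region list is empty")
        seen: Dict[str, int] = {}
        dups = []
        for r in regions:
            if r.id in seen:
                dups.append(r.id)
            seen[r.id] = 1
            if len(r.sequence) == 0:
                raise ValueError(f"region {r.id!r} has an empty sequence")
        if dups:
            raise ValueError(f"duplicate region ids: {sorted(set(dups))}")

        self.regions = regions
        self.ids = [r.id for r in regions]
        self._id_to_index = {r.id: i for i, r in enumerate(regions)}
        seqs = [mt.normalize_sequence(r.sequence, lowercase_to_n=lowercase_to_n) for r in regions]
        self._norm_seqs = seqs

        starts: List[int] = []
        codes: List[int] = []
        pos = 0
        for s in seqs:
            starts.append(pos)
            codes.extend(_CODE[c] for c in s)
            codes.append(0)  # separator after every region
            pos += len(s) + 1
        self._starts = np.asarray(starts, dtype=np.int64)
        self._lengths = np.asarray([len(s) for s in seqs], dtype=np.int64)
        arr = np.asarray(codes, dtype=np.int64)
        self._codes_arr = arr
        self._sa_arr = _suffix_array(arr)
        # Plain lists for the bisection hot path (faster scalar access).
        self._codes = arr.tolist()
        self._sa = self._sa_arr.tolist()
        self.n_indexed = int(self._lengths.sum())

    # -- interval machinery -------------------------------------------------

    def _refine(self, lo: int, hi: int, depth: int, code: int) -> Tuple[int, int]:
        """Sub-interval of sa[lo:hi] whose suffixes have `code` at `depth`."""
        sa, codes = self._sa, self._codes
        l, r = lo, hi
        while l < r:
            mid = (l + r) >> 1
            if codes[sa[mid] + depth] < code:
                l = mid + 1
            else:
                r = mid
        first = l
        r = hi
        while l < r:
            mid = (l + r) >> 1
            if codes[sa[mid] + depth] <= code:
                l = mid + 1
            else:
                r = mid
        return first, l

    def _intervals(self, motif: str) -> List[Tuple[int, int]]:
        intervals: List[Tuple[int, int]] = [(0, len(self._sa))]
        for depth, sym in enumerate(motif):
            allowed = _ALLOWED[sym]
            refined: List[Tuple[int, int]] = []
            for lo, hi in intervals:
                for code in allowed:
                    l, r = self._refine(lo, hi, depth, code)
                    if l < r:
                        refined.append((l, r))
            if not refined:
                return []
            intervals = refined
        return intervals

    def _positions(self, motif: str) -> np.ndarray:
        """Text positions of all forward matches of the motif."""
        intervals = self._intervals(motif)
        if not intervals:
            return np.empty(0, dtype=np.int64)
        sa = self._sa
        chunks = [sa[lo:hi] for lo, hi in intervals]
        return np.asarray([p for ch in chunks for p in ch], dtype=np.int64)

    def _pos_to_region(self, positions: np.ndarray) -> np.ndarray:
        return np.searchsorted(self._starts, positions, side="right") - 1

    # -- public queries -----------------------------------------------------

    def region_indices_containing(self, motif: str, mode: str = "dna") -> FrozenSet[int]:
        """Indices (into ``self.regions``) of regions containing the motif."""
        mt.validate(motif, min_length=1, max_length=10**9)
        pos = self._positions(motif)
        if mode == "dna":
            rc = mt.reverse_complement(motif)
            if rc != motif:
                rcpos = self._positions(rc)
                pos = np.concatenate([pos, rcpos]) if rcpos.size else pos
        elif mode != "rna":
            raise ValueError(f"mode must be 'dna' or 'rna', got {mode!r}")
        if pos.size == 0:
            return frozenset()
        return frozenset(np.unique(self._pos_to_region(pos)).tolist())

    def regions_containing(self, motif: str, mode: str = "dna") -> Set[str]:
        """Region ids of the positive set of the motif."""
        return {self.regions[i].id for i in self.region_indices_containing(motif, mode)}

    def occurrence_positions(self, motif: str, mode: str = "dna") -> Dict[str, List[Tuple[int, str]]]:
        """Per-region 0-based match offsets with strand.

        Reverse-strand matches (``-``) are offsets of the reverse-complement
        window on the forward text; a window matching on both strands is
        reported once per strand.
        """
        mt.validate(motif, min_length=1, max_length=10**9)
        if mode not in ("dna", "rna"):
            raise ValueError(f"mode must be 'dna' or 'rna', got {mode!r}")
        out: Dict[str, List[Tuple[int, str]]] = {}

        def collect(query: str, strand: str) -> None:
            pos = self._positions(query)
            if pos.size == 0:
                return
            ridx = self._pos_to_region(pos)
            for p, ri in zip(pos.tolist(), ridx.tolist()):
                rid = self.regions[ri].id
                out.setdefault(rid, []).append((int(p - self._starts[ri]), strand))

        collect(motif, "+")
        if mode == "dna":
            collect(mt.reverse_complement(motif), "-")
        for occ in out.values():
            occ.sort()
        return out

    def sequence(self, region_id: str) -> str:
        """Normalized sequence of a region."""
        return self._norm_seqs[self._id_to_index[region_id]]


def build_index(regions: Sequence[Region], **kwargs) -> SuffixIndex:
    """Build a :class:`SuffixIndex` over the region set."""
    return SuffixIndex(regions, **kwargs)
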