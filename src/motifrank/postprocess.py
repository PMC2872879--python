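"""PSSM construction, motif similarity and redundancy clustering.

The search returns many near-duplicate consensus motifs.  Each motif is
summarized as a PSSM from the empirical counts of its exact instantiations
inside its predicted target regions; motifs are then greedily clustered
around the highest-scoring representatives.  Two motifs are deemed similar
when (1) their PSSMs reach a Harbison similarity of at least 0.75 over some
overlap alignment and (2) they co-occur within tau nucleotides in the same
regions more often than chance (hypergeometric upper-tail test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from . import motif as mt
from .index import SuffixIndex
from .search import MotifResult

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass
class Pssm:
    """Column-stochastic base-frequency matrix; rows are motif positions."""

    matrix: np.ndarray  # shape (width, 4), columns ordered A,C,G,T
    n_sites: int = 0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PSSM matrix must have shape (width, 4)")
        if np.any(self.matrix < 0):
            raise ValueError("PSSM entries must be non-negative")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each PSSM position must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "Pssm":
        return Pssm(self.matrix[::-1, ::-1].copy(), n_sites=self.n_sites)

    @classmethod
    def from_consensus(cls, word: str) -> "Pssm":
        """One-hot (or uniform-over-set for degenerate symbols) PSSM."""
        mat = np.zeros((len(word), 4))
        for i, sym in enumerate(word.upper()):
            bases = mt.IUPAC_SETS[sym]
            for b in bases:
                mat[i, _BASE_IDX[b]] = 1.0 / len(bases)
        return cls(mat, n_sites=0)


def pssm_from_occurrences(
    result: MotifResult,
    idx: SuffixIndex,
    *,
    mode: str = "dna",
    pseudocount: float = 0.0,
) -> Pssm:
    """Empirical base frequencies over all match windows in the positive set.

    Reverse-strand windows are reverse-complemented into motif orientation
    before counting; an ambiguous sequence N spreads 1/4 count per base.
    """
    if not result.positive_set:
        raise ValueError("positive set is empty")
    w = len(result.motif)
    counts = np.full((w, 4), float(pseudocount))
    occ = idx.occurrence_positions(result.motif, mode)
    total = 0
    for rid in result.positive_set:
        seq = idx.sequence(rid)
        for offset, strand in occ.get(rid, ()):
            word = seq[offset : offset + w]
            if strand == "-":
                word = mt.reverse_complement(word)
            for i, c in enumerate(word):
                if c == "N":
                    counts[i] += 0.25
                else:
                    counts[i, _BASE_IDX[c]] += 1.0
            total += 1
    if total == 0:
        raise ValueError(f"motif {result.motif!r} has no occurrences in its positive set")
    return Pssm(counts / counts.sum(axis=1, keepdims=True), n_sites=total)


# ---------------------------------------------------------------------------
# Similarity


def harbison_distance(p: Pssm, q: Pssm) -> float:
    """Average per-position Euclidean column distance, D in [0, 1].

    D = (1/w) * sum_i sqrt(0.5 * sum_L (a_iL - b_iL)^2); requires equal
    widths (use :func:`harbison_similarity` otherwise).
    """
    if p.width != q.width:
        raise ValueError(f"width mismatch: {p.width} vs {q.width}")
    return _distance_on(p.matrix, q.matrix)


def _distance_on(a: np.ndarray, b: np.ndarray) -> float:
    per_col = np.sqrt(0.5 * ((a - b) ** 2).sum(axis=1))
    return float(per_col.mean())


def harbison_similarity(
    p: Pssm, q: Pssm, *, mode: str = "dna", return_alignment: bool = False
):
    """Max over overlap alignments (and orientations in DNA mode) of 1 - D.

    The minimum overlap is six positions, relaxed to five when either motif
    is only five positions wide.  With ``return_alignment`` the best
    ``(similarity, shift, orientation)`` is returned, where ``shift`` is the
    offset of q's first position relative to p's and orientation is '+' or
    '-' (reverse complement of q).
    """
    wp, wq = p.width, q.width
    if wp < 5 or wq < 5:
        raise ValueError("PSSMs must be at least 5 positions wide")
    min_overlap = 5 if min(wp, wq) == 5 else 6
    orientations = [("+", q.matrix)]
    if mode == "dna":
        orientations.append(("-", q.reverse_complement().matrix))
    best = (-np.inf, 0, "+")
    for orient, qmat in orientations:
        for shift in range(-(wq - min_overlap), wp - min_overlap + 1):
            p_lo, p_hi = max(0, shift), min(wp, shift + wq)
            if p_hi - p_lo < min_overlap:
                continue
            q_lo = p_lo - shift
            sim = 1.0 - _distance_on(
                p.matrix[p_lo:p_hi], qmat[q_lo : q_lo + (p_hi - p_lo)]
            )
            if sim > best[0]:
                best = (sim, shift, orient)
    if return_alignment:
        return best
    return best[0]


# ---------------------------------------------------------------------------
# Co-occurrence


def cooccurrence_pvalue(pos1: Set[str], pos2: Set[str], cooccur: Set[str], d: int) -> float:
    """Upper-tail hypergeometric probability of >= |cooccur| shared regions.

    Models |pos1| and |pos2| regions drawn without replacement from d and
    asks how surprising the observed co-occurrence count is.
    """
    if not cooccur <= (set(pos1) & set(pos2)):
        raise ValueError("cooccur must be a subset of pos1 intersection pos2")
    if max(len(pos1), len(pos2)) > d:
        raise ValueError("positive sets larger than the region universe")
    c = len(cooccur)
    if c == 0:
        return 1.0
    return float(stats.hypergeom.sf(c - 1, d, len(pos1), len(pos2)))


def cooccurring_regions(
    occ1: Dict[str, List[Tuple[int, str]]],
    occ2: Dict[str, List[Tuple[int, str]]],
    tau: int,
    restrict_to: Optional[Set[str]] = None,
) -> Set[str]:
    """Regions where both motifs occur with nearest start offsets <= tau."""
    shared = occ1.keys() & occ2.keys()
    if restrict_to is not None:
        shared &= restrict_to
    out = set()
    for rid in shared:
        starts1 = sorted(o for o, _ in occ1[rid])
        starts2 = np.asarray(sorted(o for o, _ in occ2[rid]))
        for s1 in starts1:
            j = np.searchsorted(starts2, s1)
            near = []
            if j < starts2.size:
                near.append(abs(int(starts2[j]) - s1))
            if j > 0:
                near.append(abs(int(starts2[j - 1]) - s1))
            if near and min(near) <= tau:
                out.add(rid)
                break
    return out


def motifs_similar(
    r1: MotifResult,
    r2: MotifResult,
    idx: SuffixIndex,
    *,
    mode: str = "dna",
    tau: int = 50,
    similarity_cutoff: float = 0.75,
    pvalue_cutoff: float = 0.05,
) -> bool:
    """Similarity rule for clustering: PSSM similarity AND co-occurrence."""
    if r1.pssm is None or r2.pssm is None:
        raise ValueError("build PSSMs before testing motif similarity")
    if harbison_similarity(r1.pssm, r2.pssm, mode=mode) < similarity_cutoff:
        return False
    occ1 = idx.occurrence_positions(r1.motif, mode)
    occ2 = idx.occurrence_positions(r2.motif, mode)
    both = set(r1.positive_set) & set(r2.positive_set)
    co = cooccurring_regions(occ1, occ2, tau, restrict_to=both)
    p = cooccurrence_pvalue(set(r1.positive_set), set(r2.positive_set), co, len(idx.regions))
    return p <= pvalue_cutoff


# ---------------------------------------------------------------------------
# Clustering


@dataclass
class MotifCluster:
    """A representative motif with its redundant neighbors."""

    representative: MotifResult
    members: List[MotifResult]  # includes the representative, first
    pssm: Optional[Pssm] = None


def cluster_motifs(
    results: Sequence[MotifResult],
    idx: SuffixIndex,
    *,
    mode: str = "dna",
    tau: int = 50,
    similarity_cutoff: float = 0.75,
    pvalue_cutoff: float = 0.05,
    pseudocount: float = 0.0,
) -> List[MotifCluster]:
    """Greedy peeling: the top remaining motif absorbs everything similar.

    Input must be sorted by score descending; cluster indices then follow
    score order.  Members' PSSMs are built on demand.  Each result lands in
    exactly one cluster.
    """
    results = list(results)
    for a, b in zip(results, results[1:]):
        if a.score < b.score:
            raise ValueError("results must be sorted by score descending")
    for r in results:
        if r.pssm is None:
            r.pssm = pssm_from_occurrences(r, idx, mode=mode, pseudocount=pseudocount)
    clusters: List[MotifCluster] = []
    remaining = results
    while remaining:
        rep = remaining[0]
        members = [rep] + [
            r
            for r in remaining[1:]
            if motifs_similar(
                rep,
                r,
                idx,
                mode=mode,
                tau=tau,
                similarity_cutoff=similarity_cutoff,
                pvalue_cutoff=pvalue_cutoff,
            )
        ]
        taken = set(id(r) for r in members)
        remaining = [r for r in remaining if id(r) not in taken]
        cluster = MotifCluster(representative=rep, members=members)
        cluster.pssm = cluster_pssm(cluster, mode=mode)
        clusters.append(cluster)
    return clusters


def cluster_pssm(cluster: MotifCluster, *, mode: str = "dna") -> Pssm:
    """Score-weighted average of member PSSMs in the representative's frame.

    Each member is aligned to the representative via its best Harbison
    overlap (shift and orientation); positions outside a member's overlap
    receive no contribution from it.  Negative scores are floored at 0.
    """
    rep = cluster.representative
    w = rep.pssm.width
    acc = np.zeros((w, 4))
    wsum = np.zeros(w)
    for member in cluster.members:
        weight = member.score
        if weight < 0:
            warnings.warn(
                f"negative score for cluster member {member.motif!r}; weight floored at 0",
                stacklevel=2,
            )
            weight = 0.0
        if member is rep:
            sim, shift, orient = 1.0, 0, "+"
        else:
            sim, shift, orient = harbison_similarity(
                rep.pssm, member.pssm, mode=mode, return_alignment=True
            )
        mat = member.pssm.matrix if orient == "+" else member.pssm.reverse_complement().matrix
        p_lo, p_hi = max(0, shift), min(w, shift + mat.shape[0])
        q_lo = p_lo - shift
        acc[p_lo:p_hi] += weight * mat[q_lo : q_lo + (p_hi - p_lo)]
        wsum[p_lo:p_hi] += weight
    if np.all(wsum == 0):
        warnings.warn("all cluster weights are zero; returning representative PSSM", stacklevel=2)
        return Pssm(rep.pssm.matrix.copy(), n_sites=rep.pssm.n_sites)
    mat = rep.pssm.matrix.copy()
    covered = wsum > 0
    mat[covered] = acc[covered] / wsum[covered, None]
    mat /= mat.sum(axis=1, keepdims=True)
    return Pssm(mat, n_sites=sum(m.pssm.n_sites for m in cluster.members))
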