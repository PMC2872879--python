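"""Greedy seed-and-evolve search for evidence-enriched IUPAC motifs.

Every non-degenerate 5-mer (pooled with its reverse complement in DNA mode,
giving 512 canonical seeds) initializes one hill-climbing trajectory.  At
each step the motif's local neighborhood -- single-base extensions,
single-side truncations, and single-position degeneracy widenings -- is
scored with a gene-set-enrichment style objective

    J(m) = sqrt(n) * (mean(E+) - mean(E)) / sd(E)

where E+ is the evidence over the motif's positive set (regions containing
the motif) of size n, and sd is the population standard deviation of the
full evidence vector.  The best strictly improving candidate is adopted;
ties break on the lexicographically smallest motif, so the whole search is
deterministic.  Positive sets whose size falls outside [a, floor(b*d)] give
unstable scores and are skipped.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

from . import motif as mt
from .evidence import EvidenceSet
from .index import Region, SuffixIndex, build_index


class ConstraintInfeasibleError(ValueError):
    """The region set cannot satisfy the positive-set size constraint."""


@dataclass
class SearchConfig:
    """Tunable parameters of the motif search.

    ``min_set_size`` / ``max_set_fraction`` are the set-size constraint
    [a, b*d]; presets: a=20, b=0.15 for ChIP-chip and overexpression data,
    a=100, b=0.30 for ChIP-seq.  ``mode`` 'dna' matches both strands and
    pools reverse-complement seeds; 'rna' is forward-strand with all 4^k
    seeds.  ``objective`` 'selection' binarizes evidence at
    ``selection_threshold`` before scoring.
    """

    min_set_size: int = 20
    max_set_fraction: float = 0.15
    mode: str = "dna"
    conservation: bool = False
    min_length: int = 5
    max_length: int = 20
    seed_length: int = 5
    objective: str = "average"  # or "selection"
    selection_threshold: float = 0.0
    finite_population_correction: bool = False
    evolve: bool = True

    def __post_init__(self):
        if self.min_set_size < 1:
            raise ValueError("min_set_size must be >= 1")
        if not 0 < self.max_set_fraction <= 1:
            raise ValueError("max_set_fraction must be in (0, 1]")
        if self.mode not in ("dna", "rna"):
            raise ValueError(f"mode must be 'dna' or 'rna', got {self.mode!r}")
        if self.objective not in ("average", "selection"):
            raise ValueError("objective must be 'average' or 'selection'")


@dataclass
class MotifResult:
    """One evolved motif with its score and supporting regions."""

    motif: str
    score: float
    positive_set: FrozenSet[str]
    seed: str
    steps: int
    pssm: object = None
    p_value: Optional[float] = None


def size_constraint_ok(n: int, d: int, cfg: SearchConfig) -> bool:
    """Both bounds of [a, floor(b*d)] inclusive."""
    return cfg.min_set_size <= n <= math.floor(cfg.max_set_fraction * d)


# ---------------------------------------------------------------------------
# Objective


class Scorer:
    """O(1)-per-query enrichment scorer over a fixed evidence vector."""

    def __init__(self, values: np.ndarray, *, finite_population_correction: bool = False):
        values = np.asarray(values, dtype=float)
        self.values = values
        self.d = values.size
        self.mean = float(values.mean())
        self.sd = float(values.std())  # population sd
        self.fpc = finite_population_correction

    def score_from_sum(self, total: float, n: int) -> float:
        if self.sd == 0.0 or n == 0 or n == self.d:
            return 0.0
        denom = self.sd
        if self.fpc:
            denom *= math.sqrt((self.d - n) / (self.d - 1))
        return math.sqrt(n) * (total / n - self.mean) / denom

    def score(self, indices) -> float:
        idx = (
            indices
            if isinstance(indices, np.ndarray)
            else np.fromiter(indices, dtype=np.int64)
        )
        if idx.size == 0:
            return 0.0
        return self.score_from_sum(float(self.values[idx].sum()), idx.size)


def enrichment_score(
    E: EvidenceSet, positive_ids: Set[str], *, finite_population_correction: bool = False
) -> float:
    """Centered, scaled average evidence of the positive set.

    J = sqrt(n) * (mean(E+) - mean(E)) / sd(E); 0 when the evidence is
    constant (uninformative) or the positive set is the whole region set.
    """
    if not positive_ids:
        raise ValueError("positive set is empty")
    lookup = {rid: i for i, rid in enumerate(E.ids)}
    unknown = positive_ids - lookup.keys()
    if unknown:
        raise ValueError(f"positive ids not in evidence set: {sorted(unknown)[:5]}")
    scorer = Scorer(E.values, finite_population_correction=finite_population_correction)
    return scorer.score(lookup[r] for r in positive_ids)


def selection_score(E: EvidenceSet, positive_ids: Set[str], k: float, **kwargs) -> float:
    """Enrichment of the indicator vector 1_{e_j > k} (top-gene selection)."""
    binarized = EvidenceSet(
        ids=E.ids, values=(E.values > k).astype(float), evidence_type="raw"
    )
    return enrichment_score(binarized, positive_ids, **kwargs)


# ---------------------------------------------------------------------------
# Move generators

_WIDEN = {"A": "MRW", "C": "MSY", "G": "KRS", "T": "KWY"}


def extension_moves(m: str, *, max_length: int = mt.MAX_LENGTH) -> List[str]:
    """Append or prepend each base: eight (k+1)-mers, none at the length cap."""
    if len(m) >= max_length:
        return []
    return [b + m for b in "ACGT"] + [m + b for b in "ACGT"]


def truncation_moves(m: str, *, min_length: int = mt.MIN_LENGTH) -> List[str]:
    """Drop the first or the last symbol; only for motifs of length >= 6."""
    if len(m) < max(6, min_length + 1):
        return []
    return [m[1:], m[:-1]]


def degeneracy_moves(m: str) -> List[str]:
    """Widen one position at a time.

    A base widens to its three double-degenerate supersets (A -> M,R,W;
    C -> M,S,Y; G -> K,R,S; T -> K,W,Y); a double-degenerate symbol widens
    to N except at the terminal positions; N cannot widen further.
    """
    out: List[str] = []
    last = len(m) - 1
    for j, sym in enumerate(m):
        if sym in _WIDEN:
            out.extend(m[:j] + t + m[j + 1 :] for t in _WIDEN[sym])
        elif sym != "N" and 0 < j < last:
            out.append(m[:j] + "N" + m[j + 1 :])
    return out


def neighborhood(m: str, *, min_length: int = mt.MIN_LENGTH, max_length: int = mt.MAX_LENGTH) -> List[str]:
    """All single-move candidates, de-duplicated, excluding the motif itself."""
    seen = {m}
    out: List[str] = []
    for cand in itertools.chain(
        extension_moves(m, max_length=max_length),
        truncation_moves(m, min_length=min_length),
        degeneracy_moves(m),
    ):
        if cand not in seen:
            seen.add(cand)
            out.append(cand)
    return out


def enumerate_seeds(cfg: SearchConfig) -> List[str]:
    """All non-degenerate seed k-mers.

    DNA mode pools each word with its reverse complement (512 canonical
    5-mers); RNA mode keeps all 4^k since matching is forward-strand only.
    """
    words = ("".join(w) for w in itertools.product("ACGT", repeat=cfg.seed_length))
    if cfg.mode == "dna":
        return sorted({mt.canonical_form(w) for w in words})
    return sorted(words)


# ---------------------------------------------------------------------------
# Conservation


def conservation_refine(
    positive_ids: Set[str], m: str, regions: Sequence[Region], mode: str = "dna"
) -> Set[str]:
    """Keep only regions whose every available ortholog also contains m.

    Regions with no orthologous sequences are retained unconditionally, so
    the filter never shrinks coverage of the dataset, only the positive set.
    """
    by_id = {r.id: r for r in regions}
    kept = set()
    for rid in positive_ids:
        orthologs = by_id[rid].orthologs
        if all(mt.matches(m, seq, mode) for seq in orthologs.values()):
            kept.add(rid)
    return kept


# ---------------------------------------------------------------------------
# Engine


class MotifSearch:
    """Reusable search engine bound to one region set and configuration.

    Positive sets depend only on the sequences, never on the evidence, so
    they are memoized across seeds, evolution steps and evidence
    permutations -- this is what makes the permutation null affordable.
    """

    def __init__(self, regions: Sequence[Region], cfg: SearchConfig, *, index: SuffixIndex = None):
        self.cfg = cfg
        self.index = index if index is not None else build_index(regions)
        self.regions = self.index.regions
        self.d = len(self.regions)
        if self.d < cfg.min_set_size:
            raise ConstraintInfeasibleError(
                f"{self.d} regions cannot satisfy min_set_size={cfg.min_set_size}; "
                "lower the bound or supply more regions"
            )
        self._max_size = math.floor(cfg.max_set_fraction * self.d)
        self._pos_cache: Dict[str, np.ndarray] = {}
        self._seed_matrix = None  # lazy, for the no-evolution fast path

    # -- positive sets ------------------------------------------------------

    def _pos(self, m: str) -> np.ndarray:
        """Sorted region indices of the (conservation-refined) positive set."""
        cached = self._pos_cache.get(m)
        if cached is not None:
            return cached
        pos = self.index.region_indices_containing(m, self.cfg.mode)
        if self.cfg.conservation and pos:
            pos = [
                i
                for i in pos
                if all(
                    mt.matches(m, seq, self.cfg.mode)
                    for seq in self.regions[i].orthologs.values()
                )
            ]
        arr = np.asarray(sorted(pos), dtype=np.int64)
        self._pos_cache[m] = arr
        return arr

    def positive_indices(self, m: str) -> FrozenSet[int]:
        return frozenset(self._pos(m).tolist())

    def positive_ids(self, m: str) -> FrozenSet[str]:
        return frozenset(self.regions[i].id for i in self._pos(m))

    # -- evidence alignment -------------------------------------------------

    def _aligned_values(self, E: EvidenceSet) -> np.ndarray:
        aligned = E.reordered(self.index.ids)
        return aligned.values

    def _make_scorer(self, values: np.ndarray) -> Scorer:
        if self.cfg.objective == "selection":
            values = (values > self.cfg.selection_threshold).astype(float)
        return Scorer(values, finite_population_correction=self.cfg.finite_population_correction)

    # -- greedy evolution ---------------------------------------------------

    def evolve(self, seed: str, scorer: Scorer) -> Optional[MotifResult]:
        """Hill-climb from one seed; None if no in-constraint motif is reached.

        A seed whose own positive set falls outside [a, b*d] is not scored
        (its constrained objective is -inf) but its trajectory may still
        climb into the feasible range -- short seeds on realistic region
        sets routinely match too many regions, and extension moves shrink
        the positive set.  If the trajectory never reaches the feasible
        range, the seed is reported invalid.
        """
        mt.validate(seed, min_length=self.cfg.min_length, max_length=self.cfg.max_length)
        pos = self._pos(seed)
        current, cur_pos = seed, pos
        cur_score = (
            scorer.score(pos)
            if size_constraint_ok(pos.size, self.d, self.cfg)
            else -math.inf
        )
        steps = 0
        while self.cfg.evolve:
            best = None
            best_score = cur_score
            best_pos = None
            for cand in neighborhood(
                current, min_length=self.cfg.min_length, max_length=self.cfg.max_length
            ):
                cpos = self._pos(cand)
                if not size_constraint_ok(cpos.size, self.d, self.cfg):
                    continue
                s = scorer.score(cpos)
                if s > best_score or (best is not None and s == best_score and cand < best):
                    best, best_score, best_pos = cand, s, cpos
            if best is None:
                break
            current, cur_score, cur_pos = best, best_score, best_pos
            steps += 1
        if not size_constraint_ok(cur_pos.size, self.d, self.cfg):
            return None
        return MotifResult(
            motif=current,
            score=cur_score,
            positive_set=frozenset(self.regions[i].id for i in cur_pos),
            seed=seed,
            steps=steps,
        )

    # -- full runs ----------------------------------------------------------

    def run(self, E: EvidenceSet) -> List[MotifResult]:
        values = self._aligned_values(E)
        scorer = self._make_scorer(values)
        by_motif: Dict[str, MotifResult] = {}
        for seed in enumerate_seeds(self.cfg):
            result = self.evolve(seed, scorer)
            if result is None:
                continue
            prev = by_motif.get(result.motif)
            if prev is None or result.score > prev.score:
                by_motif[result.motif] = result
        results = sorted(by_motif.values(), key=lambda r: (-r.score, r.motif))
        return results

    # -- fast no-evolution scoring (used by the permutation null) -----------

    def _build_seed_matrix(self):
        seeds = enumerate_seeds(self.cfg)
        flat: List[int] = []
        starts: List[int] = []
        sizes: List[int] = []
        kept: List[str] = []
        for s in seeds:
            pos = self._pos(s)
            n = pos.size
            if not size_constraint_ok(n, self.d, self.cfg):
                continue
            starts.append(len(flat))
            flat.extend(pos)
            sizes.append(n)
            kept.append(s)
        self._seed_matrix = (
            kept,
            np.asarray(flat, dtype=np.int64),
            np.asarray(starts, dtype=np.int64),
            np.asarray(sizes, dtype=np.float64),
        )

    def seed_scores(self, values: np.ndarray) -> Tuple[List[str], np.ndarray]:
        """Objective for every constraint-satisfying seed, vectorized."""
        if self._seed_matrix is None:
            self._build_seed_matrix()
        kept, flat, starts, sizes = self._seed_matrix
        if not kept:
            return [], np.empty(0)
        scorer = self._make_scorer(values)
        v = scorer.values
        sums = np.add.reduceat(v[flat], starts)
        if scorer.sd == 0.0:
            return kept, np.zeros(len(kept))
        denom = scorer.sd
        if scorer.fpc:
            denom = scorer.sd * np.sqrt((scorer.d - sizes) / (scorer.d - 1))
        scores = np.sqrt(sizes) * (sums / sizes - scorer.mean) / denom
        scores[sizes == scorer.d] = 0.0
        return kept, scores

    def top_score(self, values: np.ndarray) -> float:
        """Best achievable score for the given evidence vector.

        Runs the full greedy search when ``cfg.evolve``, otherwise scores
        the seed set only (the fast path).  Returns 0.0 when no motif
        satisfies the size constraint.
        """
        if self.cfg.evolve:
            scorer = self._make_scorer(values)
            best = 0.0
            found = False
            for seed in enumerate_seeds(self.cfg):
                r = self.evolve(seed, scorer)
                if r is not None and (not found or r.score > best):
                    best, found = r.score, True
            return best if found else 0.0
        kept, scores = self.seed_scores(values)
        return float(scores.max()) if len(kept) else 0.0


def greedy_evolve(
    seed: str, idx: SuffixIndex, E: EvidenceSet, cfg: SearchConfig
) -> Optional[MotifResult]:
    """Evolve one seed to a local optimum; None if the seed violates the
    set-size constraint."""
    engine = MotifSearch(idx.regions, cfg, index=idx)
    scorer = engine._make_scorer(engine._aligned_values(E))
    return engine.evolve(seed, scorer)


def run_search(
    regions: Sequence[Region], E: EvidenceSet, cfg: SearchConfig
) -> List[MotifResult]:
    """Evolve every seed and return distinct results sorted by score."""
    return MotifSearch(regions, cfg).run(E)


# ---------------------------------------------------------------------------
# Canonical miRNA seed-match baseline


def mirna_seed_motifs(mirna: str) -> List[str]:
    """DNA complements of miRNA positions 2-7, 1-7, 2-8 and 1-8 (5'->3').

    These are the canonical seed-match sites expected on the forward strand
    of target 3' UTRs; lengths are 6, 7, 7 and 8.
    """
    s = mirna.upper().replace("U", "T")
    if len(s) < 8:
        raise ValueError(f"miRNA must be at least 8 nt, got {len(s)}")
    if not set(s) <= set("ACGT"):
        raise ValueError(f"invalid miRNA sequence {mirna!r}")
    windows = [s[1:7], s[0:7], s[1:8], s[0:8]]
    return [mt.reverse_complement(w) for w in windows]


def mirna_seed_scores(
    mirna: str, regions: Sequence[Region], E: EvidenceSet, *, engine: MotifSearch = None
) -> Dict[str, float]:
    """Objective score of each canonical seed-match motif (RNA mode).

    The size constraint is not applied: the baseline is a fixed comparison
    point, not a search.  Use ``max(scores.values())`` as the baseline.
    """
    if engine is None:
        cfg = SearchConfig(mode="rna", min_set_size=1, max_set_fraction=1.0)
        engine = MotifSearch(regions, cfg)
    scorer = engine._make_scorer(engine._aligned_values(E))
    scores: Dict[str, float] = {}
    for m in mirna_seed_motifs(mirna):
        pos = engine.index.region_indices_containing(m, "rna")
        scores[m] = scorer.score(pos) if pos else 0.0
    return scores
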