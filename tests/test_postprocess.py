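import itertools
import math

import numpy as np
import pytest

from motifrank import postprocess as pp
from motifrank.index import Region, build_index
from motifrank.search import MotifResult


def _result(motif, score, positive, pssm=None):
    return MotifResult(
        motif=motif, score=score, positive_set=frozenset(positive), seed=motif[:5],
        steps=0, pssm=pssm,
    )


def _uniform_pssm(width):
    return pp.Pssm(np.full((width, 4), 0.25))


class TestPssmConstruction:
    def test_identical_words_give_unit_columns(self):
        idx = build_index([Region("a", "TTACGTATT"), Region("b", "GGACGTAGG")])
        res = _result("ACGTA", 1.0, {"a", "b"})
        pssm = pp.pssm_from_occurrences(res, idx, mode="rna")
        expected = pp.Pssm.from_consensus("ACGTA")
        assert np.allclose(pssm.matrix, expected.matrix)
        assert pssm.n_sites == 2

    def test_degenerate_position_counts(self):
        # WCGTA: three regions start with A, one with T.
        seqs = ["ACGTA", "ACGTA", "ACGTA", "TCGTA"]
        idx = build_index([Region(f"r{i}", s) for i, s in enumerate(seqs)])
        res = _result("WCGTA", 1.0, {f"r{i}" for i in range(4)})
        pssm = pp.pssm_from_occurrences(res, idx, mode="rna")
        assert pssm.matrix[0].tolist() == [0.75, 0.0, 0.0, 0.25]

    def test_reverse_strand_occurrences_flipped_to_motif_frame(self):
        # TACGT is the reverse complement of ACGTA; counts must align.
        idx = build_index([Region("fwd", "GGACGTAGG"), Region("rev", "GGTACGTGG")])
        res = _result("ACGTA", 1.0, {"fwd", "rev"})
        pssm = pp.pssm_from_occurrences(res, idx, mode="dna")
        assert np.allclose(pssm.matrix, pp.Pssm.from_consensus("ACGTA").matrix)

    def test_columns_sum_to_one(self, small_engine, small_results):
        for r in small_results[:10]:
            pssm = pp.pssm_from_occurrences(r, small_engine.index)
            assert np.allclose(pssm.matrix.sum(axis=1), 1.0)

    def test_empty_positive_set_rejected(self):
        idx = build_index([Region("a", "ACGTACGT")])
        with pytest.raises(ValueError, match="empty"):
            pp.pssm_from_occurrences(_result("ACGTA", 1.0, set()), idx)


class TestHarbisonDistance:
    def test_identical_is_zero(self):
        p = _uniform_pssm(6)
        assert pp.harbison_distance(p, p) == 0.0

    def test_opposite_unit_columns_is_one(self):
        a = pp.Pssm.from_consensus("AAAAAA")
        t = pp.Pssm.from_consensus("TTTTTT")
        assert pp.harbison_distance(a, t) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        for _ in range(100):
            w = int(rng.integers(5, 9))
            a = rng.dirichlet(np.ones(4), size=w)
            b = rng.dirichlet(np.ones(4), size=w)
            p, q = pp.Pssm(a), pp.Pssm(b)
            assert pp.harbison_distance(p, q) == pytest.approx(pp.harbison_distance(q, p))

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            pp.harbison_distance(_uniform_pssm(5), _uniform_pssm(6))


class TestHarbisonSimilarity:
    def test_self_similarity_is_one(self):
        p = pp.Pssm.from_consensus("ACGTAC")
        assert pp.harbison_similarity(p, p) == pytest.approx(1.0)

    def test_width5_pair_uses_full_overlap_only(self):
        a = pp.Pssm.from_consensus("ACGTA")
        b = pp.Pssm.from_consensus("CGTAC")
        sim, shift, orient = pp.harbison_similarity(a, b, return_alignment=True)
        assert shift == 0  # only the zero-shift alignment reaches 5 columns
        assert sim == pytest.approx(1.0 - pp.harbison_distance(a, b))

    def test_shifted_submotif_found(self):
        long = pp.Pssm.from_consensus("AATGACTCAGG")
        short = pp.Pssm.from_consensus("TGACTCA")
        assert pp.harbison_similarity(long, short, mode="rna") == pytest.approx(1.0)

    def test_reverse_orientation_found_in_dna_mode(self):
        p = pp.Pssm.from_consensus("TGACTC")
        q = pp.Pssm.from_consensus("GAGTCA")  # reverse complement
        assert pp.harbison_similarity(p, q, mode="dna") == pytest.approx(1.0)
        assert pp.harbison_similarity(p, q, mode="rna") < 1.0

    def test_at_least_full_overlap_similarity(self, rng):
        for _ in range(30):
            w = int(rng.integers(6, 9))
            p = pp.Pssm(rng.dirichlet(np.ones(4), size=w))
            q = pp.Pssm(rng.dirichlet(np.ones(4), size=w))
            assert pp.harbison_similarity(p, q) >= 1.0 - pp.harbison_distance(p, q) - 1e-12

    def test_symmetry_including_orientations(self, rng):
        for _ in range(30):
            wp, wq = int(rng.integers(5, 10)), int(rng.integers(5, 10))
            p = pp.Pssm(rng.dirichlet(np.ones(4), size=wp))
            q = pp.Pssm(rng.dirichlet(np.ones(4), size=wq))
            assert pp.harbison_similarity(p, q) == pytest.approx(pp.harbison_similarity(q, p))


class TestCooccurrence:
    def test_zero_cooccurrence_is_one(self):
        assert pp.cooccurrence_pvalue({"a"}, {"b"}, set(), 10) == 1.0

    def test_perfect_overlap_example(self):
        pos = {f"r{i}" for i in range(5)}
        p = pp.cooccurrence_pvalue(pos, pos, pos, 10)
        assert p == pytest.approx(1 / math.comb(10, 5))

    def test_monotone_in_cooccurrence_count(self):
        pos1 = {f"r{i}" for i in range(6)}
        pos2 = {f"r{i}" for i in range(3, 9)}
        shared = sorted(pos1 & pos2)
        pvals = [
            pp.cooccurrence_pvalue(pos1, pos2, set(shared[:c]), 20)
            for c in range(len(shared) + 1)
        ]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))

    def test_agrees_with_exhaustive_enumeration(self):
        # Brute-force oracle: fix the first set, enumerate every second set.
        d = 10
        universe = list(range(d))
        for n1, n2, c in [(4, 5, 2), (3, 3, 1), (5, 5, 5), (6, 2, 2)]:
            pos1 = set(universe[:n1])
            count = sum(
                1
                for comb in itertools.combinations(universe, n2)
                if len(pos1 & set(comb)) >= c
            )
            expected = count / math.comb(d, n2)
            ids1 = {f"r{i}" for i in pos1}
            ids2 = {f"r{i}" for i in range(n2)}  # only sizes matter for the p-value
            co = set(sorted(ids1 & ids2)[:c])
            if len(co) < c:
                continue
            assert pp.cooccurrence_pvalue(ids1, ids2, co, d) == pytest.approx(expected)

    def test_inconsistent_sets_rejected(self):
        with pytest.raises(ValueError):
            pp.cooccurrence_pvalue({"a"}, {"b"}, {"c"}, 10)

    def test_cooccurring_regions_respects_tau(self):
        occ1 = {"r1": [(10, "+")], "r2": [(10, "+")]}
        occ2 = {"r1": [(40, "+")], "r2": [(200, "+")]}
        assert pp.cooccurring_regions(occ1, occ2, tau=50) == {"r1"}
        assert pp.cooccurring_regions(occ1, occ2, tau=5) == set()


class TestClustering:
    def _indexed_results(self):
        # Two near-identical AP-1-like motifs co-occurring at distance 0-2,
        # plus one unrelated polyA motif in different regions.
        seqs = {}
        for i in range(12):
            seqs[f"jun{i}"] = "GG" + "TGACTCA" + "TT" + "C" * 20
        for i in range(12):
            seqs[f"pa{i}"] = "C" * 12 + "AAAAAAA" + "C" * 12
        regions = [Region(k, v) for k, v in seqs.items()]
        idx = build_index(regions)
        jun_ids = {f"jun{i}" for i in range(12)}
        pa_ids = {f"pa{i}" for i in range(12)}
        r1 = _result("TGACTCA", 10.0, jun_ids)
        r2 = _result("TGACTCW", 8.0, jun_ids)
        r3 = _result("AAAAAAA", 6.0, pa_ids)
        return idx, [r1, r2, r3]

    def test_similar_motifs_merge_under_top_representative(self):
        idx, results = self._indexed_results()
        clusters = pp.cluster_motifs(results, idx)
        assert len(clusters) == 2
        assert clusters[0].representative.motif == "TGACTCA"
        assert {m.motif for m in clusters[0].members} == {"TGACTCA", "TGACTCW"}
        assert clusters[1].representative.motif == "AAAAAAA"

    def test_clusters_partition_input(self):
        idx, results = self._indexed_results()
        clusters = pp.cluster_motifs(results, idx)
        motifs = [m.motif for c in clusters for m in c.members]
        assert sorted(motifs) == sorted(r.motif for r in results)

    def test_representative_outranks_members(self):
        idx, results = self._indexed_results()
        for c in pp.cluster_motifs(results, idx):
            assert all(c.representative.score >= m.score for m in c.members)

    def test_similarity_without_cooccurrence_does_not_merge(self):
        # Same consensus in disjoint region sets: PSSMs identical but the
        # motifs never co-occur, so they stay in separate clusters.
        seqs = {f"a{i}": "GG" + "TGACTCA" + "C" * 20 for i in range(10)}
        seqs.update({f"b{i}": "TT" + "TGACTGA" + "G" * 20 for i in range(10)})
        regions = [Region(k, v) for k, v in seqs.items()]
        idx = build_index(regions)
        r1 = _result("TGACTCA", 9.0, {f"a{i}" for i in range(10)})
        r2 = _result("TGACTGA", 7.0, {f"b{i}" for i in range(10)})
        clusters = pp.cluster_motifs([r1, r2], idx)
        assert len(clusters) == 2

    def test_low_similarity_does_not_merge_despite_cooccurrence(self):
        idx, results = self._indexed_results()
        r1, _, r3 = results
        r1.pssm = pp.pssm_from_occurrences(r1, idx)
        r3.pssm = pp.pssm_from_occurrences(r3, idx)
        assert not pp.motifs_similar(r1, r3, idx)

    def test_singleton_cluster_keeps_representative_pssm(self):
        idx, results = self._indexed_results()
        clusters = pp.cluster_motifs([results[2]], idx)
        assert len(clusters) == 1
        assert np.allclose(clusters[0].pssm.matrix, results[2].pssm.matrix)

    def test_unsorted_input_rejected(self):
        idx, results = self._indexed_results()
        with pytest.raises(ValueError, match="sorted"):
            pp.cluster_motifs(list(reversed(results)), idx)

    def test_reclustering_representatives_gives_singletons(self):
        idx, results = self._indexed_results()
        clusters = pp.cluster_motifs(results, idx)
        reps = [c.representative for c in clusters]
        again = pp.cluster_motifs(reps, idx)
        assert all(len(c.members) == 1 for c in again)


class TestClusterPssm:
    def test_equal_scores_equal_widths_average(self):
        a = pp.Pssm.from_consensus("ACGTAA")
        b = pp.Pssm.from_consensus("ACGTCC")
        r1 = _result("ACGTAA", 5.0, {"x"}, pssm=a)
        r2 = _result("ACGTCC", 5.0, {"x"}, pssm=b)
        cluster = pp.MotifCluster(representative=r1, members=[r1, r2])
        avg = pp.cluster_pssm(cluster, mode="rna")
        assert np.allclose(avg.matrix, (a.matrix + b.matrix) / 2)

    def test_score_weighting(self):
        a = pp.Pssm.from_consensus("ACGTAA")
        b = pp.Pssm.from_consensus("ACGTCC")
        r1 = _result("ACGTAA", 3.0, {"x"}, pssm=a)
        r2 = _result("ACGTCC", 1.0, {"x"}, pssm=b)
        cluster = pp.MotifCluster(representative=r1, members=[r1, r2])
        avg = pp.cluster_pssm(cluster, mode="rna")
        assert np.allclose(avg.matrix, 0.75 * a.matrix + 0.25 * b.matrix)

    def test_columns_sum_to_one(self, rng):
        mats = [pp.Pssm(rng.dirichlet(np.ones(4), size=7)) for _ in range(3)]
        members = [_result(f"ACGTAC{i}"[:7], 5.0 - i, {"x"}, pssm=m) for i, m in enumerate(mats)]
        cluster = pp.MotifCluster(representative=members[0], members=members)
        avg = pp.cluster_pssm(cluster)
        assert np.allclose(avg.matrix.sum(axis=1), 1.0)

    def test_negative_score_floored_with_warning(self):
        a = pp.Pssm.from_consensus("ACGTAA")
        b = pp.Pssm.from_consensus("TTTTTT")
        r1 = _result("ACGTAA", 5.0, {"x"}, pssm=a)
        r2 = _result("TTTTTT", -2.0, {"x"}, pssm=b)
        cluster = pp.MotifCluster(representative=r1, members=[r1, r2])
        with pytest.warns(UserWarning, match="floored"):
            avg = pp.cluster_pssm(cluster, mode="rna")
        assert np.allclose(avg.matrix, a.matrix)
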