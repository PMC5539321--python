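import numpy as np
import pytest

from phagepan import homology as ho

AAS = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n):
    return "".join(rng.choice(list(AAS), size=n))


# ------------------------------------------------------------- DP oracle

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def _score(a, b):
    if a == "X" or b == "X":
        return 0.0
    return float(_B62[a, b])


def sw_oracle(a, b, open_=11.0, ext=1.0):
    """Textbook Gotoh local alignment; first gap position costs `open_`,
    each further position `ext` (matches the production convention)."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -np.inf)  # gap in b (vertical)
    F = np.full((n + 1, m + 1), -np.inf)  # gap in a (horizontal)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i - 1, j] - open_, E[i - 1, j] - ext)
            F[i, j] = max(H[i, j - 1] - open_, F[i, j - 1] - ext)
            H[i, j] = max(
                0.0,
                H[i - 1, j - 1] + _score(a[i - 1], b[j - 1]),
                E[i, j],
                F[i, j],
            )
            best = max(best, H[i, j])
    return best


class TestAlignPair:
    def test_identical(self):
        h = ho.align_pair("MKVLLATTTTGG", "MKVLLATTTTGG")
        assert h.identity == 1.0
        assert h.coverage_q == 1.0 and h.coverage_s == 1.0

    def test_self_score_is_maximal(self):
        rng = np.random.default_rng(3)
        a = random_protein(rng, 50)
        self_score = ho.align_pair(a, a).score
        assert ho.align_pair(a, a[::-1]).score <= self_score

    def test_single_substitution_identity(self):
        rng = np.random.default_rng(4)
        a = random_protein(rng, 100)
        b = a[:50] + ("A" if a[50] != "A" else "C") + a[51:]
        h = ho.align_pair(a, b)
        assert h.identity == pytest.approx(0.99)

    def test_empty_rejected(self):
        with pytest.raises(ho.AlignmentError):
            ho.align_pair("", "MKV")

    def test_matches_independent_dp_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = random_protein(rng, int(rng.integers(3, 13)))
            b = random_protein(rng, int(rng.integers(3, 13)))
            expected = sw_oracle(a, b)
            got = ho.align_pair(a, b).score
            assert got == pytest.approx(expected), (a, b)


class _FakeGenome:
    def __init__(self, gid, prots):
        self.id = gid
        self._p = prots

    def proteins(self):
        return dict(self._p)


class TestAllVsAll:
    def test_shared_protein_two_reciprocal_hits(self):
        p = "MKVLLATTTTGGWYHH"
        a = _FakeGenome("A", {"a1": p})
        b = _FakeGenome("B", {"b1": p})
        hits = ho.all_vs_all([a, b])
        assert len(hits) == 2
        assert {(h.query, h.subject) for h in hits} == {("A:a1", "B:b1"), ("B:b1", "A:a1")}

    def test_unrelated_proteomes_no_hits(self):
        rng = np.random.default_rng(12)
        a = _FakeGenome("A", {f"a{i}": random_protein(rng, 80) for i in range(5)})
        b = _FakeGenome("B", {f"b{i}": random_protein(rng, 80) for i in range(5)})
        assert ho.all_vs_all([a, b]) == []

    def test_needs_two_genomes(self):
        with pytest.raises(ValueError):
            ho.all_vs_all([_FakeGenome("A", {"a": "MKV"})])

    def test_planted_clusters_are_hit_components(self, small_cohort, small_genomes, small_clusters):
        import networkx as nx

        _, _, truth = small_cohort
        hits, *_ = small_clusters
        g = nx.Graph()
        for genome in small_genomes:
            for locus in genome.proteins():
                g.add_node(f"{genome.id}:{locus}")
        for h in hits:
            g.add_edge(h.query, h.subject)
        comps = {frozenset(c) for c in nx.connected_components(g)}
        planted = {frozenset(m) for m in truth.cluster_members.values()}
        assert comps == planted


class TestBbh:
    def test_single_reciprocal_pair(self):
        hits = [
            ho.AlignmentHit("A:x", "B:y", 50, 1.0, 1.0, 1.0, 1e-20),
            ho.AlignmentHit("B:y", "A:x", 50, 1.0, 1.0, 1.0, 1e-20),
        ]
        assert ho.bbh_graph(hits) == {frozenset(("A:x", "B:y"))}

    def test_non_reciprocal_best_is_no_edge(self):
        hits = [
            ho.AlignmentHit("A:x", "B:y", 50, 1.0, 1.0, 1.0, 1e-20),
            ho.AlignmentHit("B:y", "A:x", 50, 1.0, 1.0, 1.0, 1e-20),
            ho.AlignmentHit("B:y", "A:z", 80, 1.0, 1.0, 1.0, 1e-30),
            ho.AlignmentHit("A:z", "B:y", 80, 1.0, 1.0, 1.0, 1e-30),
        ]
        edges = ho.bbh_graph(hits)
        assert frozenset(("A:x", "B:y")) not in edges
        assert frozenset(("A:z", "B:y")) in edges

    def test_planted_orthologs(self, small_cohort, small_clusters):
        _, _, truth = small_cohort
        hits, *_ = small_clusters
        edges = ho.bbh_graph(hits)
        # every within-cluster cross-genome pair must be a BBH edge
        for members in truth.cluster_members.values():
            if len(members) < 2:
                continue
            for i, x in enumerate(members):
                for y in members[i + 1 :]:
                    assert frozenset((x, y)) in edges


class TestCogTriangles:
    def test_three_genomes_one_cluster(self):
        edges = {
            frozenset(("A:x", "B:y")),
            frozenset(("A:x", "C:z")),
            frozenset(("B:y", "C:z")),
        }
        cs = ho.cog_triangles(edges, ["A:x", "B:y", "C:z"])
        assert cs.member_sets() == {frozenset({("A", "x"), ("B", "y"), ("C", "z")})}

    def test_two_genomes_pairs_only(self):
        edges = {frozenset(("A:x", "B:y"))}
        cs = ho.cog_triangles(edges, ["A:x", "B:y", "A:w"])
        assert cs.member_sets() == {
            frozenset({("A", "x"), ("B", "y")}),
            frozenset({("A", "w")}),
        }

    def test_planted_core_cluster_merged(self, small_cohort, small_clusters):
        _, _, truth = small_cohort
        _, cog, _, _ = small_clusters
        got = {
            frozenset(f"{g}:{l}" for g, l in members)
            for members in cog.clusters.values()
        }
        planted = {frozenset(m) for m in truth.cluster_members.values()}
        assert got == planted


class TestMcl:
    def _hits_from_edges(self, edges, score=100.0):
        out = []
        for a, b in edges:
            out.append(ho.AlignmentHit(a, b, score, 1.0, 1.0, 1.0, 1e-30))
            out.append(ho.AlignmentHit(b, a, score, 1.0, 1.0, 1.0, 1e-30))
        return out

    def test_two_cliques(self):
        clique1 = [("A:1", "B:1"), ("A:1", "C:1"), ("B:1", "C:1")]
        clique2 = [("A:2", "B:2")]
        hits = self._hits_from_edges(clique1 + clique2)
        loci = ["A:1", "B:1", "C:1", "A:2", "B:2"]
        cs = ho.mcl_cluster(hits, loci)
        assert cs.member_sets() == {
            frozenset({("A", "1"), ("B", "1"), ("C", "1")}),
            frozenset({("A", "2"), ("B", "2")}),
        }

    def test_singleton(self):
        cs = ho.mcl_cluster([], ["A:only"])
        assert cs.member_sets() == {frozenset({("A", "only")})}

    def test_inflation_validation(self):
        with pytest.raises(ValueError):
            ho.mcl_cluster([], ["A:x"], inflation=1.0)

    def test_planted_cohort_ari_one(self, small_cohort, small_clusters):
        from sklearn.metrics import adjusted_rand_score

        _, _, truth = small_cohort
        _, _, mcl, _ = small_clusters
        member_to_planted = {}
        for k, members in enumerate(truth.cluster_members.values()):
            for m in members:
                member_to_planted[m] = k
        member_to_got = {}
        for k, members in enumerate(mcl.clusters.values()):
            for g, l in members:
                member_to_got[f"{g}:{l}"] = k
        keys = sorted(member_to_planted)
        ari = adjusted_rand_score(
            [member_to_planted[k] for k in keys], [member_to_got[k] for k in keys]
        )
        assert ari == 1.0

    def test_high_inflation_singletons_except_duplicates(self):
        # chain a-b-c (cross-scores below self-scores) plus one exact
        # duplicate pair d1/d2 (cross == self): inflation 10 shatters the
        # chain but keeps the duplicates together
        hits = self._hits_from_edges([("A:a", "B:b"), ("B:b", "C:c")], score=10.0)
        hits += self._hits_from_edges([("A:d1", "B:d2")], score=20.0)
        selfs = {"A:a": 20.0, "B:b": 20.0, "C:c": 20.0, "A:d1": 20.0, "B:d2": 20.0}
        cs = ho.mcl_cluster(
            hits, list(selfs), inflation=10.0, self_scores=selfs
        )
        assert cs.member_sets() == {
            frozenset({("A", "a")}),
            frozenset({("B", "b")}),
            frozenset({("C", "c")}),
            frozenset({("A", "d1"), ("B", "d2")}),
        }


class TestIntersect:
    def test_identical(self, small_clusters):
        _, cog, _, _ = small_clusters
        assert ho.intersect_clusterings(cog, cog).member_sets() == cog.member_sets()

    def test_split_cluster_absent(self):
        a = ho.GeneClusterSet({"1": frozenset({("A", "x"), ("B", "y")})}, "cog")
        b = ho.GeneClusterSet(
            {"1": frozenset({("A", "x")}), "2": frozenset({("B", "y")})}, "mcl"
        )
        assert ho.intersect_clusterings(a, b).member_sets() == set()

    def test_matches_brute_force_set_intersection(self):
        rng = np.random.default_rng(33)
        loci = [("G", f"l{i}") for i in range(10)]
        for _ in range(20):
            la = rng.integers(0, 4, size=10)
            lb = rng.integers(0, 4, size=10)
            fam_a = {
                f"a{k}": frozenset(l for l, lab in zip(loci, la) if lab == k)
                for k in range(4)
                if (la == k).any()
            }
            fam_b = {
                f"b{k}": frozenset(l for l, lab in zip(loci, lb) if lab == k)
                for k in range(4)
                if (lb == k).any()
            }
            a = ho.GeneClusterSet(fam_a, "cog")
            b = ho.GeneClusterSet(fam_b, "mcl")
            got = ho.intersect_clusterings(a, b).member_sets()
            oracle = set(fam_a.values()) & set(fam_b.values())
            assert got == oracle
            assert got <= a.member_sets() and got <= b.member_sets()
            assert len(got) <= min(len(a), len(b))


class TestIdentityMatrix:
    def test_identical_proteomes(self):
        p = {"x": "MKVLLATTTTGGWYHH", "y": "WWHHYKLMNPQRSTVA"}
        a, b = _FakeGenome("A", p), _FakeGenome("B", p)
        hits = ho.all_vs_all([a, b])
        m = ho.identity_matrix([a, b], hits)
        assert m.loc["A", "B"] == pytest.approx(1.0)
        assert m.loc["A", "A"] == 1.0

    def test_no_hits_zero(self):
        a = _FakeGenome("A", {"x": "MKVLLATTTTGG"})
        b = _FakeGenome("B", {"y": "WWHHYYYYPPPP"})
        m = ho.identity_matrix([a, b], [])
        assert m.loc["A", "B"] == 0.0

    def test_within_group_exceeds_between(self, small_cohort, small_genomes, small_clusters):
        _, _, truth = small_cohort
        hits, *_ = small_clusters
        m = ho.identity_matrix(small_genomes, hits)
        ids = list(m.index)
        within, between = [], []
        for i, x in enumerate(ids):
            for y in ids[i + 1 :]:
                (within if truth.genome_group[x] == truth.genome_group[y] else between).append(
                    m.loc[x, y]
                )
        assert min(within) > max(between)


class TestScreenReferenceSet:
    def test_verbatim_reference_flagged(self):
        rng = np.random.default_rng(9)
        ref = random_protein(rng, 120)
        g = _FakeGenome("A", {"int1": ref, "other": random_protein(rng, 120)})
        res = ho.screen_reference_set(g, {"ref_int": ref})
        assert ("int1", "ref_int", "present") in res

    def test_random_proteome_unflagged(self):
        rng = np.random.default_rng(10)
        g = _FakeGenome("A", {f"p{i}": random_protein(rng, 100) for i in range(5)})
        refs = {f"r{i}": random_protein(rng, 100) for i in range(3)}
        assert ho.screen_reference_set(g, refs) == []

    def test_truncated_copy_low_confidence(self):
        rng = np.random.default_rng(11)
        ref = random_protein(rng, 200)
        g = _FakeGenome("A", {"t": ref[:90]})  # 45% of the reference
        res = ho.screen_reference_set(g, {"ref": ref})
        assert res == [("t", "ref", "low_confidence")]

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            ho.screen_reference_set(_FakeGenome("A", {"x": "MKV"}), {})
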