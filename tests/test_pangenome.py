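import itertools

import numpy as np
import pytest

from stutzpan import pangenome, synthetic
from stutzpan.genome_io import Proteome, SequenceRecord
from stutzpan.pangenome import (OrthoCluster, ProteinHit, SimilarityThresholds,
                                all_vs_all_hits, bdbh_cluster,
                                cog_triangles_cluster, compartmentalize,
                                consensus_core, markov_cluster, occupancy_matrix,
                                omcl_cluster, pan_genes, pangenome_intersection,
                                pathway_profile)

AMINO = list("ACDEFGHIKLMNPQRSTVWY")


def _protein(rng, length=200):
    return "".join(rng.choice(AMINO, size=length))


def _mutate(rng, seq, n_sites):
    arr = list(seq)
    sites = rng.choice(len(seq), size=n_sites, replace=False)
    for p in sites:
        arr[p] = rng.choice([a for a in AMINO if a != arr[p]])
    return "".join(arr)


class TestAllVsAllFilters:
    def test_identical_proteins_hit_at_full_identity_and_coverage(self, rng):
        seq = _protein(rng)
        a = Proteome("g1", [SequenceRecord("p1", seq, kind="protein")])
        b = Proteome("g2", [SequenceRecord("p2", seq, kind="protein")])
        hits = all_vs_all_hits([a, b])
        assert len(hits) == 2  # both directions
        assert hits[0].identity_pct == 100.0
        assert hits[0].coverage_of_longest == 1.0

    def test_low_coverage_of_longest_is_rejected(self, rng):
        # 75%-identical over only half of the longer sequence: no hit
        short = _protein(rng, 100)
        long = _mutate(rng, short, 25) + _protein(rng, 100)
        a = Proteome("g1", [SequenceRecord("p1", short, kind="protein")])
        b = Proteome("g2", [SequenceRecord("p2", long, kind="protein")])
        assert all_vs_all_hits([a, b]) == []

    def test_low_identity_is_rejected(self, rng):
        seq = _protein(rng)
        diverged = _mutate(rng, seq, 70)  # ~65% identity, full length
        a = Proteome("g1", [SequenceRecord("p1", seq, kind="protein")])
        b = Proteome("g2", [SequenceRecord("p2", diverged, kind="protein")])
        assert all_vs_all_hits([a, b]) == []


def _hit(qg, qp, sg, sp, score, identity=90.0):
    return ProteinHit((qg, qp), (sg, sp), identity, 1.0, score)


def _sym_hits(edges):
    """edges: ((genome, protein), (genome, protein), score) triples."""
    hits = []
    for a, b, score in edges:
        hits.append(ProteinHit(a, b, 90.0, 1.0, score))
        hits.append(ProteinHit(b, a, 90.0, 1.0, score))
    return hits


class TestBdbh:
    def test_clonal_proteomes_pair_up(self, rng):
        seqs = [_protein(rng) for _ in range(4)]
        a = Proteome("ref", [SequenceRecord(f"a{i}", s, kind="protein")
                             for i, s in enumerate(seqs)])
        b = Proteome("oth", [SequenceRecord(f"b{i}", s, kind="protein")
                             for i, s in enumerate(seqs)])
        hits = all_vs_all_hits([a, b])
        clusters = bdbh_cluster(hits, [a, b], "ref")
        assert len(clusters) == 4
        assert all(len(c.members) == 2 for c in clusters)
        for c in clusters:
            ids = dict(c.members)
            assert ids["ref"][1:] == ids["oth"][1:]  # a0 pairs b0 etc.

    def test_score_tie_broken_by_lower_protein_id(self):
        hits = _sym_hits([
            (("ref", "r1"), ("oth", "z"), 50.0),
            (("ref", "r1"), ("oth", "a"), 50.0),
        ])
        ref = Proteome("ref", [SequenceRecord("r1", "M" * 50, kind="protein")])
        oth = Proteome("oth", [SequenceRecord("a", "M" * 50, kind="protein"),
                               SequenceRecord("z", "M" * 50, kind="protein")])
        clusters = bdbh_cluster(hits, [ref, oth], "ref")
        assert clusters[0].member_set == {("ref", "r1"), ("oth", "a")}

    def test_missing_reference_errors(self):
        ref = Proteome("g1", [SequenceRecord("p", "M" * 50, kind="protein")])
        with pytest.raises(ValueError):
            bdbh_cluster([], [ref], "nope")


def _brute_force_triangles(hits):
    """Independent oracle: enumerate all 3-subsets of proteins and test the
    pairwise-BBH triangle condition directly."""
    best = {}
    for h in hits:
        if h.query_id[0] == h.subject_id[0]:
            continue
        key = (h.query_id, h.subject_id[0])
        cur = best.get(key)
        # same declared tie rule: score, then identity, then smaller id
        rank = (h.score, h.identity_pct)
        if cur is None or rank > cur[0] or (rank == cur[0]
                                            and h.subject_id[1] < cur[1][1]):
            best[key] = (rank, h.subject_id)
    bbh = set()
    for (q, genome), (_, s) in best.items():
        back = best.get((s, q[0]))
        if back and back[1] == q:
            bbh.add(frozenset((q, s)))
    nodes = sorted({m for e in bbh for m in e})
    triangles = []
    for trio in itertools.combinations(nodes, 3):
        if len({m[0] for m in trio}) != 3:
            continue
        if all(frozenset(pair) in bbh for pair in itertools.combinations(trio, 2)):
            triangles.append(frozenset(trio))
    return triangles


class TestCogTriangles:
    def test_single_triangle(self):
        hits = _sym_hits([
            (("g1", "a"), ("g2", "b"), 50.0),
            (("g1", "a"), ("g3", "c"), 50.0),
            (("g2", "b"), ("g3", "c"), 50.0),
        ])
        clusters = cog_triangles_cluster(hits)
        assert len(clusters) == 1
        assert clusters[0].member_set == {("g1", "a"), ("g2", "b"), ("g3", "c")}

    def test_triangles_sharing_edge_merge(self):
        hits = _sym_hits([
            (("g1", "a"), ("g2", "b"), 50.0),
            (("g1", "a"), ("g3", "c"), 50.0),
            (("g2", "b"), ("g3", "c"), 50.0),
            (("g1", "a"), ("g4", "d"), 50.0),
            (("g2", "b"), ("g4", "d"), 50.0),
        ])
        clusters = cog_triangles_cluster(hits)
        assert len(clusters) == 1
        assert len(clusters[0].members) == 4

    def test_no_closing_triangle_yields_no_cluster(self):
        # path g1-g2-g3 without the closing edge
        hits = _sym_hits([
            (("g1", "a"), ("g2", "b"), 50.0),
            (("g2", "b"), ("g3", "c"), 50.0),
        ])
        assert cog_triangles_cluster(hits) == []
        assert _brute_force_triangles(hits) == []

    def test_matches_brute_force_enumeration_on_random_graphs(self, rng):
        genomes = ["g1", "g2", "g3", "g4"]
        for _ in range(10):
            edges = []
            for ga, gb in itertools.combinations(genomes, 2):
                for i in range(2):
                    for j in range(2):
                        if rng.random() < 0.4:
                            edges.append(((ga, f"{ga}p{i}"), (gb, f"{gb}p{j}"),
                                          float(rng.integers(10, 100))))
            hits = _sym_hits(edges)
            triangles = _brute_force_triangles(hits)
            clustered = {m for c in cog_triangles_cluster(hits) for m in c.members}
            in_triangles = {m for t in triangles for m in t}
            assert clustered == in_triangles

    def test_fewer_than_three_genomes_errors(self):
        hits = _sym_hits([(("g1", "a"), ("g2", "b"), 50.0)])
        with pytest.raises(ValueError):
            cog_triangles_cluster(hits)


def _brute_force_mcl(nodes, edges, inflation, iterations=200):
    """Straightforward dense MCL re-implementation used as an oracle."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for e, w in edges.items():
        a, b = tuple(e)
        M[idx[a], idx[b]] = M[idx[b], idx[a]] = w
    loops = M.max(axis=0)
    loops[loops == 0] = 1.0
    for i in range(n):
        M[i, i] = loops[i]
    M /= M.sum(axis=0)
    for _ in range(iterations):
        M = np.linalg.matrix_power(M, 2)
        M = M ** inflation
        M[M < 1e-5] = 0
        s = M.sum(axis=0)
        s[s == 0] = 1
        M /= s
    support = (M + M.T) > 0
    comps, seen = [], set()
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            comp.add(nodes[v])
            stack.extend(int(x) for x in np.nonzero(support[v])[0])
        comps.append(frozenset(comp))
    return set(comps)


class TestMarkovClustering:
    def test_two_cliques_split(self):
        nodes = list("abcdef")
        edges = {}
        for clique in ("abc", "def"):
            for x, y in itertools.combinations(clique, 2):
                edges[frozenset((x, y))] = 1.0
        parts = markov_cluster(nodes, edges)
        assert {frozenset(p) for p in parts} == {frozenset("abc"), frozenset("def")}

    def test_path_graph_matches_brute_force(self):
        nodes = list("abcde")
        edges = {frozenset(p): 1.0 for p in zip(nodes, nodes[1:])}
        got = {frozenset(p) for p in markov_cluster(nodes, edges, inflation=1.5)}
        want = _brute_force_mcl(nodes, edges, inflation=1.5)
        assert got == want

    def test_higher_inflation_never_coarsens(self, rng):
        for _ in range(10):
            nodes = [f"n{i}" for i in range(8)]
            edges = {}
            for a, b in itertools.combinations(nodes, 2):
                if rng.random() < 0.35:
                    edges[frozenset((a, b))] = float(rng.uniform(0.5, 2.0))
            fine = markov_cluster(nodes, edges, inflation=5.0)
            coarse = markov_cluster(nodes, edges, inflation=1.2)
            assert len(fine) >= len(coarse)

    def test_deterministic(self, rng):
        nodes = [f"n{i}" for i in range(10)]
        edges = {frozenset((a, b)): float(rng.uniform(1, 5))
                 for a, b in itertools.combinations(nodes, 2) if rng.random() < 0.3}
        first = [sorted(p) for p in markov_cluster(nodes, edges)]
        second = [sorted(p) for p in markov_cluster(nodes, edges)]
        assert first == second


class TestConsensusCore:
    def _cluster(self, tag, algo, members):
        return OrthoCluster(tag, tuple(sorted(members)), algo)

    def test_agreeing_single_copy_cluster_retained(self):
        members = [("g1", "a"), ("g2", "b")]
        core = consensus_core(
            [self._cluster("x", "BDBH", members)],
            [self._cluster("y", "COGT", members)],
            [self._cluster("z", "OMCL", members)],
            ["g1", "g2"])
        assert len(core) == 1
        assert core[0].member_set == set(members)

    def test_multi_copy_cluster_excluded(self):
        members = [("g1", "a"), ("g1", "a2"), ("g2", "b")]
        core = consensus_core(
            [self._cluster("x", "BDBH", members)],
            [self._cluster("y", "COGT", members)],
            [self._cluster("z", "OMCL", members)],
            ["g1", "g2"])
        assert core == []

    def test_disagreement_excluded(self):
        m1 = [("g1", "a"), ("g2", "b")]
        m2 = [("g1", "a"), ("g2", "c")]
        core = consensus_core(
            [self._cluster("x", "BDBH", m1)],
            [self._cluster("y", "COGT", m2)],
            [self._cluster("z", "OMCL", m1)],
            ["g1", "g2"])
        assert core == []


def _cluster_in(genomes):
    key = "_".join(genomes)
    return OrthoCluster(f"c_{key}", tuple((g, f"p@{g}") for g in genomes), "consensus")


class TestCompartments:
    def test_core_soft_core_shell_cloud_labels(self):
        genomes = [f"g{i:03d}" for i in range(103)]
        clusters = [
            _cluster_in(genomes),            # all 103 -> core
            _cluster_in(genomes[:99]),       # 96.1% -> soft-core
            _cluster_in(genomes[:50]),       # -> shell
            _cluster_in(genomes[:2]),        # -> cloud
            _cluster_in(genomes[:1]),        # -> cloud
        ]
        matrix = compartmentalize(clusters, genomes)
        labels = [matrix.compartments[c.cluster_id] for c in clusters]
        assert labels == ["core", "soft-core", "shell", "cloud", "cloud"]

    def test_eleven_genome_core(self):
        genomes = [f"g{i}" for i in range(11)]
        matrix = compartmentalize([_cluster_in(genomes)], genomes)
        assert list(matrix.compartments.values()) == ["core"]

    def test_labels_partition_the_cluster_set(self, rng):
        genomes = [f"g{i}" for i in range(20)]
        clusters = []
        for k in range(50):
            size = int(rng.integers(1, 21))
            chosen = list(rng.choice(genomes, size=size, replace=False))
            clusters.append(OrthoCluster(
                f"c{k}", tuple((g, f"p{k}@{g}") for g in chosen), "consensus"))
        matrix = compartmentalize(clusters, genomes)
        assert sum(matrix.compartment_sizes().values()) == len(clusters)


class TestPanGenes:
    def _matrix(self):
        genomes = [f"in{i}" for i in range(3)] + [f"out{i}" for i in range(3)]
        clusters = [
            _cluster_in(genomes[:3]),        # in-group exclusive
            _cluster_in(genomes[:4]),        # leaks into one out-group genome
            _cluster_in(genomes),            # everywhere
            _cluster_in(genomes[:2]),        # not in all of the in-group
        ]
        return compartmentalize(clusters, genomes), genomes

    def test_exclusive_clusters_only(self):
        matrix, genomes = self._matrix()
        found = pan_genes(matrix, set(genomes[:3]), set(genomes[3:]))
        assert [c.cluster_id for c in found] == ["c_in0_in1_in2"]

    def test_invariant_under_genome_permutation(self, rng):
        matrix, genomes = self._matrix()
        order = list(rng.permutation(len(genomes)))
        permuted = compartmentalize([matrix.clusters[i] for i in
                                     rng.permutation(len(matrix.clusters))],
                                    [genomes[i] for i in order])
        a = {c.cluster_id for c in pan_genes(matrix, set(genomes[:3]), set(genomes[3:]))}
        b = {c.cluster_id for c in pan_genes(permuted, set(genomes[:3]), set(genomes[3:]))}
        assert a == b

    def test_overlapping_groups_rejected(self):
        matrix, genomes = self._matrix()
        with pytest.raises(ValueError):
            pan_genes(matrix, {genomes[0]}, {genomes[0]})


class TestPathwayProfile:
    def test_exact_seed_copies_complete_pathway(self, rng):
        seeds = [SequenceRecord(f"seed{i}", _protein(rng, 150), kind="protein")
                 for i in range(3)]
        genome = Proteome("g1", [SequenceRecord(f"p{i}", s.sequence, kind="protein")
                                 for i, s in enumerate(seeds)])
        profile = pathway_profile(seeds, [genome])
        assert profile["g1"].tolist() == [1, 1, 1, 1]  # last row: complete

    def test_low_identity_breaks_completeness(self, rng):
        seeds = [SequenceRecord("seed0", _protein(rng, 150), kind="protein"),
                 SequenceRecord("seed1", _protein(rng, 150), kind="protein")]
        genome = Proteome("g1", [
            SequenceRecord("p0", seeds[0].sequence, kind="protein"),
            SequenceRecord("p1", _protein(rng, 150), kind="protein"),  # unrelated
        ])
        profile = pathway_profile(seeds, [genome])
        assert profile.loc["seed0", "g1"] == 1
        assert profile.loc["seed1", "g1"] == 0
        assert profile.loc["_pathway_complete", "g1"] == 0


class TestGroundTruthRecovery:
    def test_all_algorithms_recover_separated_families(self):
        genomes = [f"g{i}" for i in range(5)]
        specs = synthetic.separated_family_design(10, genomes, within_identity=0.90)
        proteomes, truth = synthetic.simulate_proteomes(genomes, specs, seed=3)
        hits = all_vs_all_hits(proteomes)
        expected = {frozenset(map(tuple, fam))
                    for fam in truth.data["families"].values()}
        bdbh = bdbh_cluster(hits, proteomes, "g0")
        cogt = cog_triangles_cluster(hits)
        omcl = omcl_cluster(hits)
        for clustering in (bdbh, cogt, omcl):
            assert {c.member_set for c in clustering} == expected
        core = consensus_core(bdbh, cogt, omcl, genomes)
        assert {c.member_set for c in core} == expected  # all single-copy

    def test_intersection_pangenome(self):
        genomes = [f"g{i}" for i in range(4)]
        specs = synthetic.separated_family_design(6, genomes, within_identity=0.92)
        proteomes, truth = synthetic.simulate_proteomes(genomes, specs, seed=8)
        hits = all_vs_all_hits(proteomes)
        pan = pangenome_intersection(cog_triangles_cluster(hits),
                                     omcl_cluster(hits))
        assert len(pan) == 6
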