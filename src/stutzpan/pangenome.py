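"""Ortholog clustering under the 70/70 rule and pan-genome compartment logic.

Three clustering routes are provided over the same all-vs-all protein hit
table: bidirectional best hit against a reference genome (BDBH), mutually
consistent best-hit triangles merged on shared edges (COG-triangles style),
and Markov clustering of the similarity graph (OrthoMCL style). Two proteins
are candidate family members only if they share at least 70% identity over at
least 70% of the length of the longest of the two (the 70/70 rule).

The pan-genome is the intersection of the COG-triangles and OMCL clusterings
(clusters with identical member sets); the strict consensus core additionally
requires BDBH agreement and exactly one member per genome. Compartments:
core (all genomes), soft-core (>=95% of genomes), cloud (one or two genomes),
shell (the rest). Pan-genes of an in-group are clusters present in every
in-group genome and absent from every out-group genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _align
from .genome_io import Proteome, SequenceRecord

Member = tuple[str, str]  # (genome_id, protein_id)


@dataclass(frozen=True)
class SimilarityThresholds:
    min_identity_pct: float = 70.0
    min_coverage_fraction: float = 0.70  # of the LONGEST sequence
    pathway_min_identity_pct: float = 30.0
    pathway_min_seed_coverage: float = 0.50  # set 0 to disable
    min_shared_kmers: int = 4  # 4-mer prefilter; 0 disables

    def __post_init__(self) -> None:
        if not (0 < self.min_identity_pct <= 100):
            raise ValueError("min_identity_pct out of range")
        if not (0 < self.min_coverage_fraction <= 1):
            raise ValueError("min_coverage_fraction out of range")


@dataclass(frozen=True)
class ProteinHit:
    query_id: Member
    subject_id: Member
    identity_pct: float
    coverage_of_longest: float
    score: float


@dataclass(frozen=True)
class OrthoCluster:
    cluster_id: str
    members: tuple[Member, ...]
    algorithm: str  # BDBH | COGT | OMCL | consensus

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty ortholog cluster")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"cluster {self.cluster_id} has duplicate members")

    @property
    def member_set(self) -> frozenset[Member]:
        return frozenset(self.members)

    @property
    def genomes(self) -> set[str]:
        return {g for g, _ in self.members}


def _shared_kmers(a: str, b: str, k: int = 4) -> int:
    if len(a) < k or len(b) < k:
        return 0
    kmers = {a[i:i + k] for i in range(len(a) - k + 1)}
    return sum(1 for i in range(len(b) - k + 1) if b[i:i + k] in kmers)


def all_vs_all_hits(proteomes: list[Proteome],
                    thresholds: SimilarityThresholds = SimilarityThresholds()
                    ) -> list[ProteinHit]:
    """All-vs-all protein hits that survive the 70/70 filter.

    One BLOSUM62 local alignment is computed per unordered protein pair and
    emitted as two symmetric directed hits. Pairs sharing fewer than
    ``min_shared_kmers`` 4-mers are skipped without alignment; at the 70%
    identity floor homologous pairs share dozens of 4-mers, so the prefilter
    cannot drop a qualifying pair.
    """
    if len(proteomes) < 2:
        raise ValueError("need at least two proteomes")
    for p in proteomes:
        if not p.proteins:
            raise ValueError(f"empty proteome {p.genome_id}")
    entries: list[tuple[Member, str]] = [
        ((p.genome_id, prot.id), prot.sequence)
        for p in proteomes for prot in p.proteins
    ]
    hits: list[ProteinHit] = []
    for i in range(len(entries)):
        (mi, si) = entries[i]
        for j in range(i + 1, len(entries)):
            (mj, sj) = entries[j]
            if thresholds.min_shared_kmers and \
                    _shared_kmers(si, sj) < thresholds.min_shared_kmers:
                continue
            res = _align.local_align_protein(si, sj)
            if res is None:
                continue
            longest = max(len(si), len(sj))
            if len(si) >= len(sj):
                span = res.query_end - res.query_start
            else:
                span = res.subject_end - res.subject_start
            coverage = span / longest
            if (res.identity_pct >= thresholds.min_identity_pct
                    and coverage >= thresholds.min_coverage_fraction):
                hits.append(ProteinHit(mi, mj, res.identity_pct, coverage, res.score))
                hits.append(ProteinHit(mj, mi, res.identity_pct, coverage, res.score))
    return hits


def _best_hits(hits: list[ProteinHit]) -> dict[tuple[Member, str], Member]:
    """query -> best subject per target genome; ties broken by (score,
    identity, lexicographically smaller protein id)."""
    best: dict[tuple[Member, str], ProteinHit] = {}
    for h in hits:
        if h.query_id[0] == h.subject_id[0]:
            continue  # best hits are inter-genome
        key = (h.query_id, h.subject_id[0])
        cur = best.get(key)
        if cur is None or (h.score, h.identity_pct, ) > (cur.score, cur.identity_pct) \
                or ((h.score, h.identity_pct) == (cur.score, cur.identity_pct)
                    and h.subject_id[1] < cur.subject_id[1]):
            best[key] = h
    return {k: v.subject_id for k, v in best.items()}


def _bbh_pairs(hits: list[ProteinHit]) -> set[frozenset[Member]]:
    best = _best_hits(hits)
    pairs: set[frozenset[Member]] = set()
    for (query, target_genome), subject in best.items():
        if best.get((subject, query[0])) == query:
            pairs.add(frozenset((query, subject)))
    return pairs


def bdbh_cluster(hits: list[ProteinHit], proteomes: list[Proteome],
                 reference_genome: str) -> list[OrthoCluster]:
    """One cluster per reference protein: its bidirectional best hits.

    For every protein of the reference genome, the cluster contains, per other
    genome, the protein that is a bidirectional best hit with it; genomes with
    no BDBH partner are simply absent from that cluster.
    """
    by_id = {p.genome_id: p for p in proteomes}
    if reference_genome not in by_id:
        raise ValueError(f"reference genome {reference_genome!r} not among proteomes")
    best = _best_hits(hits)
    other_genomes = sorted(g for g in by_id if g != reference_genome)
    clusters = []
    for k, prot in enumerate(by_id[reference_genome].proteins):
        ref_member: Member = (reference_genome, prot.id)
        members = [ref_member]
        for genome in other_genomes:
            partner = best.get((ref_member, genome))
            if partner is not None and best.get((partner, reference_genome)) == ref_member:
                members.append(partner)
        clusters.append(OrthoCluster(f"BDBH_{k:05d}", tuple(members), "BDBH"))
    return clusters


def cog_triangles_cluster(hits: list[ProteinHit]) -> list[OrthoCluster]:
    """Merge mutually consistent best-hit triangles sharing an edge.

    BBH pairs form edges; any three proteins from three distinct genomes that
    are pairwise BBH form a triangle; triangles sharing an edge are merged
    into one cluster. Proteins in no triangle stay unclustered.
    """
    genomes = {m[0] for h in hits for m in (h.query_id, h.subject_id)}
    if len(genomes) < 3:
        raise ValueError("COG-triangles needs hits spanning at least 3 genomes")
    edges = _bbh_pairs(hits)
    neighbors: dict[Member, set[Member]] = {}
    for e in edges:
        a, b = tuple(e)
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)
    # enumerate triangles with members in 3 distinct genomes
    triangles: list[tuple[Member, Member, Member]] = []
    nodes = sorted(neighbors)
    for a in nodes:
        for b in sorted(neighbors[a]):
            if b <= a:
                continue
            for c in sorted(neighbors[a] & neighbors[b]):
                if c <= b:
                    continue
                if len({a[0], b[0], c[0]}) == 3:
                    triangles.append((a, b, c))
    # union-find over triangles via shared edges
    parent = list(range(len(triangles)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edge_owner: dict[frozenset[Member], int] = {}
    for t_idx, (a, b, c) in enumerate(triangles):
        for e in (frozenset((a, b)), frozenset((a, c)), frozenset((b, c))):
            if e in edge_owner:
                parent[find(t_idx)] = find(edge_owner[e])
            else:
                edge_owner[e] = t_idx
    groups: dict[int, set[Member]] = {}
    for t_idx, tri in enumerate(triangles):
        groups.setdefault(find(t_idx), set()).update(tri)
    clusters = []
    for k, members in enumerate(sorted(groups.values(), key=lambda m: sorted(m))):
        clusters.append(OrthoCluster(f"COGT_{k:05d}", tuple(sorted(members)), "COGT"))
    return clusters


def markov_cluster(nodes: list, edges: dict[frozenset, float], inflation: float = 1.5,
                   pruning: float = 1e-5, tol: float = 1e-6,
                   max_iter: int = 100) -> list[set]:
    """Plain Markov clustering of an undirected weighted graph.

    Adds self-loops (per-column maximum weight), column-normalizes, then
    alternates expansion (matrix square) and inflation (element-wise power
    followed by renormalization) with pruning of entries below ``pruning``
    until the matrix changes by less than ``tol`` or ``max_iter`` iterations.
    Clusters are the connected components of the limiting matrix's nonzero
    structure. Fully deterministic.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    n = len(nodes)
    idx = {node: i for i, node in enumerate(nodes)}
    M = np.zeros((n, n))
    for e, w in edges.items():
        pair = tuple(e)
        if len(pair) == 1:
            continue
        a, b = idx[pair[0]], idx[pair[1]]
        M[a, b] = M[b, a] = max(M[a, b], w)
    loop = M.max(axis=0)
    loop[loop == 0] = 1.0
    M[np.diag_indices(n)] = loop
    M = M / M.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        previous = M
        M = M @ M                      # expansion
        M = np.power(M, inflation)     # inflation
        M[M < pruning] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M = M / colsum
        if np.max(np.abs(M - previous)) < tol:
            converged = True
            break
    if not converged:
        import warnings
        warnings.warn("Markov clustering did not converge; returning current partition")
    support = (M + M.T) > 0
    seen = [False] * n
    components: list[set] = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], set()
        while stack:
            v = stack.pop()
            if seen[v]:
                continue
            seen[v] = True
            comp.add(nodes[v])
            stack.extend(np.nonzero(support[v])[0])
        components.append(comp)
    return components


def omcl_cluster(hits: list[ProteinHit], inflation: float = 1.5) -> list[OrthoCluster]:
    """OrthoMCL-style clustering: MCL on the symmetric similarity graph.

    Edge weights are min(score_ab, score_ba) over the two hit directions —
    a simplification of the OrthoMCL between-species normalization that
    preserves partition behaviour on identity-separated families.
    """
    scores: dict[frozenset[Member], float] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        e = frozenset((h.query_id, h.subject_id))
        scores[e] = min(scores.get(e, h.score), h.score)
    nodes = sorted({m for e in scores for m in e})
    components = markov_cluster(nodes, scores, inflation=inflation)
    clusters = []
    for k, comp in enumerate(sorted(components, key=lambda c: sorted(c))):
        clusters.append(OrthoCluster(f"OMCL_{k:05d}", tuple(sorted(comp)), "OMCL"))
    return clusters


def consensus_core(bdbh: list[OrthoCluster], cogt: list[OrthoCluster],
                   omcl: list[OrthoCluster], genomes: list[str]) -> list[OrthoCluster]:
    """Strict consensus core: identical member sets in all three algorithms
    and exactly one protein from every genome."""
    genome_set = set(genomes)
    for clustering in (bdbh, cogt, omcl):
        covered = {g for c in clustering for g in c.genomes}
        if not covered <= genome_set:
            raise ValueError("clustering mentions genomes outside the given set")
    sets = [frozenset(c.member_set) for c in bdbh]
    common = set(sets) & {c.member_set for c in cogt} & {c.member_set for c in omcl}
    core = []
    for members in sorted(common, key=sorted):
        per_genome = [g for g, _ in members]
        if sorted(set(per_genome)) == sorted(genome_set) and \
                len(per_genome) == len(genome_set):
            core.append(members)
    return [OrthoCluster(f"CORE_{k:05d}", tuple(sorted(m)), "consensus")
            for k, m in enumerate(core)]


@dataclass
class PangenomeMatrix:
    """Cluster x genome occupancy counts with compartment labels."""

    clusters: list[OrthoCluster]
    genomes: list[str]
    occupancy: np.ndarray  # shape (n_clusters, n_genomes), counts
    compartments: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=int)
        if self.occupancy.shape != (len(self.clusters), len(self.genomes)):
            raise ValueError("occupancy shape disagrees with clusters/genomes")
        if (self.occupancy < 0).any():
            raise ValueError("occupancy counts must be non-negative")

    @property
    def presence(self) -> np.ndarray:
        return self.occupancy > 0

    def compartment_sizes(self) -> dict[str, int]:
        sizes = {"core": 0, "soft-core": 0, "shell": 0, "cloud": 0}
        for label in self.compartments.values():
            sizes[label] += 1
        return sizes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.occupancy,
                            index=[c.cluster_id for c in self.clusters],
                            columns=self.genomes)


def occupancy_matrix(clusters: list[OrthoCluster], genomes: list[str]) -> np.ndarray:
    gidx = {g: j for j, g in enumerate(genomes)}
    occ = np.zeros((len(clusters), len(genomes)), dtype=int)
    for i, c in enumerate(clusters):
        for g, _ in c.members:
            occ[i, gidx[g]] += 1
    return occ


def pangenome_intersection(cogt: list[OrthoCluster],
                           omcl: list[OrthoCluster]) -> list[OrthoCluster]:
    """Pan-genome clusters: identical member sets in COGT and OMCL."""
    common = {c.member_set for c in cogt} & {c.member_set for c in omcl}
    return [OrthoCluster(f"PAN_{k:05d}", tuple(sorted(m)), "consensus")
            for k, m in enumerate(sorted(common, key=sorted))]


def compartmentalize(clusters: list[OrthoCluster], genomes: list[str],
                     soft_core_fraction: float = 0.95) -> PangenomeMatrix:
    """Label each cluster core / soft-core / shell / cloud.

    core: present in all genomes; soft-core: present in >= ``soft_core_fraction``
    of the genomes (but not all); cloud: present in exactly one or two genomes;
    shell: everything else. The labels partition the cluster set.
    """
    occ = occupancy_matrix(clusters, genomes)
    n = len(genomes)
    compartments: dict[str, str] = {}
    for i, c in enumerate(clusters):
        present = int((occ[i] > 0).sum())
        if present == n:
            label = "core"
        elif present >= soft_core_fraction * n:
            label = "soft-core"
        elif present <= 2:
            label = "cloud"
        else:
            label = "shell"
        compartments[c.cluster_id] = label
    return PangenomeMatrix(clusters, list(genomes), occ, compartments)


def pan_genes(matrix: PangenomeMatrix, ingroup: set[str],
              outgroup: set[str]) -> list[OrthoCluster]:
    """Clusters present in every in-group genome and absent from every
    out-group genome (the in-group's pan-genes)."""
    if not ingroup or not outgroup:
        raise ValueError("ingroup and outgroup must both be non-empty")
    if ingroup & outgroup:
        raise ValueError(f"ingroup/outgroup overlap: {sorted(ingroup & outgroup)}")
    missing = (ingroup | outgroup) - set(matrix.genomes)
    if missing:
        raise ValueError(f"genomes not in matrix: {sorted(missing)}")
    in_idx = [matrix.genomes.index(g) for g in sorted(ingroup)]
    out_idx = [matrix.genomes.index(g) for g in sorted(outgroup)]
    presence = matrix.presence
    keep = presence[:, in_idx].all(axis=1) & ~presence[:, out_idx].any(axis=1)
    return [c for c, k in zip(matrix.clusters, keep) if k]


def pathway_profile(seed_proteins: list[SequenceRecord], proteomes: list[Proteome],
                    thresholds: SimilarityThresholds = SimilarityThresholds()
                    ) -> pd.DataFrame:
    """Presence/absence matrix of pathway seed proteins across genomes.

    A genome scores 1 for a seed when it has at least one protein aligning at
    >= ``pathway_min_identity_pct`` identity covering >=
    ``pathway_min_seed_coverage`` of the seed length. A pathway (the seed set)
    is complete in a genome iff every seed is present; the returned frame has
    one row per seed plus a ``_pathway_complete`` row.
    """
    if not seed_proteins:
        raise ValueError("need at least one seed protein")
    data = {}
    for proteome in proteomes:
        col = []
        for seed in seed_proteins:
            found = 0
            for prot in proteome.proteins:
                res = _align.local_align_protein(seed.sequence, prot.sequence)
                if res is None:
                    continue
                seed_cov = (res.query_end - res.query_start) / len(seed)
                if (res.identity_pct >= thresholds.pathway_min_identity_pct
                        and seed_cov >= thresholds.pathway_min_seed_coverage):
                    found = 1
                    break
            col.append(found)
        data[proteome.genome_id] = col + [int(all(col))]
    index = [s.id for s in seed_proteins] + ["_pathway_complete"]
    return pd.DataFrame(data, index=index)
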