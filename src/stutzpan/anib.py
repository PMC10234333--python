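"""Fragment-based average nucleotide identity (ANIb) and genomospecies calls.

ANIb between two genomes: cut the query into 1,020-base fragments, find each
fragment's best local alignment anywhere in the subject (either strand), keep
hits with >=30% identity over >=70% of the fragment length, and average the
identities of the kept hits. The two one-way values are averaged to give the
pairwise ANIb. Genomes sharing ANIb >= 95% belong to the same genomospecies
(phylogenomic species); the partition is the single-linkage closure of that
pairwise relation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from . import _align
from .genome_io import Fragment, GenomeAssembly, fragment_assembly


@dataclass(frozen=True)
class AnibParams:
    """Knobs of the ANIb computation; defaults are the canonical ones."""

    fragment_length: int = 1020
    min_hit_identity_pct: float = 30.0
    min_alignable_fraction: float = 0.70
    species_threshold_pct: float = 95.0
    seed_k: int = 13  # exact-seed length for candidate-window search

    def __post_init__(self) -> None:
        if not (0 < self.min_hit_identity_pct <= 100):
            raise ValueError("min_hit_identity_pct must be in (0, 100]")
        if not (0 < self.min_alignable_fraction <= 1):
            raise ValueError("min_alignable_fraction must be in (0, 1]")
        if not (0 < self.species_threshold_pct <= 100):
            raise ValueError("species_threshold_pct must be in (0, 100]")


@dataclass(frozen=True)
class AlignmentHit:
    """Best local hit of one fragment against a subject genome."""

    fragment_id: str
    subject_contig: str
    identity_pct: float
    alignable_fraction: float
    score: float


@dataclass(frozen=True)
class AnibResult:
    """Bidirectional ANIb value with its one-way components.

    ``value`` is None when neither direction had any qualifying fragment
    ("no alignable fraction"); ``one_way_only`` flags a value derived from a
    single defined direction.
    """

    value: float | None
    forward: float | None
    reverse: float | None
    one_way_only: bool = False

    @property
    def defined(self) -> bool:
        return self.value is not None


class _SubjectIndex:
    """Per-subject k-mer indexes of both strands of every contig."""

    def __init__(self, subject: GenomeAssembly, k: int):
        self.k = k
        self.contigs: list[tuple[str, str, int, dict]] = []
        self._seqs: dict[tuple[str, str], str] = {}
        for contig in subject.contigs:
            for strand, seq in (("+", contig.sequence),
                                ("-", _align.reverse_complement(contig.sequence))):
                self.contigs.append((contig.id, strand, len(seq),
                                     _align.kmer_index(seq, k)))
                self._seqs[(contig.id, strand)] = seq

    def sequence(self, contig_id: str, strand: str) -> str:
        return self._seqs[(contig_id, strand)]


def _best_hit_indexed(fragment: Fragment, index: _SubjectIndex,
                      params: AnibParams) -> AlignmentHit | None:
    best: AlignmentHit | None = None
    for contig_id, strand, length, kidx in index.contigs:
        window = _align.seed_window(fragment.sequence, kidx, length, index.k)
        if window is None:
            continue
        subject_seq = index.sequence(contig_id, strand)[window[0]:window[1]]
        res = _align.local_align_nucleotide(fragment.sequence, subject_seq)
        if res is None:
            continue
        hit = AlignmentHit(
            fragment_id=fragment.fragment_id,
            subject_contig=contig_id,
            identity_pct=res.identity_pct,
            alignable_fraction=(res.query_end - res.query_start) / len(fragment),
            score=res.score,
        )
        if best is None or hit.score > best.score:
            best = hit
    return best


def best_fragment_hit(fragment: Fragment, subject: GenomeAssembly,
                      params: AnibParams = AnibParams()) -> AlignmentHit | None:
    """Highest-scoring local alignment of one fragment against a subject.

    Both strands of every contig are searched. Candidate regions are located
    with exact 13-mer seeds and the winner is refined with Smith-Waterman
    (match +1, mismatch -1, gap open -5, extend -2); a fragment sharing no
    seed with the subject has no hit.
    """
    if len(fragment) < 100:
        raise ValueError("fragments shorter than 100 bases are not searched")
    return _best_hit_indexed(fragment, _SubjectIndex(subject, params.seed_k), params)


def anib_oneway(query: GenomeAssembly, subject: GenomeAssembly,
                params: AnibParams = AnibParams()) -> float | None:
    """One-way ANIb: mean identity of qualifying fragment hits, or None.

    A fragment qualifies when its best hit reaches ``min_hit_identity_pct``
    identity over at least ``min_alignable_fraction`` of the fragment length.
    Returns None ("no alignable fraction") when no fragment qualifies —
    deliberately distinct from 0.
    """
    fragments = fragment_assembly(query, params.fragment_length)
    index = _SubjectIndex(subject, params.seed_k)
    identities = []
    for fragment in fragments:
        hit = _best_hit_indexed(fragment, index, params)
        if hit is None:
            continue
        if (hit.identity_pct >= params.min_hit_identity_pct
                and hit.alignable_fraction >= params.min_alignable_fraction):
            identities.append(hit.identity_pct)
    if not identities:
        return None
    return float(np.mean(identities))


def anib_pair(a: GenomeAssembly, b: GenomeAssembly,
              params: AnibParams = AnibParams()) -> AnibResult:
    """Bidirectional ANIb: arithmetic mean of the two one-way values."""
    ab = anib_oneway(a, b, params)
    ba = anib_oneway(b, a, params)
    if ab is None and ba is None:
        return AnibResult(None, None, None)
    if ab is None or ba is None:
        return AnibResult(ab if ab is not None else ba, ab, ba, one_way_only=True)
    return AnibResult((ab + ba) / 2.0, ab, ba)


@dataclass
class AniMatrix:
    """Symmetric all-vs-all ANIb matrix; undefined pairs stored as NaN."""

    genome_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genome_ids)
        if self.values.shape != (n, n):
            raise ValueError("ANI matrix shape disagrees with genome list")
        if not np.allclose(np.diag(self.values), 100.0):
            raise ValueError("ANI matrix diagonal must be 100")
        finite = np.isfinite(self.values)
        if not np.array_equal(self.values[finite & finite.T],
                              self.values.T[finite & finite.T]):
            raise ValueError("ANI matrix must be symmetric")

    def value(self, a: str, b: str) -> float:
        i, j = self.genome_ids.index(a), self.genome_ids.index(b)
        return float(self.values[i, j])


def build_ani_matrix(assemblies: list[GenomeAssembly],
                     params: AnibParams = AnibParams()) -> AniMatrix:
    """All-vs-all bidirectional ANIb matrix (diagonal fixed at 100)."""
    if len(assemblies) < 2:
        raise ValueError("need at least two assemblies")
    ids = [a.genome_id for a in assemblies]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")
    n = len(assemblies)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            result = anib_pair(assemblies[i], assemblies[j], params)
            v = result.value if result.defined else np.nan
            values[i, j] = values[j, i] = v
    return AniMatrix(ids, values)


def cluster_genomospecies(matrix: AniMatrix,
                          threshold_pct: float = 95.0) -> list[set[str]]:
    """Single-linkage partition at the species threshold.

    Two genomes share a cluster iff they are connected by a chain of pairwise
    ANIb values >= ``threshold_pct`` (transitive closure of the pairwise
    species rule). Undefined (NaN) pairs never link. Clusters are returned
    largest-first, ties broken by smallest member id.
    """
    n = len(matrix.genome_ids)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            v = matrix.values[i, j]
            if np.isfinite(v) and v >= threshold_pct:
                parent[find(i)] = find(j)
    groups: dict[int, set[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(matrix.genome_ids[i])
    return sorted(groups.values(), key=lambda g: (-len(g), min(g)))


def ani_dendrogram(matrix: AniMatrix):
    """Average-linkage dendrogram on Pearson-correlation distances.

    Genomes are compared by the Pearson correlation r of their ANI-matrix
    rows; the clustering distance is 1 - r and the linkage is average
    (UPGMA-style). Returns an skbio ``TreeNode`` whose leaves are genome ids.
    """
    n = len(matrix.genome_ids)
    if n < 3:
        raise ValueError("dendrogram needs at least 3 genomes")
    rows = matrix.values
    if np.isnan(rows).any():
        raise ValueError("dendrogram undefined with missing ANI values")
    stds = rows.std(axis=1)
    for gid, s in zip(matrix.genome_ids, stds):
        if s == 0:
            raise ValueError(f"genome {gid!r} has a constant ANI row; "
                             "Pearson distance is undefined")
    corr = np.corrcoef(rows)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    linkage = average(squareform(dist, checks=False))
    from skbio.tree import TreeNode
    return TreeNode.from_linkage_matrix(linkage, matrix.genome_ids)


def write_ani_tables(matrix: AniMatrix, long_path, square_path) -> None:
    """Write the pairwise long-format and square TSV reports."""
    import pandas as pd
    ids = matrix.genome_ids
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            rows.append({"genome_a": ids[i], "genome_b": ids[j],
                         "ani_mean": matrix.values[i, j]})
    pd.DataFrame(rows).to_csv(long_path, sep="\t", index=False)
    pd.DataFrame(matrix.values, index=ids, columns=ids).to_csv(square_path, sep="\t")
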