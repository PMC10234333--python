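"""Distance-based phylogenetics: Jukes-Cantor distances, neighbor-joining,
column-resampling bootstrap, and alignment trimming/concatenation.

Trees are represented as skbio ``TreeNode`` objects (unrooted NJ trees are
returned with a trifurcating root). Negative NJ branch lengths are clamped to
zero. Bootstrap supports are attached to internal nodes as ``name`` (integer
percentage), the conventional Newick encoding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skbio.tree import TreeNode

from .genome_io import SequenceRecord

def _gaplike(kind: str) -> set[str]:
    # ambiguity codes are treated like gaps when counting residues
    return set("-NRYSWKMBDHV") if kind == "nucleotide" else set("-X")

_GAPLIKE = set("-N")  # nucleotide shortcut used by jc_distance


@dataclass
class MultipleAlignment:
    """Equal-length gapped sequences over one taxon set."""

    records: list[SequenceRecord]
    partitions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate taxon ids in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.records[0])

    @property
    def taxa(self) -> list[str]:
        return [r.id for r in self.records]

    def columns(self) -> np.ndarray:
        return np.array([list(r.sequence) for r in self.records])

    def subset_columns(self, indices: list[int]) -> "MultipleAlignment":
        arr = self.columns()[:, indices]
        recs = [SequenceRecord(r.id, "".join(row), kind=r.kind, description=r.description)
                for r, row in zip(self.records, arr)]
        return MultipleAlignment(recs)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape disagrees with taxa")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if (self.values < 0).any() or not np.allclose(np.diag(self.values), 0):
            raise ValueError("distances must be >= 0 with zero diagonal")


def jc_distance(aln: MultipleAlignment) -> DistanceMatrix:
    """Jukes-Cantor distances d = -(3/4) ln(1 - (4/3) p).

    p is the mismatch fraction over columns where neither sequence has a gap
    or an ambiguous base. Errors if a pair has no comparable columns or
    p >= 0.75 (distance undefined under the model).
    """
    seqs = [r.sequence for r in aln.records]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            compared = mismatches = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in _GAPLIKE or b in _GAPLIKE:
                    continue
                compared += 1
                if a != b:
                    mismatches += 1
            if compared == 0:
                raise ValueError(f"no comparable columns between "
                                 f"{aln.taxa[i]!r} and {aln.taxa[j]!r}")
            p = mismatches / compared
            if p >= 0.75:
                raise ValueError(f"JC distance undefined (p={p:.3f} >= 0.75) for "
                                 f"{aln.taxa[i]!r} vs {aln.taxa[j]!r}")
            d[i, j] = d[j, i] = -0.75 * np.log1p(-4.0 * p / 3.0)
    return DistanceMatrix(list(aln.taxa), d)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Ties in the Q criterion are broken by the smallest (i, j) index pair in
    the current working matrix. On additive input the tree's path lengths
    reproduce the matrix exactly. Negative branch lengths are clamped to 0
    with a warning.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.values.astype(float).copy()
    nodes = [TreeNode(name=t) for t in dm.taxa]

    def clamp(x: float) -> float:
        if x < 0:
            if x < -1e-9:
                warnings.warn(f"negative NJ branch length {x:.4g} clamped to 0")
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        totals = d.sum(axis=1)
        q_best = np.inf
        bi = bj = -1
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - totals[i] - totals[j]
                if q < q_best - 1e-12:
                    q_best, bi, bj = q, i, j
        vi = 0.5 * d[bi, bj] + (totals[bi] - totals[bj]) / (2 * (m - 2))
        vj = d[bi, bj] - vi
        new = TreeNode()
        nodes[bi].length = clamp(vi)
        nodes[bj].length = clamp(vj)
        new.append(nodes[bi])
        new.append(nodes[bj])
        dk = 0.5 * (d[bi, :] + d[bj, :] - d[bi, bj])
        keep = [x for x in range(m) if x not in (bi, bj)]
        d_new = np.zeros((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = dk[keep]
        d = d_new
        nodes = [nodes[x] for x in keep] + [new]
    # final trifurcation
    a, b, c = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    root = TreeNode()
    for node, length in ((a, la), (b, lb), (c, lc)):
        node.length = clamp(length)
        root.append(node)
    return root


def tree_distance_matrix(tree: TreeNode, taxa: list[str]) -> DistanceMatrix:
    """Patristic (path-length) distances between the named leaves."""
    n = len(taxa)
    d = np.zeros((n, n))
    tip = {t: tree.find(t) for t in taxa}
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tip[taxa[i]].distance(tip[taxa[j]])
    return DistanceMatrix(list(taxa), d)


def _bipartitions(tree: TreeNode, taxa: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalized as the side not containing
    the lexicographically smallest taxon (unrooted comparison)."""
    anchor = min(taxa)
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        if anchor in side:
            side = taxa - side
        parts.add(side)
    return parts


def bootstrap_support(aln: MultipleAlignment, n_replicates: int = 1000,
                      seed: int = 0) -> TreeNode:
    """NJ tree with bootstrap supports from column resampling.

    Columns are resampled with replacement; each replicate alignment is run
    through jc_distance + neighbor_joining and its bipartitions tallied.
    Supports (percent of replicates containing the bipartition) are written to
    the internal nodes of the full-data tree. Replicates with undefined JC
    distances are redrawn, capped at 10x the replicate count.
    """
    full = neighbor_joining(jc_distance(aln))
    taxa = frozenset(aln.taxa)
    counts: dict[frozenset[str], int] = {p: 0 for p in _bipartitions(full, taxa)}
    rng = np.random.default_rng(seed)
    done = attempts = 0
    cols = aln.columns()
    while done < n_replicates:
        if attempts >= 10 * n_replicates:
            raise RuntimeError("too many bootstrap replicates with undefined distances")
        attempts += 1
        idx = rng.integers(0, aln.n_columns, size=aln.n_columns)
        recs = [SequenceRecord(r.id, "".join(row), kind=r.kind)
                for r, row in zip(aln.records, cols[:, idx])]
        try:
            rep_tree = neighbor_joining(jc_distance(MultipleAlignment(recs)))
        except ValueError:
            continue
        done += 1
        for part in _bipartitions(rep_tree, taxa):
            if part in counts:
                counts[part] += 1
    for node in full.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        if min(taxa) in side:
            side = taxa - side
        node.name = str(round(100.0 * counts[side] / n_replicates))
    return full


def trim_alignment(aln: MultipleAlignment, min_nongap_fraction: float = 0.5,
                   min_conserved_fraction: float = 0.5,
                   min_block_length: int = 5) -> MultipleAlignment:
    """Gblocks-style column filter.

    Keeps columns whose non-gap fraction and majority-residue fraction (among
    non-gap residues) both meet their thresholds, then drops kept runs shorter
    than ``min_block_length``. Output columns are a subset of input columns;
    the kept indices are recorded in ``partitions`` as one ("kept", start,
    end) entry per block.
    """
    cols = aln.columns()
    n_seqs = len(aln.records)
    gaplike = _gaplike(aln.records[0].kind)
    kept_flags = []
    for j in range(aln.n_columns):
        col = cols[:, j]
        residues = [c for c in col if c not in gaplike]
        nongap = len(residues) / n_seqs
        if nongap < min_nongap_fraction or not residues:
            kept_flags.append(False)
            continue
        _, top = max(((residues.count(c), c) for c in set(residues)))
        conserved = residues.count(top) / len(residues)
        kept_flags.append(conserved >= min_conserved_fraction)
    # drop runs shorter than min_block_length
    kept_indices: list[int] = []
    blocks: list[tuple[str, int, int]] = []
    j = 0
    while j < len(kept_flags):
        if not kept_flags[j]:
            j += 1
            continue
        k = j
        while k < len(kept_flags) and kept_flags[k]:
            k += 1
        if k - j >= min_block_length:
            kept_indices.extend(range(j, k))
            blocks.append(("kept", j, k))
        j = k
    if not kept_indices:
        raise ValueError("all alignment columns removed by trimming")
    out = aln.subset_columns(kept_indices)
    out.partitions = blocks
    return out


def concatenate(alignments: list[MultipleAlignment]) -> MultipleAlignment:
    """Column-wise concatenation of alignments over one taxon set.

    A partition map (alignment index, start, end) is retained on the result.
    """
    if not alignments:
        raise ValueError("nothing to concatenate")
    taxa = set(alignments[0].taxa)
    pieces: dict[str, list[str]] = {t: [] for t in taxa}
    partitions: list[tuple[str, int, int]] = []
    offset = 0
    for k, aln in enumerate(alignments):
        if set(aln.taxa) != taxa:
            missing = sorted(taxa ^ set(aln.taxa))
            raise ValueError(f"taxon set mismatch in alignment {k}: {missing}")
        for r in aln.records:
            pieces[r.id].append(r.sequence)
        partitions.append((f"part{k}", offset, offset + aln.n_columns))
        offset += aln.n_columns
    kind = alignments[0].records[0].kind
    order = alignments[0].taxa
    recs = [SequenceRecord(t, "".join(pieces[t]), kind=kind) for t in order]
    out = MultipleAlignment(recs)
    out.partitions = partitions
    return out


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")
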