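import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj as skbio_nj

from stutzpan import phylo
from stutzpan.genome_io import SequenceRecord
from stutzpan.phylo import (DistanceMatrix, MultipleAlignment, bootstrap_support,
                            concatenate, jc_distance, neighbor_joining,
                            tree_distance_matrix, trim_alignment)
from conftest import random_additive_matrix


def _aln(seqs, kind="nucleotide"):
    return MultipleAlignment([SequenceRecord(f"t{i}", s, kind=kind)
                              for i, s in enumerate(seqs)])


class TestJukesCantor:
    def test_identical_sequences_have_zero_distance(self):
        dm = jc_distance(_aln(["ACGTACGTAC", "ACGTACGTAC"]))
        assert dm.values[0, 1] == 0.0

    def test_ten_percent_mismatch_closed_form(self):
        a = "A" * 100
        b = "C" * 10 + "A" * 90  # p = 0.10
        dm = jc_distance(_aln([a, b]))
        assert dm.values[0, 1] == pytest.approx(0.10732, abs=1e-4)

    def test_saturation_is_an_error(self):
        a = "A" * 100
        b = "C" * 75 + "A" * 25  # p = 0.75
        with pytest.raises(ValueError, match="undefined"):
            jc_distance(_aln([a, b]))

    def test_gap_and_n_columns_excluded(self):
        # one mismatch over 8 comparable columns (2 columns masked by -/N)
        a = "ACGTACGTAA"
        b = "ACGTACGA-N"
        dm = jc_distance(_aln([a, b]))
        p = 1 / 8
        expected = -0.75 * np.log(1 - 4 * p / 3)
        assert dm.values[0, 1] == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_p(self):
        distances = []
        for mismatches in (5, 10, 20, 40):
            a = "A" * 100
            b = "C" * mismatches + "A" * (100 - mismatches)
            distances.append(jc_distance(_aln([a, b])).values[0, 1])
        assert distances == sorted(distances)


class TestNeighborJoining:
    def test_four_taxon_additive_tree_exact(self):
        # cherries (A:1, B:2) and (C:3, D:4) joined by an internal edge of 5
        taxa = ["A", "B", "C", "D"]
        d = np.array([
            [0.0, 3.0, 9.0, 10.0],
            [3.0, 0.0, 10.0, 11.0],
            [9.0, 10.0, 0.0, 7.0],
            [10.0, 11.0, 7.0, 0.0],
        ])
        tree = neighbor_joining(DistanceMatrix(taxa, d))
        back = tree_distance_matrix(tree, taxa)
        np.testing.assert_allclose(back.values, d, atol=1e-9)
        clades = {frozenset(t.name for t in n.tips()) for n in tree.non_tips()}
        assert frozenset({"A", "B"}) in clades or frozenset({"C", "D"}) in clades

    def test_three_equidistant_taxa(self):
        d = np.full((3, 3), 2.0)
        np.fill_diagonal(d, 0.0)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        lengths = sorted(t.length for t in tree.tips())
        assert lengths == pytest.approx([1.0, 1.0, 1.0])

    def test_inverts_random_additive_matrices(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 11))
            dm = random_additive_matrix(n, rng)
            tree = neighbor_joining(dm)
            back = tree_distance_matrix(tree, dm.taxa)
            np.testing.assert_allclose(back.values, dm.values, atol=1e-8)

    def test_topology_agrees_with_skbio_nj(self, rng):
        dm = random_additive_matrix(7, rng)
        ours = neighbor_joining(dm)
        theirs = skbio_nj(SkbioDM(dm.values, ids=dm.taxa))
        taxa = frozenset(dm.taxa)

        def bips(tree):
            out = set()
            for node in tree.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if 1 < len(side) < len(taxa) - 1:
                    out.add(min(side, taxa - side, key=sorted))
            return out

        assert bips(ours) == bips(theirs)

    def test_too_few_taxa(self):
        d = np.zeros((2, 2))
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"], d))


class TestBootstrap:
    def _panel(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=300))
        twin = base
        others = []
        for k in range(3):
            arr = list(base)
            sites = rng.choice(300, size=90 + 30 * k, replace=False)
            for p in sites:
                arr[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[p]]
            others.append("".join(arr))
        return MultipleAlignment(
            [SequenceRecord("twin1", base), SequenceRecord("twin2", twin)]
            + [SequenceRecord(f"far{k}", s) for k, s in enumerate(others)])

    def test_identical_pair_gets_full_support(self, rng):
        tree = bootstrap_support(self._panel(rng), n_replicates=50, seed=5)
        supports = {frozenset(t.name for t in n.tips()): n.name
                    for n in tree.non_tips()}
        assert supports[frozenset({"twin1", "twin2"})] == "100"

    def test_same_seed_is_bit_reproducible(self, rng):
        panel = self._panel(rng)
        a = bootstrap_support(panel, n_replicates=30, seed=9)
        b = bootstrap_support(panel, n_replicates=30, seed=9)
        assert str(a) == str(b)


class TestTrimming:
    def test_identical_sequences_unchanged(self):
        aln = _aln(["ACGTACGTACGT"] * 3)
        out = trim_alignment(aln)
        assert [r.sequence for r in out.records] == [r.sequence for r in aln.records]

    def test_gappy_column_removed(self):
        # column 5 is 2/3 gaps; flanks are clean and long enough to keep
        seqs = ["AAAAA-AAAAA", "AAAAA-AAAAA", "AAAAACAAAAA"]
        out = trim_alignment(_aln(seqs), min_nongap_fraction=0.5)
        assert out.n_columns == 10

    def test_planted_clean_block_retained_exactly(self, rng):
        block = "".join(rng.choice(list("ACGT"), size=40))
        rows = []
        for k in range(4):
            noise_left = "".join(rng.choice(list("ACGT-"), size=20))
            noise_right = "".join(rng.choice(list("ACGT-"), size=20))
            rows.append(noise_left + block + noise_right)
        aln = _aln(rows)
        out = trim_alignment(aln, min_nongap_fraction=0.9,
                             min_conserved_fraction=0.9, min_block_length=5)
        assert [r.sequence for r in out.records] == [block] * 4

    def test_all_columns_removed_errors(self):
        with pytest.raises(ValueError):
            trim_alignment(_aln(["A---", "C---", "G---"]),
                           min_nongap_fraction=0.9, min_conserved_fraction=0.9)


class TestConcatenation:
    def test_column_counts_add(self, rng):
        parts = []
        for _ in range(5):
            cols = int(rng.integers(10, 60))
            seqs = ["".join(rng.choice(list("ACGT"), size=cols)) for _ in range(3)]
            parts.append(_aln(seqs))
        combined = concatenate(parts)
        assert combined.n_columns == sum(p.n_columns for p in parts)
        assert len(combined.partitions) == 5

    def test_taxon_mismatch_names_taxon(self):
        a = _aln(["ACGT", "ACGT"])
        b = MultipleAlignment([SequenceRecord("t0", "ACGT"),
                               SequenceRecord("zz", "ACGT")])
        with pytest.raises(ValueError, match="zz"):
            concatenate([a, b])

    def test_order_does_not_change_nj_topology(self, rng):
        parts = []
        base = "".join(rng.choice(list("ACGT"), size=120))
        taxa_seqs = {f"t{i}": list(base) for i in range(5)}
        for i, (t, arr) in enumerate(taxa_seqs.items()):
            sites = rng.choice(120, size=6 * (i + 1), replace=False)
            for p in sites:
                arr[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[p]]
        records = [SequenceRecord(t, "".join(arr)) for t, arr in taxa_seqs.items()]
        full = MultipleAlignment(records)
        half1 = full.subset_columns(list(range(60)))
        half2 = full.subset_columns(list(range(60, 120)))

        def topology(aln_list):
            tree = neighbor_joining(jc_distance(concatenate(aln_list)))
            return {frozenset(t.name for t in n.tips()) for n in tree.non_tips()}

        assert topology([half1, half2]) == topology([half2, half1])
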