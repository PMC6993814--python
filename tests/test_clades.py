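from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kojigenomics import clades
from kojigenomics.core_io import (
    MAT1_1,
    MAT1_2,
    MAT_AMBIGUOUS,
    MAT_UNKNOWN,
    AlignmentSet,
    CladeAssignment,
    GeneAlignment,
    reverse_complement,
)
from kojigenomics.synthetic_data import simulate_dataset


def _aset(*alignments):
    strains = tuple(sorted(alignments[0].strains))
    return AlignmentSet(alignments=tuple(alignments), strains=strains)


def _aln(og, **seqs):
    return GeneAlignment(og_id=og, sequences=seqs)


class TestConcatDegapped:
    def test_gap_free_lengths_add_up(self):
        aset = _aset(
            _aln("og1", s1="ACGTACGTA", s2="ACGTACGTA"),
            _aln("og2", s1="A" * 12, s2="C" * 12),
        )
        concat = clades.concat_degapped(aset)
        assert concat.columns == 21
        assert concat.retained == {"og1": 9, "og2": 12}

    def test_column_gapped_in_one_strain_dropped_for_all(self):
        aset = _aset(
            _aln("og1", s1="ACG-ACGTA", s2="ACGTACGTA"),
        )
        concat = clades.concat_degapped(aset)
        assert concat.columns == 8
        assert concat.matrix["s2"] == "ACGACGTA"

    def test_all_gap_orthogroup_skipped_with_warning(self):
        aset = _aset(
            _aln("og1", s1="---", s2="AAA"),
            _aln("og2", s1="ACG", s2="ACG"),
        )
        with pytest.warns(UserWarning, match="og1"):
            concat = clades.concat_degapped(aset)
        assert concat.skipped == ("og1",)
        assert concat.columns == 3


def _concat(rows):
    strains = tuple(sorted(rows))
    cols = len(next(iter(rows.values())))
    return clades.ConcatenatedMatrix(
        strains=strains,
        columns=cols,
        matrix=rows,
        retained={"og1": cols},
        skipped=(),
    )


class TestPDistance:
    def test_identical_rows_zero(self):
        dm = clades.pdistance(_concat({"a": "ACGT", "b": "ACGT"}))
        assert dm.value("a", "b") == 0.0

    def test_quarter_difference(self):
        dm = clades.pdistance(_concat({"a": "AAAA", "b": "AAAT"}))
        assert dm.value("a", "b") == 0.25

    def test_n_is_a_wildcard(self):
        dm = clades.pdistance(_concat({"a": "AANA", "b": "AAGA"}))
        assert dm.value("a", "b") == 0.0

    @given(
        st.lists(
            st.text(alphabet="ACGT", min_size=30, max_size=30),
            min_size=3,
            max_size=5,
        )
    )
    def test_metric_properties_on_gap_free_rows(self, seqs):
        rows = {f"s{i}": s for i, s in enumerate(seqs)}
        dm = clades.pdistance(_concat(rows))
        n = len(seqs)
        assert np.allclose(dm.d, dm.d.T)
        assert np.allclose(np.diag(dm.d), 0.0)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert dm.d[i, j] <= dm.d[i, k] + dm.d[k, j] + 1e-12


class TestClustering:
    @staticmethod
    def _dm(pairs, names):
        n = len(names)
        d = np.full((n, n), 0.5)  # unspecified pairs are far apart
        np.fill_diagonal(d, 0.0)
        for (i, j), v in pairs.items():
            d[i, j] = d[j, i] = v
        return clades.DistanceMatrix(strains=tuple(names), d=d)

    def test_pair_within_threshold_merges(self):
        dm = self._dm({(0, 1): 5e-5}, ["a", "b"])
        labels = clades.cluster_clades(dm)
        assert labels["a"] == labels["b"]

    def test_pair_beyond_threshold_splits(self):
        dm = self._dm({(0, 1): 2e-4}, ["a", "b"])
        labels = clades.cluster_clades(dm)
        assert labels["a"] != labels["b"]

    def test_zero_threshold_isolates_distinct_sequences(self):
        dm = self._dm({(0, 1): 1e-9, (0, 2): 1e-9, (1, 2): 1e-9}, ["a", "b", "c"])
        labels = clades.cluster_clades(dm, threshold=0.0)
        assert len(set(labels.values())) == 3

    def test_labels_ordered_by_first_appearing_strain(self):
        dm = self._dm({(1, 2): 1e-5}, ["z", "m", "n"])
        labels = clades.cluster_clades(dm)
        assert labels == {"z": "C1", "m": "C2", "n": "C2"}

    def test_monotone_refinement_in_threshold(self):
        rng = np.random.default_rng(8)
        n = 12
        raw = rng.random((n, n)) * 0.01
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0)
        dm = clades.DistanceMatrix(strains=tuple(f"s{i}" for i in range(n)), d=d)
        for t1, t2 in [(0.001, 0.003), (0.002, 0.008)]:
            fine = clades.cluster_clades(dm, threshold=t1)
            coarse = clades.cluster_clades(dm, threshold=t2)
            # every fine cluster maps into exactly one coarse cluster
            for label in set(fine.values()):
                members = [s for s, l in fine.items() if l == label]
                assert len({coarse[m] for m in members}) == 1


def _bipartitions(tree):
    """Leaf-label splits induced by the tree's internal edges."""
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    splits = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        splits.add(min(side, all_leaves - side, key=sorted))
    return splits


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        tree = clades.nj_tree(
            clades.DistanceMatrix(strains=("a", "b", "c"), d=d)
        )
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(0.05)
        assert lengths["b"] == pytest.approx(0.15)
        assert lengths["c"] == pytest.approx(0.25)

    @pytest.mark.parametrize("pairing", [("a", "b"), ("a", "c"), ("a", "d")])
    def test_recovers_generating_topology_for_additive_matrices(self, pairing):
        # build an additive matrix from the tree pairing `pairing` as cherries
        taxa = ["a", "b", "c", "d"]
        partner = {pairing[0]: pairing[1], pairing[1]: pairing[0]}
        rest = [t for t in taxa if t not in pairing]
        partner.update({rest[0]: rest[1], rest[1]: rest[0]})
        leaf_len = {"a": 0.05, "b": 0.07, "c": 0.06, "d": 0.04}
        internal = 0.03
        n = len(taxa)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ti, tj = taxa[i], taxa[j]
                dij = leaf_len[ti] + leaf_len[tj]
                if partner[ti] != tj:
                    dij += internal
                d[i, j] = d[j, i] = dij
        tree = clades.nj_tree(clades.DistanceMatrix(strains=tuple(taxa), d=d))
        expected_split = min(
            frozenset(pairing), frozenset(rest), key=sorted
        )
        assert expected_split in _bipartitions(tree)

    def test_equidistant_taxa_get_equal_leaf_branches(self):
        n = 5
        d = np.full((n, n), 0.2)
        np.fill_diagonal(d, 0.0)
        tree = clades.nj_tree(
            clades.DistanceMatrix(strains=tuple(f"s{i}" for i in range(n)), d=d)
        )
        lengths = {l.edge.length for l in tree.leaf_node_iter()}
        assert all(abs(l - 0.1) < 1e-12 for l in lengths)

    def test_fewer_than_three_taxa_rejected(self):
        d = np.array([[0, 0.1], [0.1, 0]])
        with pytest.raises(ValueError, match="at least 3"):
            clades.nj_tree(clades.DistanceMatrix(strains=("a", "b"), d=d))

    def test_topology_matches_scikit_bio_on_additive_matrix(self):
        # independent cross-check against another NJ implementation
        skbio = pytest.importorskip("skbio")
        import random

        import dendropy

        # random additive matrix from a random 6-taxon tree via path lengths
        names = [f"t{i}" for i in range(6)]
        tns = dendropy.TaxonNamespace(names)
        source = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0,
            death_rate=0.0,
            num_extant_tips=6,
            taxon_namespace=tns,
            rng=random.Random(7),
        )
        pdm = source.phylogenetic_distance_matrix()
        d = np.zeros((6, 6))
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i != j:
                    d[i, j] = pdm.distance(tns.get_taxon(a), tns.get_taxon(b))
        ours = clades.nj_tree(clades.DistanceMatrix(strains=tuple(names), d=d))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids=names))
        ours_splits = _bipartitions(ours)
        # convert skbio tree to splits over the same leaf set
        all_leaves = frozenset(names)
        their_splits = set()
        for node in theirs.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < 5:
                their_splits.add(min(side, all_leaves - side, key=sorted))
        assert ours_splits == their_splits

    def test_simulated_clades_are_monophyletic(self, small_config):
        # distance tree over clonal clade members: each clade one subtree
        cfg = replace(small_config, n_recombinants=0)
        ds = simulate_dataset(cfg)
        concat = clades.concat_degapped(ds.alignments)
        dm = clades.pdistance(concat)
        tree = clades.nj_tree(dm)
        splits = _bipartitions(tree)
        all_leaves = frozenset(ds.strains)
        for clade in cfg.clade_labels:
            members = frozenset(
                s for s in ds.strains if ds.clade_of[s] == clade
            )
            split = min(members, all_leaves - members, key=sorted)
            assert split in splits


MARKERS = clades.MatMarkers(mat1_1="ATGACGTACGTAGCTT", mat1_2="TTGACCATGGTACGAA")


class TestMatTyping:
    def test_forward_marker_detected(self):
        genome = "AAAA" + MARKERS.mat1_1 + "CCCC"
        assert clades.mat_type(genome, MARKERS) == MAT1_1

    def test_reverse_complement_marker_detected(self):
        genome = "AAAA" + reverse_complement(MARKERS.mat1_2) + "CCCC"
        assert clades.mat_type(genome, MARKERS) == MAT1_2

    def test_both_markers_is_ambiguous(self):
        genome = MARKERS.mat1_1 + "AAAA" + MARKERS.mat1_2
        assert clades.mat_type(genome, MARKERS) == MAT_AMBIGUOUS

    def test_neither_marker_is_unknown(self):
        assert clades.mat_type("ACGT" * 20, MARKERS) == MAT_UNKNOWN

    def test_multiple_contigs_searched(self):
        contigs = ["ACGT" * 5, MARKERS.mat1_1]
        assert clades.mat_type(contigs, MARKERS) == MAT1_1


class TestMatCladeLinkage:
    @staticmethod
    def _assignment(mats):
        labels = {f"s{i}": "C1" for i in range(len(mats))}
        mat = {f"s{i}": m for i, m in enumerate(mats)}
        return CladeAssignment(labels=labels, mat=mat)

    def test_uniform_clade_is_consistent(self):
        report = clades.mat_clade_ld(self._assignment([MAT1_1, MAT1_1]))
        assert report.all_consistent
        assert report.per_clade["C1"] == (MAT1_1,)

    def test_mixed_clade_is_flagged(self):
        report = clades.mat_clade_ld(self._assignment([MAT1_1, MAT1_2]))
        assert not report.all_consistent
        assert report.flagged == ("C1",)

    def test_unknown_is_ignored(self):
        report = clades.mat_clade_ld(self._assignment([MAT1_1, MAT_UNKNOWN]))
        assert report.all_consistent

    def test_simulated_mat_truth_recovered(self, dataset):
        from kojigenomics.synthetic_data import MAT1_1_MARKER, MAT1_2_MARKER

        markers = clades.MatMarkers(mat1_1=MAT1_1_MARKER, mat1_2=MAT1_2_MARKER)
        for strain, contigs in dataset.genomes.items():
            detected = clades.mat_type(list(contigs.values()), markers)
            assert detected == dataset.truth.true_mat[strain]
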