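import dendropy
import numpy as np
import pytest

from _oracles import tree_path_distances, trim_keep_mask
from conftest import random_protein
from wadjetscan.composite_phylo import (
    CompositeAlignment,
    DistanceMatrix,
    RegionSpec,
    bootstrap_support,
    build_composite,
    distance_matrix,
    export_for_ml,
    neighbor_joining,
    read_newick,
    tree_bipartitions,
    trim_gappy_columns,
    write_newick,
)
from wadjetscan.errors import ValidationError
from wadjetscan.seq_io import Alignment, read_fasta
from wadjetscan.synthetic_data import EvolutionSpec, evolve_family, random_join_tree

EIGHT_TAXON_TREE = (
    "((A:0.10,B:0.15):0.15,(C:0.22,D:0.08):0.15,"
    "((E:0.12,F:0.25):0.15,(G:0.18,H:0.05):0.15):0.15);"
)
# the generating tree's five internal splits, normalized like
# tree_bipartitions (the side not containing the smallest taxon label)
TRUE_SPLITS = tree_bipartitions(
    dendropy.Tree.get(data=EIGHT_TAXON_TREE, schema="newick")
)


def _spec(rng, ref_len=300):
    ref = random_protein(rng, ref_len)
    return RegionSpec(
        reference_name="ref",
        reference_seq=ref,
        spans={"headN": (0, 60), "headC": (240, 300), "hinge": (120, 180)},
    )


def _composite_from_rows(names, rows):
    n = len(rows[0])
    thirds = [n // 3, 2 * n // 3]
    return CompositeAlignment(
        alignment=Alignment(names=list(names), rows=list(rows)),
        block_boundaries=[
            ("headN", 0, thirds[0]),
            ("headC", thirds[0], thirds[1]),
            ("hinge", thirds[1], n),
        ],
    )


class TestRegionSpec:
    def test_overlapping_spans_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            RegionSpec(
                reference_name="r",
                reference_seq="A" * 100,
                spans={"headN": (0, 40), "headC": (30, 70), "hinge": (80, 95)},
            )

    def test_span_outside_reference_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            RegionSpec(
                reference_name="r",
                reference_seq="A" * 50,
                spans={"headN": (0, 20), "headC": (30, 60), "hinge": (20, 30)},
            )


class TestExtractRegion:
    def test_reference_member_returns_span_residues(self):
        rng = np.random.default_rng(0)
        spec = _spec(rng)
        from wadjetscan.composite_phylo import extract_region

        frag = extract_region(spec.reference_seq, spec, "hinge")
        assert frag == spec.reference_seq[120:180]

    def test_deletion_inside_span_shortens_fragment(self):
        rng = np.random.default_rng(1)
        spec = _spec(rng)
        from wadjetscan.composite_phylo import extract_region

        member = spec.reference_seq[:140] + spec.reference_seq[145:]
        frag = extract_region(member, spec, "hinge")
        assert len(frag) == 55

    def test_identity_floor_violation_names_member(self):
        rng = np.random.default_rng(2)
        spec = _spec(rng)
        from wadjetscan.composite_phylo import extract_region

        with pytest.raises(ValidationError, match="stranger"):
            extract_region(random_protein(rng, 300), spec, "headN", name="stranger")


class TestBuildComposite:
    def test_identical_members_give_gap_free_composite(self):
        rng = np.random.default_rng(3)
        spec = _spec(rng)
        members = {f"m{i}": spec.reference_seq for i in range(5)}
        caln = build_composite(members, spec)
        assert caln.alignment.n_cols == 60 + 60 + 60
        assert all("-" not in r for r in caln.alignment.rows)
        assert len(caln.block_boundaries) == 3
        assert [b[0] for b in caln.block_boundaries] == ["headN", "headC", "hinge"]

    def test_member_order_is_irrelevant(self):
        leaves = evolve_family(
            EvolutionSpec(root_length=300, tree=EIGHT_TAXON_TREE, seed=8)
        )
        spec = RegionSpec(
            reference_name="A",
            reference_seq=leaves["A"],
            spans={"headN": (0, 60), "headC": (240, 300), "hinge": (120, 180)},
        )
        members = {k: leaves[k] for k in ["B", "C", "D", "E", "F"]}
        a = build_composite(members, spec)
        b = build_composite(dict(reversed(list(members.items()))), spec)
        assert a.alignment == b.alignment

    def test_failing_member_excluded_and_recorded(self):
        rng = np.random.default_rng(5)
        spec = _spec(rng)
        members = {f"m{i}": spec.reference_seq for i in range(4)}
        members["odd"] = random_protein(rng, 250)
        with pytest.warns(UserWarning, match="odd"):
            caln = build_composite(members, spec)
        assert set(caln.excluded) == {"odd"}
        assert "odd" not in caln.alignment.names


class TestTrim:
    def test_strictly_greater_than_cutoff_removed(self):
        rows_col_a = ["A"] * 6 + ["-"] * 4  # 0.40 gaps: removed
        rows_col_b = ["C"] * 7 + ["-"] * 3  # 0.30 gaps: retained
        rows = ["".join(p) for p in zip(rows_col_a, rows_col_b, "DDDDDDDDDD")]
        caln = CompositeAlignment(
            alignment=Alignment(names=[f"s{i}" for i in range(10)], rows=rows),
            block_boundaries=[("headN", 0, 1), ("headC", 1, 2), ("hinge", 2, 3)],
        )
        trimmed = trim_gappy_columns(caln, max_gap=0.30)
        assert trimmed.alignment.n_cols == 2
        assert trimmed.block_boundaries == [("headN", 0, 0), ("headC", 0, 1), ("hinge", 1, 2)]

    def test_gap_free_alignment_unchanged(self):
        caln = _composite_from_rows(["a", "b"], ["MKWVTF", "MKWVTF"])
        assert trim_gappy_columns(caln).alignment == caln.alignment

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_per_column_oracle_and_is_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        n_rows, n_cols = int(rng.integers(2, 12)), int(rng.integers(9, 40))
        rows = []
        for _ in range(n_rows):
            chars = [
                "-" if rng.random() < 0.35 else "ACDEFGHIKLMNPQRSTVWY"[rng.integers(0, 20)]
                for _ in range(n_cols)
            ]
            rows.append("".join(chars))
        keep = trim_keep_mask(rows, 0.30)
        if not any(keep):
            return
        caln = _composite_from_rows([f"s{i}" for i in range(n_rows)], rows)
        trimmed = trim_gappy_columns(caln, max_gap=0.30)
        expected_rows = [
            "".join(c for c, k in zip(r, keep) if k) for r in rows
        ]
        assert trimmed.alignment.rows == expected_rows
        again = trim_gappy_columns(trimmed, max_gap=0.30)
        assert again.alignment == trimmed.alignment
        assert again.block_boundaries == trimmed.block_boundaries

    def test_all_columns_gappy_raises(self):
        caln = _composite_from_rows(["a", "b", "c"], ["A-K", "-L-", "M--"])
        with pytest.raises(ValidationError):
            trim_gappy_columns(caln, max_gap=0.30)


class TestDistanceMatrix:
    def test_identical_rows_distance_zero(self):
        aln = Alignment(names=["a", "b"], rows=["MKWVTF" * 10, "MKWVTF" * 10])
        D = distance_matrix(aln)
        assert D.matrix[0, 1] == 0.0

    def test_half_different_gives_ln2(self):
        a = "A" * 100
        b = "A" * 50 + "C" * 50
        D = distance_matrix(Alignment(names=["a", "b"], rows=[a, b]))
        assert D.matrix[0, 1] == pytest.approx(np.log(2.0))

    def test_saturation_clamped(self):
        a = "A" * 100
        b = "C" * 100
        D = distance_matrix(Alignment(names=["a", "b"], rows=[a, b]))
        assert D.matrix[0, 1] == pytest.approx(-np.log(0.05))

    def test_x_never_matches(self):
        a = "X" * 30 + "A" * 70
        b = "X" * 30 + "A" * 70
        D = distance_matrix(Alignment(names=["a", "b"], rows=[a, b]))
        assert D.matrix[0, 1] == pytest.approx(-np.log(1 - 0.30))

    def test_insufficient_overlap_names_pair(self):
        a = "A" * 49 + "-" * 51
        b = "-" * 51 + "A" * 49
        with pytest.raises(ValidationError, match="49|share"):
            distance_matrix(Alignment(names=["u", "v"], rows=[a, b]))

    def test_symmetry_and_zero_diagonal_exact(self):
        rng = np.random.default_rng(9)
        rows = [random_protein(rng, 120) for _ in range(6)]
        D = distance_matrix(Alignment(names=[f"s{i}" for i in range(6)], rows=rows))
        assert np.array_equal(D.matrix, D.matrix.T)
        assert np.all(np.diag(D.matrix) == 0.0)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = DistanceMatrix(
            names=["a", "b", "c"],
            matrix=np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]]),
        )
        tree = neighbor_joining(D)
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.3)
        assert lengths["c"] == pytest.approx(0.5)

    def test_fewer_than_three_taxa_rejected(self):
        D = DistanceMatrix(names=["a", "b"], matrix=np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValidationError):
            neighbor_joining(D)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_additive_matrix_recovered_exactly(self, n_taxa):
        rng = np.random.default_rng(40 + n_taxa)
        names = [f"t{i}" for i in range(n_taxa)]
        newick = random_join_tree(names, rng, bl_range=(0.05, 0.3))
        true_tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        nm, D = tree_path_distances(true_tree)
        nj = neighbor_joining(DistanceMatrix(names=nm, matrix=D))
        assert tree_bipartitions(nj) == tree_bipartitions(true_tree)
        # exact branch lengths: patristic distances reproduce the input
        nm2, D2 = tree_path_distances(nj)
        assert nm2 == nm
        assert np.allclose(D2, D, atol=1e-9)

    def test_agrees_with_scikit_bio_on_additive_matrix(self):
        import io

        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(77)
        names = [f"t{i}" for i in range(7)]
        newick = random_join_tree(names, rng, bl_range=(0.05, 0.3))
        true_tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        nm, D = tree_path_distances(true_tree)
        mine = neighbor_joining(DistanceMatrix(names=nm, matrix=D))
        other = skbio_nj(SkbioDM(D, ids=nm))
        other_dendropy = dendropy.Tree.get(
            data=str(other), schema="newick", preserve_underscores=True
        )
        assert tree_bipartitions(mine) == tree_bipartitions(other_dendropy)

    def test_taxon_input_order_invariant(self):
        rng = np.random.default_rng(13)
        names = [f"t{i}" for i in range(6)]
        newick = random_join_tree(names, rng, bl_range=(0.05, 0.3))
        true_tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        nm, D = tree_path_distances(true_tree)
        perm = [3, 0, 5, 1, 4, 2]
        D2 = D[np.ix_(perm, perm)]
        nm2 = [nm[i] for i in perm]
        t1 = neighbor_joining(DistanceMatrix(names=nm, matrix=D))
        t2 = neighbor_joining(DistanceMatrix(names=nm2, matrix=D2))
        assert tree_bipartitions(t1) == tree_bipartitions(t2)


class TestSequenceRecovery:
    def test_evolved_eight_taxon_topology_recovered(self):
        leaves = evolve_family(
            EvolutionSpec(root_length=1000, tree=EIGHT_TAXON_TREE, seed=31)
        )
        names = sorted(leaves)
        aln = Alignment(names=names, rows=[leaves[n] for n in names])
        tree = neighbor_joining(distance_matrix(aln))
        assert tree_bipartitions(tree) == TRUE_SPLITS  # RF distance 0

    def test_bootstrap_gives_full_support_on_clean_signal(self):
        leaves = evolve_family(
            EvolutionSpec(root_length=1000, tree=EIGHT_TAXON_TREE, seed=31)
        )
        names = sorted(leaves)
        aln = Alignment(names=names, rows=[leaves[n] for n in names])
        tree = bootstrap_support(aln, reps=100, seed=5)
        supports = [
            float(n.label)
            for n in tree.preorder_node_iter()
            if n is not tree.seed_node and not n.is_leaf() and n.label
        ]
        assert len(supports) == len(TRUE_SPLITS)
        assert all(s == 100.0 for s in supports)

    def test_single_replicate_supports_are_binary(self):
        leaves = evolve_family(
            EvolutionSpec(root_length=400, tree=EIGHT_TAXON_TREE, seed=31)
        )
        names = sorted(leaves)
        aln = Alignment(names=names, rows=[leaves[n] for n in names])
        tree = bootstrap_support(aln, reps=1, seed=2)
        supports = {
            float(n.label)
            for n in tree.preorder_node_iter()
            if n is not tree.seed_node and not n.is_leaf() and n.label
        }
        assert supports <= {0.0, 100.0}

    def test_zero_divergence_alignment_does_not_crash(self):
        aln = Alignment(
            names=["a", "b", "c", "d"], rows=["MKWVTF" * 20] * 4
        )
        tree = bootstrap_support(aln, reps=5, seed=1)
        assert len(list(tree.leaf_node_iter())) == 4


class TestNewickAndExport:
    def test_newick_round_trip_preserves_leaves_and_lengths(self, tmp_path):
        D = DistanceMatrix(
            names=["a", "b", "c", "d"],
            matrix=np.array(
                [
                    [0, 0.3, 0.5, 0.6],
                    [0.3, 0, 0.6, 0.7],
                    [0.5, 0.6, 0, 0.3],
                    [0.6, 0.7, 0.3, 0],
                ]
            ),
        )
        tree = neighbor_joining(D)
        p = tmp_path / "t.nwk"
        write_newick(tree, str(p))
        back = read_newick(str(p))
        assert tree_bipartitions(back) == tree_bipartitions(tree)
        nm1, D1 = tree_path_distances(tree)
        nm2, D2 = tree_path_distances(back)
        assert nm1 == nm2 and np.allclose(D1, D2)

    def test_export_files_are_consistent(self, tmp_path):
        rng = np.random.default_rng(21)
        spec = _spec(rng)
        members = {f"m{i}": spec.reference_seq for i in range(4)}
        caln = trim_gappy_columns(build_composite(members, spec))
        paths = export_for_ml(caln, str(tmp_path / "comp"))

        fasta_back = read_fasta(paths["fasta"])
        assert fasta_back == list(zip(caln.alignment.names, caln.alignment.rows))

        phy_lines = open(paths["phylip"]).read().splitlines()
        n, L = map(int, phy_lines[0].split())
        assert (n, L) == (caln.alignment.n_rows, caln.alignment.n_cols)
        phy_rows = dict(l.split(None, 1) for l in phy_lines[1:])
        assert phy_rows == {
            name: row.strip()
            for name, row in zip(caln.alignment.names, caln.alignment.rows)
        }

        part_lines = open(paths["partitions"]).read().splitlines()
        assert part_lines == [
            f"PROT, {region} = {s + 1}-{e}"
            for region, s, e in caln.block_boundaries
            if e > s
        ]
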