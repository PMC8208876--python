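"""Supermatrix construction, distances, NJ, bootstrap, monophyly."""

import math

import numpy as np
import pandas as pd
import pytest

import mitokit as mk
from mitokit.model import MitokitError
from mitokit.phylo import normalize_gene_symbol


# ---------------------------------------------------------------- blocks

def _blocks():
    return [
        mk.GeneAlignmentBlock("g1", ["A", "B", "C"], ["ACGTACGTAC" * 3] * 3),
        mk.GeneAlignmentBlock("g2", ["A", "B"], ["TTTTGGGGCC" * 6] * 2),
    ]


def test_concatenation_widths_and_partitions():
    sm = mk.concatenate_blocks(_blocks())
    assert sm.width == 90
    assert sm.partitions == [("g1", 1, 30), ("g2", 31, 90)]
    # taxon C is absent from g2: padded with gaps over that partition
    assert sm.rows[sm.taxa.index("C")][30:] == "-" * 60


def test_partition_slicing_round_trip():
    rng = np.random.default_rng(4)
    blocks = []
    taxa = ["t1", "t2", "t3", "t4"]
    for i, w in enumerate([17, 31, 8]):
        rows = ["".join(rng.choice(list("ACGT"), size=w)) for _ in taxa]
        blocks.append(mk.GeneAlignmentBlock(f"b{i}", list(taxa), rows))
    sm = mk.concatenate_blocks(blocks)
    for b in blocks:
        assert sm.block(b.gene_name).rows == b.rows


def test_duplicate_taxon_within_block_rejected():
    with pytest.raises(MitokitError):
        mk.GeneAlignmentBlock("g", ["A", "A"], ["ACGT", "ACGT"])


def test_extract_conserved_pcgs_and_missing_gene():
    genomes, tables = [], []
    for i in range(3):
        g = mk.generate_genome(20_000, seed=50 + i, genome_id=f"tax{i}")
        genomes.append(g)
        tables.append(mk.generate_feature_table(len(g), seed=50 + i, genome_id=g.id))
    sets = mk.extract_conserved_pcgs(genomes, tables, ["ATP8", "CO2", "NAD3"])
    assert set(sets) == {"ATP8", "COX2", "NAD3"}  # CO2 normalised to COX2
    assert all(len(d) == 3 for d in sets.values())
    # a taxon lacking one gene drops from that block only
    tables[1] = mk.FeatureTable(
        "tax1", [f for f in tables[1] if f.name != "ATP8"]
    )
    sets = mk.extract_conserved_pcgs(genomes, tables, ["ATP8", "NAD3"])
    assert set(sets["ATP8"]) == {"tax0", "tax2"}
    assert set(sets["NAD3"]) == {"tax0", "tax1", "tax2"}
    # extraction composes splice_feature gene by gene
    assert sets["NAD3"]["tax0"] == mk.splice_feature(
        genomes[0], tables[0].by_name("NAD3")
    )


def test_gene_symbol_normalization():
    assert normalize_gene_symbol("CO2") == "COX2"
    assert normalize_gene_symbol("nad4l") == "NAD4L"
    assert normalize_gene_symbol("Cytb") == "COB"


# ---------------------------------------------------------------- distances

def test_distance_examples():
    rows = ["A" * 100, "A" * 99 + "C"]
    sm = mk.Supermatrix(["x", "y"], rows)
    d_p = mk.distance_matrix(sm, "p")
    assert d_p.loc["x", "y"] == pytest.approx(0.01)
    d_jc = mk.distance_matrix(sm, "jc69")
    assert d_jc.loc["x", "y"] == pytest.approx(-0.75 * math.log(1 - 4 * 0.01 / 3))
    ident = mk.Supermatrix(["x", "y"], ["ACGT", "ACGT"])
    assert mk.distance_matrix(ident).loc["x", "y"] == 0.0


def test_pairwise_deletion_excludes_gapped_sites():
    sm = mk.Supermatrix(["x", "y"], ["ACG-TN", "ACGCTA"])
    # comparable sites: 1,2,3,5 -> no differences
    assert mk.distance_matrix(sm).loc["x", "y"] == 0.0


def test_distance_matrix_brute_force_recount():
    rng = np.random.default_rng(8)
    taxa = [f"t{i}" for i in range(5)]
    ancestor = rng.choice(list("ACGT"), size=200)
    rows = []
    for _ in taxa:
        row = ancestor.copy()
        mut = rng.random(200) < 0.1
        row[mut] = rng.choice(list("ACGT"), size=int(mut.sum()))
        missing = rng.random(200) < 0.06
        row[missing] = rng.choice(["-", "N"], size=int(missing.sum()))
        rows.append("".join(row))
    sm = mk.Supermatrix(taxa, rows)
    D = mk.distance_matrix(sm, "p")
    for i in range(5):
        assert D.iloc[i, i] == 0.0
        for j in range(i + 1, 5):
            diffs = comparable = 0
            for a, b in zip(rows[i], rows[j]):
                if a in "ACGT" and b in "ACGT":
                    comparable += 1
                    diffs += a != b
            assert D.iloc[i, j] == pytest.approx(diffs / comparable)
            assert D.iloc[j, i] == D.iloc[i, j]
    # JC69 >= p elementwise where defined
    J = mk.distance_matrix(sm, "jc69")
    assert (J.to_numpy() >= D.to_numpy() - 1e-12).all()


def test_no_comparable_sites_errors():
    sm = mk.Supermatrix(["x", "y"], ["AC--", "--GT"])
    with pytest.raises(MitokitError):
        mk.distance_matrix(sm)


# ---------------------------------------------------------------- NJ

def _additive_matrix_from_random_tree(rng, n_taxa):
    """Random binary tree with positive edge lengths -> path-length matrix."""
    import dendropy

    taxa = [f"t{i}" for i in range(n_taxa)]
    nodes = [f"{t}:{rng.uniform(0.05, 1.0):.4f}" for t in taxa]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.05, 1.0):.4f}"
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [merged]
    newick = f"({nodes[0]},{nodes[1]});"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    D = pd.DataFrame(0.0, index=labels, columns=labels)
    for a in tree.taxon_namespace:
        for b in tree.taxon_namespace:
            D.loc[a.label, b.label] = pdm.patristic_distance(a, b)
    return newick, D


@pytest.mark.parametrize("seed", range(8))
def test_nj_recovers_additive_trees(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    newick, D = _additive_matrix_from_random_tree(rng, n)
    got = mk.nj_tree(D)
    want = mk.PhyloTree.from_newick(newick)
    assert got.bipartitions() == want.bipartitions()
    # branch lengths are recovered too: pairwise path lengths match
    import dendropy

    pdm = got.dendropy_tree.phylogenetic_distance_matrix()
    ns = got.dendropy_tree.taxon_namespace
    for a in ns:
        for b in ns:
            assert pdm.patristic_distance(a, b) == pytest.approx(
                D.loc[a.label, b.label], abs=1e-6
            )


def test_nj_matches_scikit_bio_on_random_matrices():
    # independent implementation cross-check
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(77)
    for _ in range(5):
        n = 6
        taxa = [f"t{i}" for i in range(n)]
        M = rng.uniform(0.05, 1.0, size=(n, n))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0.0)
        ours = mk.nj_tree(pd.DataFrame(M, index=taxa, columns=taxa))
        theirs = mk.PhyloTree.from_newick(str(skbio_nj(DistanceMatrix(M, ids=taxa))))
        assert ours.bipartitions() == theirs.bipartitions()


def test_two_taxon_tree_convention():
    D = pd.DataFrame([[0, 0.4], [0.4, 0]], index=["a", "b"], columns=["a", "b"])
    t = mk.nj_tree(D)
    assert sorted(t.leaf_labels()) == ["a", "b"]
    total = sum(
        lf.edge.length for lf in t.dendropy_tree.leaf_node_iter()
    )
    assert total == pytest.approx(0.4)


def test_negative_branch_lengths_clamped():
    # a decidedly non-additive matrix
    taxa = ["a", "b", "c", "d"]
    M = np.array(
        [[0, 0.1, 0.9, 0.9], [0.1, 0, 0.05, 0.9], [0.9, 0.05, 0, 0.1], [0.9, 0.9, 0.1, 0]]
    )
    t = mk.nj_tree(pd.DataFrame(M, index=taxa, columns=taxa))
    for edge in t.dendropy_tree.preorder_edge_iter():
        if edge.length is not None:
            assert edge.length >= 0.0


# ---------------------------------------------------------------- bootstrap & monophyly

def _clade_supermatrix(seed=11):
    tree = (
        "(((A:0.02,B:0.02):0.25,(C:0.02,D:0.02):0.25):0.02,"
        "(E:0.02,F:0.02):0.25);"
    )
    _, sm = mk.simulate_supermatrix(tree, [400, 300, 300], seed=seed)
    return sm


def test_bootstrap_reproducible_and_supported():
    sm = _clade_supermatrix()
    t1 = mk.bootstrap(sm, n_reps=100, seed=5)
    t2 = mk.bootstrap(sm, n_reps=100, seed=5)
    assert t1.as_newick() == t2.as_newick()
    assert t1.has_split({"A", "B"})
    supports = [
        float(n.label)
        for n in t1.dendropy_tree.preorder_node_iter()
        if not n.is_leaf() and n.parent_node is not None and n.label
    ]
    assert supports and min(supports) >= 50.0


def test_monophyly_judged_against_outgroup():
    sm = _clade_supermatrix()
    tree = mk.nj_tree(mk.distance_matrix(sm))
    assert mk.is_monophyletic(tree, {"A", "B"}, "F")
    assert mk.is_monophyletic(tree, {"A", "B", "C", "D"}, "F")
    assert not mk.is_monophyletic(tree, {"A", "C"}, "F")
    with pytest.raises(MitokitError):
        mk.is_monophyletic(tree, {"A", "B"}, "nope")
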