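"""Alignment distances, neighbor-joining, newick round-trips, tree export."""

import shutil

import numpy as np
import pytest

from regmech.phylo import (
    DistanceMatrix,
    EngineUnavailableError,
    FamilyMember,
    FamilySelection,
    Tree,
    build_distance_matrix,
    build_family_tree,
    export_tree_bundle,
    nj_tree,
    pairwise_distance,
    run_external_pipeline,
    select_family,
)

from _oracle import enumerate_alignment_best

TOY = dict(matrix=(2, -1), gap_open=3, gap_extend=1)


def test_identical_sequences_have_distance_zero():
    assert pairwise_distance("MKVLAWYT", "MKVLAWYT") == 0.0
    assert pairwise_distance("AAAA", "AAAA", **TOY) == 0.0


def test_fully_mismatched_sequences_have_distance_one():
    assert pairwise_distance("AAAA", "TTTT", **TOY) == 1.0


def test_distance_symmetric_and_bounded():
    rng = np.random.default_rng(3)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(25):
        a = "".join(rng.choice(aas, size=rng.integers(3, 30)))
        b = "".join(rng.choice(aas, size=rng.integers(3, 30)))
        d_ab = pairwise_distance(a, b)
        d_ba = pairwise_distance(b, a)
        assert d_ab == pytest.approx(d_ba)
        assert 0.0 <= d_ab <= 1.0


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        pairwise_distance("", "MKV")


def test_alignment_matches_exhaustive_enumeration_small():
    from regmech._align import align_stats

    rng = np.random.default_rng(4)
    alphabet = list("ACGT")
    for _ in range(150):
        a = "".join(rng.choice(alphabet, size=rng.integers(1, 6)))
        b = "".join(rng.choice(alphabet, size=rng.integers(1, 6)))
        got = align_stats(a, b, **TOY)
        want = enumerate_alignment_best(a, b, 2, -1, 3, 1)
        assert got == want, (a, b)


def test_nj_three_taxon_closed_form():
    dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0.0]]))
    tree = nj_tree(dm)
    lengths = {t.name: t.length for t in tree.root.tips()}
    assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})


def test_nj_two_taxa_single_edge():
    tree = nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 0.42], [0.42, 0.0]])))
    d = tree.tip_distances()
    assert float(d.d[0, 1]) == pytest.approx(0.42)


def _random_additive_tree(rng, n):
    """Random binary tree with positive branch lengths; returns (Tree, DistanceMatrix)."""
    from skbio import TreeNode

    nodes = [TreeNode(name=f"T{i}") for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(0.1, 2.0))
        b.length = float(rng.uniform(0.1, 2.0))
        parent = TreeNode(children=[b, a])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    for x in nodes:
        x.length = float(rng.uniform(0.1, 2.0))
    root = TreeNode(children=nodes)
    tree = Tree(root)
    dm = tree.tip_distances()
    order = sorted(range(len(dm.ids)), key=lambda k: dm.ids[k])
    return tree, DistanceMatrix(
        [dm.ids[k] for k in order], dm.d[np.ix_(order, order)]
    )


def test_nj_recovers_additive_six_taxon_trees():
    rng = np.random.default_rng(5)
    for _ in range(10):
        true_tree, dm = _random_additive_tree(rng, 6)
        est = nj_tree(dm)
        rf = est.root.compare_rfd(true_tree.root)
        assert rf == 0.0
        d_est = est.tip_distances()
        idx = {name: k for k, name in enumerate(d_est.ids)}
        perm = [idx[name] for name in dm.ids]
        assert np.allclose(d_est.d[np.ix_(perm, perm)], dm.d, atol=1e-9)


def test_nj_invariant_under_taxon_permutation():
    rng = np.random.default_rng(6)
    _true, dm = _random_additive_tree(rng, 7)
    t1 = nj_tree(dm)
    perm = rng.permutation(len(dm.ids))
    dm2 = DistanceMatrix(
        [dm.ids[k] for k in perm], dm.d[np.ix_(perm, perm)]
    )
    t2 = nj_tree(dm2)
    assert t1.root.compare_rfd(t2.root) == 0.0


def test_nj_agrees_with_reference_implementation():
    """Cross-check against scikit-bio's neighbor joining on a generic
    (non-additive) random distance matrix."""
    import skbio
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(12)
    n = 8
    ids = [f"S{i}" for i in range(n)]
    d = np.round(rng.uniform(0.2, 1.0, size=(n, n)), 3)
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    ours = nj_tree(DistanceMatrix(ids, d))
    ref = skbio_nj(skbio.DistanceMatrix(d, ids))
    assert ours.root.compare_rfd(ref) == 0.0


def test_nj_rejects_bad_matrices():
    with pytest.raises(ValueError):
        DistanceMatrix(["A", "B"], np.array([[0, 1], [2, 0.0]]))  # asymmetric
    with pytest.raises(ValueError):
        DistanceMatrix(["A", "B"], np.array([[-1, 1], [1, 0.0]]))  # bad diagonal


def test_newick_round_trip_identity():
    nwk = "((A:0.123456,B:0.5):0.25,C:1.0,(D:0.1,E:0.2):0.3);"
    tree = Tree.from_newick(nwk)
    again = Tree.from_newick(tree.newick)
    assert again.root.compare_rfd(tree.root) == 0.0
    d1, d2 = tree.tip_distances(), again.tip_distances()
    idx = {name: k for k, name in enumerate(d2.ids)}
    perm = [idx[name] for name in d1.ids]
    assert np.allclose(d1.d, d2.d[np.ix_(perm, perm)], atol=1e-6)


def _selection(n=5, seed=0):
    rng = np.random.default_rng(seed)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    base = "".join(rng.choice(aas, size=80))
    members = []
    for i in range(n):
        seq = list(base)
        for p in rng.choice(80, size=5 + 3 * i, replace=False):
            seq[p] = aas[int(rng.integers(20))]
        members.append(
            FamilyMember(
                protein_id=f"B{i}|g0|0|+1",
                sequence="".join(seq),
                source="MIBiG",
                product_class="NRP",
                mechanism="OCS",
            )
        )
    return FamilySelection(accession="PF00196", members=members)


def test_build_family_tree_internal_route():
    sel = _selection()
    tree = build_family_tree(sel)
    assert sorted(tree.leaf_names) == sorted(sel.ids)


def test_select_family_and_co_require(registry):
    from conftest import build_bgc
    from regmech.classify import classify_bgcs
    from regmech.io_bgc import protein_id

    specs = [
        ({"PF02518", "PF00512"}, 1),
        ({"PF00512"}, 1),
        ({"PF00196"}, -1),
    ]
    bgc, archs = build_bgc(specs, bgc_id="B9")
    anns, _ = classify_bgcs([bgc], archs)
    seqs = {protein_id(bgc.bgc_id, g): g.translation for g in bgc.genes}
    # NB: a lone DHp gene is not an HK, hence not annotated -> not selectable
    sel = select_family(anns, archs, seqs, "PF00512")
    assert len(sel.members) == 1
    sel = select_family(anns, archs, seqs, "PF00512", co_require=["PF02518"])
    assert len(sel.members) == 1
    sel = select_family(anns, archs, seqs, "PF00196", co_require=["PF00072"])
    assert sel.members == []
    with pytest.raises(ValueError, match="registry"):
        select_family(anns, archs, seqs, "PF99999")


def test_export_tree_bundle_round_trip(tmp_path):
    sel = _selection()
    tree = build_family_tree(sel)
    nwk, csv = export_tree_bundle(tree, sel, tmp_path / "fam")
    leaves = set(Tree.from_newick(nwk.read_text()).leaf_names)
    ids = {line.split(",")[0] for line in csv.read_text().splitlines()[1:]}
    assert leaves == ids == set(sel.ids)


def test_export_tree_bundle_missing_metadata_names_offender(tmp_path):
    sel = _selection()
    tree = build_family_tree(sel)
    import re

    short = FamilySelection(accession=sel.accession, members=sel.members[:-1])
    with pytest.raises(ValueError, match=re.escape(sel.members[-1].protein_id)):
        export_tree_bundle(tree, short, tmp_path / "fam")


def test_external_pipeline_engine_missing_suggests_internal_route():
    sel = _selection(3)
    with pytest.raises(EngineUnavailableError, match="internal"):
        run_external_pipeline(sel, aligner_cmd=("definitely-not-a-binary", "{in}"))


def test_external_pipeline_requires_three_members():
    with pytest.raises(ValueError, match="at least 3"):
        run_external_pipeline(_selection(2))


@pytest.mark.skipif(
    shutil.which("mafft") is None or shutil.which("fasttree") is None,
    reason="external aligner / FastTree not on PATH",
)
def test_external_pipeline_with_installed_engines():
    sel = _selection(5)
    tree = run_external_pipeline(
        sel, aligner_cmd=("mafft", "--quiet", "--auto", "{in}")
    )
    assert tree.provenance == "external"
    assert sorted(tree.leaf_names) == sorted(sel.ids)
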