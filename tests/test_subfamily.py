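import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

import oracles
from marinerscan.io_formats import PanelRecord
from marinerscan.subfamily_classification import (
    ClassifyParams,
    build_distance_tree,
    center_star_msa,
    clade_assign,
    distance_matrix,
    encode_msa,
    identity_cluster,
    neighbor_joining,
    pairwise_identity,
    root_on_outgroup,
)


def _dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _mutate(rng, seq, frac):
    out = list(seq)
    for p in rng.choice(len(seq), size=int(frac * len(seq)), replace=False):
        out[p] = "ACGT"[(("ACGT".index(out[p])) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def test_identity_of_identical_sequences(rng):
    s = _dna(rng, 1000)
    assert pairwise_identity(s, s) == 1.0


def test_identity_after_100_of_1000_substitutions(rng):
    s = _dna(rng, 1000)
    m = _mutate(rng, s, 0.10)
    assert abs(pairwise_identity(s, m) - 0.90) < 0.02


def test_identity_is_symmetric(rng):
    a, b = _dna(rng, 300), _dna(rng, 280)
    assert pairwise_identity(a, b) == pairwise_identity(b, a)


@pytest.mark.parametrize("trial", range(8))
def test_identity_equals_dp_oracle(trial):
    rng = np.random.default_rng(40 + trial)
    a = _dna(rng, int(rng.integers(120, 300)))
    b = _mutate(rng, a, float(rng.uniform(0.02, 0.25)))[: int(rng.integers(100, 300))]
    assert abs(pairwise_identity(a, b) - oracles.global_identity(a, b)) < 1e-12


@pytest.fixture(scope="module")
def labeled_refs():
    rng = np.random.default_rng(77)
    mau, ver = _dna(rng, 1000), _dna(rng, 1000)
    refs = [
        PanelRecord("Mau_ref", mau, subfamily="Mauritiana", role="phylo_reference"),
        PanelRecord("Ver_ref", ver, subfamily="Vertumana", role="phylo_reference"),
    ]
    return rng, mau, ver, refs


def test_identity_rule_assigns_close_element(labeled_refs):
    rng, mau, _, refs = labeled_refs
    elem = _mutate(rng, mau, 0.08)
    out = identity_cluster([("e", elem)], refs)
    assert out["e"].subfamily == "Mauritiana"
    assert out["e"].method == "identity_rule"


def test_identity_rule_tir_fallback(labeled_refs):
    rng, _, _, refs = labeled_refs
    elem = _dna(rng, 1000)  # unrelated full sequence
    consensi = {"Vertumana": "ACGTTGCACGGATCCGTACGTAGCATC"}
    tirs = {"e": "ACGTTGCACGGATCCGTACGTAGCATC"}
    out = identity_cluster([("e", elem)], refs, element_tirs=tirs,
                           tir_consensi=consensi)
    assert out["e"].subfamily == "Vertumana"


def test_identity_rule_defers_distant_elements(labeled_refs):
    rng, mau, _, refs = labeled_refs
    elem = _mutate(rng, mau, 0.45)
    out = identity_cluster([("e", elem)], refs)
    assert out["e"].subfamily is None
    assert out["e"].method == "unassigned"


def _tree_distances(tree):
    tips = list(tree.tips())
    out = {}
    for i, a in enumerate(tips):
        for b in tips[i + 1:]:
            out[(a.name, b.name)] = a.distance(b)
    return out


def test_nj_exact_on_additive_four_taxon_matrix():
    # additive distances of the tree ((A:2,B:3):1,(C:4,D:5):1)
    names = ["A", "B", "C", "D"]
    D = np.array([[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float)
    tree = neighbor_joining(D, names)
    dists = _tree_distances(tree)
    for (x, y), d in dists.items():
        i, j = names.index(x), names.index(y)
        assert abs(d - D[i, j]) < 1e-9


@pytest.mark.parametrize("trial", range(5))
def test_nj_topology_matches_independent_implementation(trial):
    rng = np.random.default_rng(200 + trial)
    n = 6
    # random additive matrix from a random tree: build via random bifurcation
    coords = rng.random((n, 4)) * 10
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = np.abs(coords[i] - coords[j]).sum()
    names = [f"t{i}" for i in range(n)]
    mine = neighbor_joining(D, names)
    ref = skbio_nj(DistanceMatrix(D, names))
    assert mine.compare_rfd(ref) == 0.0


def test_root_on_outgroup_splits_leaf_edge():
    tree = TreeNode.read(["((A:1,B:1):1,(C:1,OG:4):1);"])
    rooted = root_on_outgroup(tree, "OG")
    assert len(rooted.children) == 2
    names = {c.name for c in rooted.children if c.is_tip()}
    assert "OG" in names


def test_center_star_msa_columns_consistent(rng):
    base = _dna(rng, 200)
    seqs = [base, _mutate(rng, base, 0.05), _mutate(rng, base, 0.1)[:180]]
    msa = center_star_msa(seqs)
    assert len({len(r) for r in msa}) == 1
    for row, orig in zip(msa, seqs):
        assert row.replace("-", "") == orig


def test_distance_models_orderings(rng):
    base = _dna(rng, 500)
    msa = center_star_msa([base, _mutate(rng, base, 0.05), _mutate(rng, base, 0.2)])
    enc = encode_msa(msa)
    p = distance_matrix(enc, "p-distance")
    jc = distance_matrix(enc, "JC69")
    k2p = distance_matrix(enc, "K2P")
    assert p[0, 1] < p[0, 2]
    # model corrections expand distances
    assert jc[0, 2] >= p[0, 2]
    assert k2p[0, 2] >= p[0, 2] - 1e-9
    assert np.allclose(p, p.T)


def test_two_subfamily_simulation_forms_supported_clades():
    """Two planted subfamilies must come out as disjoint clades with high
    bootstrap support when intra-divergence is far below inter-divergence."""
    rng = np.random.default_rng(17)
    ancestor = _dna(rng, 1300)
    mau_c = _mutate(rng, ancestor, 0.22)
    dro_c = _mutate(rng, ancestor, 0.22)
    entries = []
    for name, cons in (("Mau", mau_c), ("Dro", dro_c)):
        for r in range(4):
            entries.append((f"{name}{r}", _mutate(rng, cons, 0.05)))
    # the outgroup descends from the same ancestor at much larger distance,
    # so it is alignable and attaches outside both subfamily clades
    entries.append(("OG", _mutate(rng, ancestor, 0.45)))
    params = ClassifyParams(n_bootstrap=200, outgroup_id="OG")
    res = build_distance_tree(entries, params, np.random.default_rng(5))
    mau = frozenset(f"Mau{r}" for r in range(4))
    dro = frozenset(f"Dro{r}" for r in range(4))
    assert res.supports.get(mau, 0.0) >= 0.95
    assert res.supports.get(dro, 0.0) >= 0.95


def test_clade_assign_labels_and_conflicts():
    tree = TreeNode.read([
        "((e1:0.1,RefDro:0.1):0.2,((e2:0.1,RefMau:0.1):0.1,RefVer:0.2):0.2,OG:1.0);"
    ])
    from marinerscan.subfamily_classification import (
        DistanceTreeResult,
        SubfamilyAssignment,
    )
    result = DistanceTreeResult(tree=tree, supports={}, msa=[], ids=[])
    assignments = {
        "e1": SubfamilyAssignment("e1", None, "unassigned"),
        "e2": SubfamilyAssignment("e2", None, "unassigned"),
    }
    labels = {"RefDro": "Drosophila", "RefMau": "Mauritiana",
              "RefVer": "Vertumana"}
    out = clade_assign(result, labels, assignments)
    assert out["e1"].subfamily == "Drosophila"
    assert out["e2"].subfamily == "Mauritiana"


def test_label_permutation_invariance(labeled_refs):
    rng, mau, ver, refs = labeled_refs
    elems = [("e1", _mutate(rng, mau, 0.08)), ("e2", _mutate(rng, ver, 0.08))]
    out1 = identity_cluster(elems, refs)
    swapped = [
        PanelRecord(r.seq_id, r.sequence,
                    subfamily={"Mauritiana": "Vertumana",
                               "Vertumana": "Mauritiana"}[r.subfamily],
                    role=r.role)
        for r in refs
    ]
    out2 = identity_cluster(elems, swapped)
    assert out2["e1"].subfamily == "Vertumana"
    assert out2["e2"].subfamily == "Mauritiana"
    assert out1["e1"].subfamily == "Mauritiana"
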