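"""Graph construction: static/dynamic edges, geometry, basis functions."""

import numpy as np
import pytest
from scipy.integrate import quad

from rnadiff import graph as G
from rnadiff import structure as S
from rnadiff import synthetic as syn
from rnadiff import diffusion as DF

from conftest import random_rotation


@pytest.fixture(scope="module")
def coarse_hairpin():
    st, ss = syn.make_hairpin(4, 4)
    return S.coarse_grain(st), ss


# ---------------------------------------------------------------------------
# Static edges
# ---------------------------------------------------------------------------

def test_single_purine_residue_covalent_edges():
    st, _ = syn.make_helix("G")
    one = S.coarse_grain(S.RnaStructure([st.chains[0]], name="one"))
    edges = G.build_static_edges(one)
    assert len(edges) == 5
    assert all(e.cls == G.COVALENT for e in edges)
    # P-C4', C4'-N9, and the N9/C2/C6 triangle
    names = [n.atom_name for n in G.enumerate_nodes(one)[0]]
    pairs = {frozenset((names[e.i], names[e.j])) for e in edges}
    assert pairs == {frozenset(p) for p in
                     [("P", "C4'"), ("C4'", "N9"), ("N9", "C2"),
                      ("C2", "C6"), ("C6", "N9")]}


def test_backbone_edge_between_consecutive_residues():
    st, _ = syn.make_helix("GC")
    two = S.coarse_grain(S.RnaStructure([st.chains[0]], name="two"))
    edges = G.build_static_edges(two)
    assert len(edges) == 2 * 5 + 1
    names = [n.atom_name for n in G.enumerate_nodes(two)[0]]
    cross = [e for e in edges
             if {names[e.i], names[e.j]} == {"C4'", "P"}
             and abs(e.i - e.j) > 3]
    assert len(cross) == 1


def test_pairing_edges_two_per_pair():
    st, ss = syn.make_helix("GCAU")
    cg = S.coarse_grain(st)
    edges = G.build_static_edges(cg, ss)
    pairing = [e for e in edges if e.cls == G.PAIRING]
    assert len(pairing) == 2 * len(ss.pairs) == 8


def test_pairing_edge_out_of_range_raises(coarse_hairpin):
    cg, _ = coarse_hairpin
    bad = S.SecondaryStructure(pairs={(0, 99)})
    with pytest.raises(IndexError):
        G.build_static_edges(cg, bad)


# ---------------------------------------------------------------------------
# Dynamic edges
# ---------------------------------------------------------------------------

def test_two_atoms_local_edge():
    coords = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
    edges = G.build_dynamic_edges(coords, [])
    assert [(e.i, e.j, e.cls) for e in edges] == [(0, 1, G.LOCAL)]


def test_two_atoms_global_edge():
    coords = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
    edges = G.build_dynamic_edges(coords, [])
    assert [(e.i, e.j, e.cls) for e in edges] == [(0, 1, G.GLOBAL)]


def test_two_atoms_beyond_cutoff_no_edge():
    coords = np.array([[0.0, 0.0, 0.0], [17.0, 0.0, 0.0]])
    assert G.build_dynamic_edges(coords, []) == []


def test_static_pairs_excluded_from_dynamic():
    coords = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
    static = [G.Edge(0, 1, G.COVALENT)]
    assert G.build_dynamic_edges(coords, static) == []


def test_degree_cap_twenty_local_neighbors(rng):
    """Dense cluster: the central atom keeps exactly 20 local neighbors."""
    n_outer = 24
    phi = np.arccos(1 - 2 * (np.arange(n_outer) + 0.5) / n_outer)
    theta = np.pi * (1 + 5**0.5) * np.arange(n_outer)
    shell = 4.5 * np.stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)], axis=1)
    coords = np.vstack([[0.0, 0.0, 0.0], shell])
    edges = G.build_dynamic_edges(coords, [])
    local_deg0 = sum(1 for e in edges
                     if e.cls == G.LOCAL and 0 in (e.i, e.j))
    assert local_deg0 == 20


def test_dynamic_edges_per_class_degree_bounded(rng):
    coords = rng.uniform(-8, 8, size=(80, 3))
    edges = G.build_dynamic_edges(coords, [])
    for cls in (G.LOCAL, G.GLOBAL):
        deg = np.zeros(80, int)
        for e in edges:
            if e.cls == cls:
                deg[e.i] += 1
                deg[e.j] += 1
        assert deg.max() <= 20


def test_dynamic_edges_distance_windows(rng):
    for trial in range(10):
        coords = rng.uniform(-10, 10, size=(40, 3))
        edges = G.build_dynamic_edges(coords, [])
        for e in edges:
            d = np.linalg.norm(coords[e.i] - coords[e.j])
            if e.cls == G.LOCAL:
                assert d <= 5.0
            else:
                assert 5.0 < d <= 16.0


def test_dynamic_edges_rigid_motion_invariant(rng):
    coords = rng.uniform(-10, 10, size=(50, 3))
    moved = coords @ random_rotation(rng).T + np.array([3.0, -7.0, 11.0])
    a = {(e.i, e.j, e.cls) for e in G.build_dynamic_edges(coords, [])}
    b = {(e.i, e.j, e.cls) for e in G.build_dynamic_edges(moved, [])}
    assert a == b


def test_no_class_overlap(rng):
    coords = rng.uniform(-6, 6, size=(30, 3))
    edges = G.build_dynamic_edges(coords, [])
    seen = {}
    for e in edges:
        key = (e.i, e.j)
        assert key not in seen
        seen[key] = e.cls


# ---------------------------------------------------------------------------
# Edge geometry
# ---------------------------------------------------------------------------

def _graph_for(coords, edges):
    nodes = [G.NodeInfo("C4'", "C", k, "G", True) for k in range(len(coords))]
    return G.RnaGraph(nodes=nodes, edges=edges)


def test_collinear_theta_is_pi():
    coords = np.array([[0.0, 0, 0], [2.0, 0, 0], [4.0, 0, 0]])
    g = _graph_for(coords, [G.Edge(0, 1, G.LOCAL), G.Edge(1, 2, G.LOCAL)])
    G.edge_geometry(g, coords)
    f = g.edge_features[(1, 0)]  # edge 1->0; other neighbor of 1 is 2
    np.testing.assert_allclose(f.thetas, [np.pi], atol=1e-12)


def test_right_angle_theta():
    coords = np.array([[2.0, 0, 0], [0.0, 0, 0], [0.0, 2.0, 0]])
    g = _graph_for(coords, [G.Edge(0, 1, G.LOCAL), G.Edge(1, 2, G.LOCAL)])
    G.edge_geometry(g, coords)
    np.testing.assert_allclose(g.edge_features[(1, 0)].thetas, [np.pi / 2],
                               atol=1e-12)


def test_angles_match_arccos_oracle(rng):
    coords = rng.normal(scale=2.0, size=(4, 3))
    edges = [G.Edge(0, 1, G.LOCAL), G.Edge(1, 2, G.LOCAL),
             G.Edge(2, 3, G.LOCAL)]
    g = _graph_for(coords, edges)
    G.edge_geometry(g, coords)

    def ang(u, v):
        return float(np.arccos(np.clip(
            np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v), -1, 1)))

    # directed edge 1 -> 0: theta at source 1 w.r.t. neighbor 2
    f = g.edge_features[(1, 0)]
    np.testing.assert_allclose(
        f.thetas, [ang(coords[0] - coords[1], coords[2] - coords[1])],
        atol=1e-9)
    # phi: (1->0) against two-hop edge (2->3)
    np.testing.assert_allclose(
        f.phis, [ang(coords[1] - coords[0], coords[3] - coords[2])],
        atol=1e-9)


def test_global_edges_distance_only(rng):
    coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
    g = _graph_for(coords, [G.Edge(0, 1, G.GLOBAL)])
    G.edge_geometry(g, coords)
    f = g.edge_features[(0, 1)]
    assert f.sbf is None and len(f.thetas) == 0
    assert f.d == pytest.approx(10.0)


def test_coincident_atoms_raise():
    coords = np.zeros((2, 3))
    g = _graph_for(coords, [G.Edge(0, 1, G.LOCAL)])
    with pytest.raises(ValueError):
        G.edge_geometry(g, coords)


def test_vectorized_features_match_reference(coarse_hairpin):
    cg, ss = coarse_hairpin
    _, coords = G.enumerate_nodes(cg)
    static = G.build_static_edges(cg, ss)
    dyn = G.build_dynamic_edges(coords, static)
    g = G.RnaGraph(nodes=G.enumerate_nodes(cg)[0], edges=static + dyn)
    G.edge_geometry(g, coords)
    src, dst, feats = G.close_edge_feature_matrix(g.edges, coords)
    for k in range(len(src)):
        f = g.edge_features[(int(src[k]), int(dst[k]))]
        np.testing.assert_allclose(feats[k, :16], f.rbf, atol=1e-9)
        if len(f.thetas):
            sbf_ref = np.outer(G.angular_basis(f.thetas).sum(axis=1), f.rbf)
        else:
            sbf_ref = np.zeros((7, 16))
            sbf_ref[0] = f.rbf
        np.testing.assert_allclose(feats[k, 16:128].reshape(7, 16), sbf_ref,
                                   atol=1e-8)
        phi_ref = (G.angular_basis(f.phis).sum(axis=1) if len(f.phis)
                   else np.zeros(7))
        np.testing.assert_allclose(feats[k, 128:], phi_ref, atol=1e-8)


# ---------------------------------------------------------------------------
# Basis functions
# ---------------------------------------------------------------------------

def test_rbf_zero_at_cutoff():
    np.testing.assert_array_equal(G.radial_basis(5.0, 5.0), np.zeros(16))


def test_rbf_finite_near_zero():
    vals = G.radial_basis(1e-9, 5.0)
    assert np.all(np.isfinite(vals))
    np.testing.assert_allclose(
        vals, np.sqrt(2 / 5.0) * np.arange(1, 17) * np.pi / 5.0, rtol=1e-6)


def test_unenveloped_bessel_orthonormality():
    """Quadrature oracle: int b_m b_n d^2 over [0, c] equals delta_mn."""
    c = 5.0
    for m in (1, 3, 7):
        for n in (1, 3, 7, 12):
            f = lambda d: (np.sqrt(2 / c) * np.sin(m * np.pi * d / c) / d
                           * np.sqrt(2 / c) * np.sin(n * np.pi * d / c) / d
                           * d * d)
            val, _ = quad(f, 0, c)
            assert val == pytest.approx(1.0 if m == n else 0.0, abs=1e-9)


def test_basis_expand_shapes_and_zero_theta():
    rbf, sbf = G.basis_expand(2.0, np.array([0.3, 1.1]), 5.0)
    assert rbf.shape == (16,) and sbf.shape == (7, 16)
    rbf2, sbf2 = G.basis_expand(8.0, None, 16.0)
    assert sbf2 is None and rbf2.shape == (16,)


def test_basis_expand_beyond_cutoff_is_zero():
    rbf, _ = G.basis_expand(5.0, None, 5.0)
    np.testing.assert_array_equal(rbf, 0.0)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _zero_embeddings(structure):
    return np.zeros((structure.n_residues, G.SEQ_EMB_DIM))


def test_assemble_node_count(coarse_hairpin):
    cg, ss = coarse_hairpin
    g = G.assemble_graph(cg, ss, _zero_embeddings(cg),
                         DF.time_embedding(0, T=10))
    assert g.node_count == 5 * cg.n_residues


def test_assemble_node_count_missing_5prime_p(coarse_hairpin):
    cg, ss = coarse_hairpin
    st = cg.copy()
    del st.chains[0][0].atoms["P"]
    g = G.assemble_graph(st, ss, _zero_embeddings(st),
                         DF.time_embedding(0, T=10))
    assert g.node_count == 5 * st.n_residues - 1


def test_assemble_embedding_mismatch_raises(coarse_hairpin):
    cg, ss = coarse_hairpin
    with pytest.raises(ValueError):
        G.assemble_graph(cg, ss, np.zeros((3, 256)),
                         DF.time_embedding(0, T=10))


def test_assemble_pairing_edges_present(helix8):
    st, ss = helix8
    cg = S.coarse_grain(st)
    g = G.assemble_graph(cg, ss, _zero_embeddings(cg),
                         DF.time_embedding(0, T=10))
    pairing = g.edges_of_class(G.PAIRING)
    assert len(pairing) == 2 * len(ss.pairs)
    residue_of = [n.residue_index for n in g.nodes]
    found = {tuple(sorted((residue_of[e.i], residue_of[e.j])))
             for e in pairing}
    assert found == ss.pairs


def test_assemble_atoms_share_residue_embedding(coarse_hairpin):
    cg, ss = coarse_hairpin
    emb = np.random.default_rng(0).normal(size=(cg.n_residues, 256))
    g = G.assemble_graph(cg, ss, emb, DF.time_embedding(3, T=10))
    for k, node in enumerate(g.nodes):
        np.testing.assert_array_equal(g.node_features[k, 8:264],
                                      emb[node.residue_index])


def test_chain_permutation_is_consistent_relabeling(helix8):
    st, _ = helix8
    cg = S.coarse_grain(st)
    swapped = S.RnaStructure([cg.chains[1], cg.chains[0]], name="sw",
                             coarse_grained=True)
    g1 = G.assemble_graph(cg, None, _zero_embeddings(cg),
                          DF.time_embedding(0, T=10), with_geometry=False)
    g2 = G.assemble_graph(swapped, None, _zero_embeddings(swapped),
                          DF.time_embedding(0, T=10), with_geometry=False)
    assert g1.node_count == g2.node_count
    n_half = g1.node_count // 2
    perm = np.r_[np.arange(n_half, g1.node_count), np.arange(n_half)]
    e1 = {(min(e.i, e.j), max(e.i, e.j), e.cls) for e in g1.edges}
    e2 = {(min(perm[e.i], perm[e.j]), max(perm[e.i], perm[e.j]), e.cls)
          for e in g2.edges}
    assert e1 == e2


def test_edge_dump_deterministic(tmp_path, coarse_hairpin):
    cg, ss = coarse_hairpin
    g = G.assemble_graph(cg, ss, _zero_embeddings(cg),
                         DF.time_embedding(0, T=10))
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    G.dump_edges(g, p1)
    G.dump_edges(g, p2)
    assert p1.read_text() == p2.read_text()
    assert p1.read_text().startswith("i\tj\tclass\td\n")
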