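"""Spectral machinery against closed forms and brute-force heat-kernel oracles."""

import numpy as np
import pytest
from scipy.linalg import expm

from spectradti.kg import RELATIONS
from spectradti.spectral import (
    DistanceCache,
    build_distance_cache,
    build_operator,
    compute_spectral_basis,
    diffusion_distance,
    diffusion_distance_matrix,
    dirichlet_energy,
    expand_features,
    geodesic_distance,
    geodesic_distance_matrix,
)

from conftest import make_hetero_graph, random_hetero_graph


def k2_graph():
    return make_hetero_graph(1, 1, 0, {"drug_target": [(0, 1)]})


# --------------------------------------------------------------- operator
def test_operator_on_single_edge_unit_weight():
    op = build_operator(k2_graph(), weights={"drug_target": 1.0})
    np.testing.assert_allclose(op.matrix.todense(), [[0, 1], [1, 0]], atol=1e-12)


def test_operator_uniform_triangle_closed_form():
    # one relation covering all edges of a triangle: G = A/2, eigvals {1, -1/2, -1/2}
    g = make_hetero_graph(3, 0, 0, {"drug_drug": [(0, 1), (1, 2), (0, 2)]})
    op = build_operator(g, weights={"drug_drug": 1.0})
    np.testing.assert_allclose(op.matrix.todense(), (np.ones((3, 3)) - np.eye(3)) / 2, atol=1e-12)
    vals = np.sort(np.linalg.eigvalsh(np.asarray(op.matrix.todense())))
    np.testing.assert_allclose(vals, [-0.5, -0.5, 1.0], atol=1e-10)


def test_operator_additive_over_disjoint_relations():
    g = make_hetero_graph(
        2, 2, 0, {"drug_drug": [(0, 1)], "pathway_target": [], "drug_target": [(0, 2), (1, 3)]}
    )
    both = build_operator(g, weights={"drug_drug": 0.3, "drug_target": 0.7})
    a = build_operator(g, weights={"drug_drug": 0.3, "drug_target": 0.0})
    b = build_operator(g, weights={"drug_drug": 0.0, "drug_target": 0.7})
    np.testing.assert_allclose(
        both.matrix.todense(), (a.matrix + b.matrix).todense(), atol=1e-12
    )


def test_operator_rejects_degenerate_weights():
    with pytest.raises(ValueError):
        build_operator(k2_graph(), weights={r: 0.0 for r in RELATIONS})
    with pytest.raises(ValueError):
        build_operator(k2_graph(), weights={"drug_target": -1.0})


def test_spectrum_bound_on_random_graphs():
    """With weights summing to one, Laplacian eigenvalues lie in [0, 2]."""
    rng = np.random.default_rng(7)
    for _ in range(50):
        g = random_hetero_graph(rng)
        w = rng.random(len(RELATIONS)) + 0.05
        weights = dict(zip(RELATIONS, w / w.sum()))
        op = build_operator(g, weights=weights)
        L = op.dense_laplacian()
        vals = np.linalg.eigvalsh(L)
        assert vals.min() >= -1e-9 and vals.max() <= 2 + 1e-9


# ------------------------------------------------------------------ basis
def test_k2_basis_closed_form():
    op = build_operator(k2_graph(), weights={"drug_target": 1.0})
    basis = compute_spectral_basis(op, d_eig=2)
    np.testing.assert_allclose(np.sort(basis.lambdas), [0.0, 2.0], atol=1e-10)
    # lambda = 0 eigenvector is the (degree-weighted) constant
    phi0 = basis.phi[:, np.argmin(basis.lambdas)]
    np.testing.assert_allclose(phi0, [1 / np.sqrt(2)] * 2, atol=1e-10)


def test_disjoint_components_block_structure():
    g = make_hetero_graph(2, 2, 0, {"drug_target": [(0, 2), (1, 3)]})
    op = build_operator(g, weights={"drug_target": 1.0})
    basis = compute_spectral_basis(op, d_eig=4)
    assert basis.phi.shape == (4, 4)
    for m in range(4):
        support = np.flatnonzero(np.abs(basis.phi[:, m]) > 1e-10)
        comps = set(basis.component_of[support])
        assert len(comps) == 1, "eigenvector must live on exactly one component"


def test_phi_tilde_columns_nonnegative_unit_norm():
    rng = np.random.default_rng(3)
    g = random_hetero_graph(rng)
    op = build_operator(g)
    basis = compute_spectral_basis(op, d_eig=min(6, g.n_nodes))
    assert (basis.phi_tilde >= 0).all()
    norms = np.linalg.norm(basis.phi_tilde, axis=0)
    np.testing.assert_allclose(norms[norms > 0], 1.0, atol=1e-10)


def test_d_eig_truncation_warns_and_caps(caplog):
    op = build_operator(k2_graph(), weights={"drug_target": 1.0})
    basis = compute_spectral_basis(op, d_eig=10)
    assert basis.d_total == 2


def test_expand_features_contract():
    g = make_hetero_graph(2, 2, 0, {"drug_target": [(0, 2), (1, 3)]})
    op = build_operator(g, weights={"drug_target": 1.0})
    basis = compute_spectral_basis(op, d_eig=4)
    X = np.arange(12, dtype=np.float32).reshape(4, 3)
    H0 = expand_features(X, basis)
    assert H0.shape == (4, 3 + 4)
    np.testing.assert_allclose(H0[:, :3], X)
    # zero-column X reduces to the basis
    H0b = expand_features(np.zeros((4, 0), dtype=np.float32), basis)
    np.testing.assert_allclose(H0b, basis.phi_tilde, atol=1e-7)
    with pytest.raises(ValueError):
        expand_features(np.zeros((3, 2)), basis)


def test_expansion_is_permutation_equivariant():
    """Permuting node order permutes H0 rows identically (distances compared,
    eigenvector sign/rotation handled by comparing row sets of distances)."""
    g = make_hetero_graph(2, 2, 0, {"drug_target": [(0, 2), (0, 3), (1, 3)]})
    op = build_operator(g, weights={"drug_target": 1.0})
    basis = compute_spectral_basis(op, d_eig=4)
    d = diffusion_distance_matrix(basis)
    # relabel drug 0 <-> drug 1 (an automorphism-free relabeling): distances
    # between the same physical nodes must be preserved
    g2 = make_hetero_graph(2, 2, 0, {"drug_target": [(1, 2), (1, 3), (0, 3)]})
    op2 = build_operator(g2, weights={"drug_target": 1.0})
    basis2 = compute_spectral_basis(op2, d_eig=4)
    d2 = diffusion_distance_matrix(basis2)
    perm = np.array([1, 0, 2, 3])
    np.testing.assert_allclose(d2, d[np.ix_(perm, perm)], atol=1e-8)


# -------------------------------------------------------------- diffusion
def test_diffusion_identity_and_k2_closed_form():
    op = build_operator(k2_graph(), weights={"drug_target": 1.0})
    basis = compute_spectral_basis(op, d_eig=2, t=0.5)
    assert diffusion_distance(basis, 0, 0) == 0.0
    # d^2 = e^{-2 t lambda}(phi(u)-phi(v))^2 summed: only lambda=2 contributes,
    # (phi_u - phi_v)^2 = 2, so d^2 = 2 e^{-2} at t = 0.5
    d = diffusion_distance(basis, 0, 1)
    assert d**2 == pytest.approx(2 * np.exp(-2.0), rel=1e-10)


def test_diffusion_matches_heat_kernel_oracle_on_random_graphs():
    rng = np.random.default_rng(21)
    for _ in range(20):
        g = random_hetero_graph(rng)
        op = build_operator(g)
        t = float(rng.uniform(0.2, 2.0))
        basis = compute_spectral_basis(op, d_eig=g.n_nodes, t=t)
        K = expm(-t * op.dense_laplacian())
        for _ in range(10):
            u, v = rng.integers(0, g.n_nodes, size=2)
            if basis.component_of[u] != basis.component_of[v]:
                continue
            oracle = np.linalg.norm(K[u] - K[v])
            assert diffusion_distance(basis, int(u), int(v)) == pytest.approx(
                oracle, abs=1e-8
            )


def test_diffusion_monotone_nonincreasing_in_t():
    rng = np.random.default_rng(5)
    g = random_hetero_graph(rng)
    op = build_operator(g)
    pairs = [(u, v) for u in range(g.n_nodes) for v in range(u + 1, g.n_nodes)]
    prev = None
    for t in (0.25, 0.5, 1.0, 2.0, 4.0):
        basis = compute_spectral_basis(op, d_eig=g.n_nodes, t=t)
        cur = np.array(
            [
                diffusion_distance(basis, u, v)
                for u, v in pairs
                if basis.component_of[u] == basis.component_of[v]
            ]
        )
        if prev is not None:
            assert (cur <= prev + 1e-9).all()
        prev = cur


def test_truncated_basis_lower_bounds_full_distance():
    rng = np.random.default_rng(9)
    g = random_hetero_graph(rng)
    if g.n_nodes < 4:
        g = random_hetero_graph(np.random.default_rng(10))
    op = build_operator(g)
    full = compute_spectral_basis(op, d_eig=g.n_nodes)
    trunc = compute_spectral_basis(op, d_eig=max(1, g.n_nodes // 2))
    for u in range(g.n_nodes):
        for v in range(g.n_nodes):
            if full.component_of[u] == full.component_of[v]:
                assert (
                    diffusion_distance(trunc, u, v)
                    <= diffusion_distance(full, u, v) + 1e-8
                )


def test_cross_component_sentinel_dominates():
    g = make_hetero_graph(2, 2, 0, {"drug_target": [(0, 2), (1, 3)]})
    op = build_operator(g, weights={"drug_target": 1.0})
    basis = compute_spectral_basis(op, d_eig=4)
    d = diffusion_distance_matrix(basis)
    within = d[0, 2]
    cross = d[0, 1]
    assert cross == pytest.approx(2 * max(d[0, 2], d[1, 3]))
    assert cross > within


# --------------------------------------------------------------- geodesic
def test_geodesic_prioritized_edge_costs_and_dijkstra_oracle():
    # drug0 - pathway0 - protein0 chain plus a direct drug1 - protein0 edge
    g = make_hetero_graph(
        2, 1, 1,
        {"drug_pathway": [(0, 3)], "pathway_target": [(3, 2)], "drug_target": [(1, 2)]},
    )
    assert geodesic_distance(g, 0, 3) == 1.0  # prioritized edge
    assert geodesic_distance(g, 0, 2) == 2.0  # drug -> pathway -> target
    assert geodesic_distance(g, 1, 2) == 2.0  # one non-prioritized edge

    import networkx as nx

    G = nx.Graph()
    G.add_edge(0, 3, weight=1)
    G.add_edge(3, 2, weight=1)
    G.add_edge(1, 2, weight=2)
    D = geodesic_distance_matrix(g)
    for u in range(4):
        for v in range(4):
            if nx.has_path(G, u, v):
                assert D[u, v] == pytest.approx(
                    nx.shortest_path_length(G, u, v, weight="weight")
                )


def test_geodesic_unreachable_gets_finite_sentinel():
    g = make_hetero_graph(2, 2, 0, {"drug_target": [(0, 2)]})
    D = geodesic_distance_matrix(g)
    finite_max = 2.0  # only one edge of cost 2
    assert D[1, 3] == pytest.approx(2 * finite_max)


# -------------------------------------------------------------- dirichlet
def test_dirichlet_energy_examples_and_expansion_oracle():
    op = build_operator(k2_graph(), weights={"drug_target": 1.0})
    basis = compute_spectral_basis(op, d_eig=2)
    order = np.argsort(basis.lambdas)
    phi0 = basis.phi[:, order[0]]
    phi1 = basis.phi[:, order[1]]
    assert dirichlet_energy(phi0, op) == pytest.approx(0.0, abs=1e-10)
    assert dirichlet_energy(phi1, op) == pytest.approx(basis.lambdas[order[1]], abs=1e-10)

    rng = np.random.default_rng(13)
    for _ in range(20):
        g = random_hetero_graph(rng)
        op = build_operator(g)
        H = rng.normal(size=(g.n_nodes, 3))
        G = np.asarray(
            (op.matrix if op.operator_kind == "normalized_adjacency" else 0).todense()
        )
        # explicit expansion: 1/2 sum G_uv ||h_u - h_v||^2 + sum_u (1 - sum_v G_uv)||h_u||^2
        pairwise = 0.0
        for u in range(g.n_nodes):
            for v in range(g.n_nodes):
                pairwise += 0.5 * G[u, v] * np.sum((H[u] - H[v]) ** 2)
        diag = np.sum((1.0 - G.sum(axis=1)) * np.sum(H**2, axis=1))
        assert dirichlet_energy(H, op) == pytest.approx(pairwise + diag, abs=1e-8)
        assert dirichlet_energy(H, op) >= -1e-10


def test_dirichlet_dimension_mismatch():
    op = build_operator(k2_graph(), weights={"drug_target": 1.0})
    with pytest.raises(ValueError):
        dirichlet_energy(np.zeros((5, 2)), op)


# ------------------------------------------------------------------ cache
def test_distance_cache_standardization(small_kg):
    _, graph, _, _ = small_kg
    op = build_operator(graph)
    basis = compute_spectral_basis(op, d_eig=8)
    cache = build_distance_cache(graph, basis)
    src, dst, _ = graph.directed_edge_list()
    z = cache.z_diff(cache.d_diff[src, dst])
    assert abs(z.mean()) < 1e-5 and z.std() == pytest.approx(1.0, rel=1e-3)
    assert (cache.d_diff >= 0).all() and (cache.d_geo >= 0).all()
    np.testing.assert_allclose(cache.d_diff, cache.d_diff.T, atol=1e-9)
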