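"""Structure-preserving spectral expansion over the heterogeneous graph.

The relation-weighted operator

    G = sum_r  omega_r  D_r^{-1/2} A_r D_r^{-1/2}

balances degrees across relations; with the weights summing to one its
spectrum lies in [-1, 1] and the associated normalized Laplacian L = I - G
has eigenvalues in [0, 2].  Eigenvectors of L (lowest frequencies first)
supply global spectral coordinates that are concatenated to node features,
drive heat-kernel diffusion distances

    d^2(u, v; t) = sum_m exp(-2 t lambda_m) (phi_m(u) - phi_m(v))^2,

and define the Dirichlet-energy regularizer tr(H^T L H).  Disconnected
components get their own eigenbases, block-concatenated; cross-component
distances return a finite dominating sentinel (twice the largest finite
within-component distance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial.distance import cdist

from .kg import RELATIONS, HeteroGraph

logger = logging.getLogger(__name__)

__all__ = [
    "RelationWeightedOperator",
    "SpectralBasis",
    "DistanceCache",
    "build_operator",
    "compute_spectral_basis",
    "expand_features",
    "diffusion_distance",
    "diffusion_distance_matrix",
    "geodesic_distance_matrix",
    "dirichlet_energy",
    "build_distance_cache",
]

#: relations whose edges cost 1 on meta-path geodesics (drug->pathway->target
#: chains are prioritized); every other edge costs 2
PRIORITIZED_RELATIONS = ("drug_pathway", "pathway_target")


@dataclass
class RelationWeightedOperator:
    matrix: sp.csr_matrix  # G itself, or I - G for the Laplacian kind
    weights: dict
    operator_kind: str = "normalized_adjacency"  # | normalized_laplacian

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def laplacian(self) -> sp.csr_matrix:
        """L = I - G regardless of which kind is stored."""
        if self.operator_kind == "normalized_laplacian":
            return self.matrix
        return sp.identity(self.n_nodes, format="csr") - self.matrix

    def dense_laplacian(self) -> np.ndarray:
        return np.asarray(self.laplacian().todense(), dtype=np.float64)


def build_operator(
    graph: HeteroGraph,
    weights: dict | None = None,
    kind: str = "normalized_adjacency",
) -> RelationWeightedOperator:
    """Form the sparse relation-weighted operator; 0/0 degree terms are 0."""
    if graph.n_nodes == 0:
        raise ValueError("graph is empty")
    if weights is None:
        weights = {r: 1.0 / len(RELATIONS) for r in RELATIONS}
    if any(w < 0 for w in weights.values()):
        raise ValueError("relation weights must be nonnegative")
    if sum(weights.values()) <= 0:
        raise ValueError("all-zero relation weights give a null operator")
    n = graph.n_nodes
    G = sp.csr_matrix((n, n))
    for r, w in weights.items():
        if w == 0:
            continue
        A = graph.adjacency(r)
        deg = np.asarray(A.sum(axis=1)).ravel()
        with np.errstate(divide="ignore"):
            dinv = 1.0 / np.sqrt(deg)
        dinv[~np.isfinite(dinv)] = 0.0  # isolated-in-relation nodes contribute zero
        D = sp.diags(dinv)
        G = G + w * (D @ A @ D)
    if kind == "normalized_laplacian":
        mat = sp.identity(n, format="csr") - G
    elif kind == "normalized_adjacency":
        mat = G.tocsr()
    else:
        raise ValueError(f"unknown operator kind {kind!r}")
    return RelationWeightedOperator(matrix=mat, weights=dict(weights), operator_kind=kind)


@dataclass
class SpectralBasis:
    """Per-component eigenpairs of the Laplacian, block-concatenated."""

    lambdas: np.ndarray  # Laplacian eigenvalues, ascending within components
    phi: np.ndarray  # (n, d_total) signed eigenvectors, block-supported
    component_of: np.ndarray  # component id per node
    phi_tilde: np.ndarray  # col_norm(|phi|)
    t: float
    _sentinel: float | None = field(default=None, repr=False)

    @property
    def d_total(self) -> int:
        return self.phi.shape[1]

    def sentinel(self) -> float:
        """Finite dominating value returned for cross-component pairs."""
        if self._sentinel is None:
            d = diffusion_distance_matrix(self, sentinel=False)
            finite = d[np.isfinite(d)]
            mx = float(finite.max()) if finite.size else 1.0
            self._sentinel = 2.0 * max(mx, 1e-12)
        return self._sentinel


def _component_eig(L_sub: np.ndarray, d_c: int) -> tuple[np.ndarray, np.ndarray]:
    m = L_sub.shape[0]
    if m < 500:
        vals, vecs = np.linalg.eigh(L_sub)
    else:  # pragma: no cover - large graphs
        k = min(d_c, m - 1)
        vals, vecs = sp.linalg.eigsh(sp.csr_matrix(L_sub), k=k, which="SM", tol=1e-9)
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    return vals[:d_c], vecs[:, :d_c]


def compute_spectral_basis(op: RelationWeightedOperator, d_eig: int, t: float = 1.0) -> SpectralBasis:
    """Lowest-frequency Laplacian eigenpairs, computed per connected component.

    The per-component share of d_eig is proportional to component size with a
    minimum of one.  Eigenvectors are unit-norm, sign-fixed (first nonzero
    coordinate positive) and supported on exactly one component.
    """
    if d_eig < 1:
        raise ValueError("d_eig must be >= 1")
    if t <= 0:
        raise ValueError("diffusion time t must be > 0")
    n = op.n_nodes
    if d_eig > n:
        logger.warning("d_eig=%d exceeds node count %d; truncating", d_eig, n)
        d_eig = n
    pattern = op.matrix.copy()
    pattern.setdiag(0)
    pattern.eliminate_zeros()
    n_comp, comp_of = connected_components(pattern, directed=False)
    L = op.dense_laplacian() if n < 2000 else None

    sizes = np.array([(comp_of == c).sum() for c in range(n_comp)])
    # largest-remainder allocation, minimum one eigenpair per component
    raw = d_eig * sizes / n
    alloc = np.maximum(1, np.floor(raw)).astype(int)
    alloc = np.minimum(alloc, sizes)
    while alloc.sum() < d_eig:
        room = (alloc < sizes)
        if not room.any():
            break
        frac = np.where(room, raw - alloc, -np.inf)
        alloc[int(np.argmax(frac))] += 1
    while alloc.sum() > d_eig:
        over = np.where(alloc > 1, alloc - raw, -np.inf)
        if not np.isfinite(over).any():
            break
        alloc[int(np.argmax(over))] -= 1

    lambdas, cols = [], []
    phi = np.zeros((n, int(alloc.sum())))
    col = 0
    for c in range(n_comp):
        idx = np.flatnonzero(comp_of == c)
        Lsub = L[np.ix_(idx, idx)] if L is not None else np.asarray(
            op.laplacian()[np.ix_(idx, idx)].todense()
        )
        vals, vecs = _component_eig(Lsub, int(alloc[c]))
        for j in range(vecs.shape[1]):
            v = vecs[:, j]
            nz = np.flatnonzero(np.abs(v) > 1e-12)
            if nz.size and v[nz[0]] < 0:
                v = -v
            phi[idx, col] = v
            lambdas.append(vals[j])
            cols.append(c)
            col += 1

    lambdas = np.array(lambdas)
    absphi = np.abs(phi)
    norms = np.linalg.norm(absphi, axis=0)
    phi_tilde = absphi / np.where(norms > 0, norms, 1.0)
    return SpectralBasis(
        lambdas=lambdas, phi=phi, component_of=comp_of, phi_tilde=phi_tilde, t=float(t)
    )


def expand_features(X: np.ndarray, basis: SpectralBasis) -> np.ndarray:
    """H0 = [X || Phi~]; X is untouched."""
    if X.shape[0] != basis.phi_tilde.shape[0]:
        raise ValueError(
            f"X has {X.shape[0]} rows but the basis covers {basis.phi_tilde.shape[0]} nodes"
        )
    return np.hstack([X, basis.phi_tilde]).astype(np.float32)


def diffusion_distance(basis: SpectralBasis, u: int, v: int) -> float:
    """Heat-kernel diffusion distance between two nodes at the basis' t."""
    if u == v:
        return 0.0
    if basis.component_of[u] != basis.component_of[v]:
        return basis.sentinel()
    w = np.exp(-2.0 * basis.t * basis.lambdas)
    diff = basis.phi[u] - basis.phi[v]
    return float(np.sqrt(np.sum(w * diff**2)))


def diffusion_distance_matrix(basis: SpectralBasis, sentinel: bool = True) -> np.ndarray:
    """All-pairs diffusion distances; cross-component entries get the sentinel
    (or +inf when sentinel=False)."""
    coords = basis.phi * np.exp(-basis.t * basis.lambdas)[None, :]
    d = cdist(coords, coords)
    cross = basis.component_of[:, None] != basis.component_of[None, :]
    d[cross] = np.inf
    if sentinel and cross.any():
        finite = d[~cross & (d > 0)]
        mx = float(finite.max()) if finite.size else 1.0
        basis._sentinel = 2.0 * max(mx, 1e-12)
        d[cross] = basis._sentinel
    np.fill_diagonal(d, 0.0)
    return d


def geodesic_distance_matrix(graph: HeteroGraph, sources: np.ndarray | None = None) -> np.ndarray:
    """Meta-path geodesic distances: drug-pathway and pathway-target edges
    cost 1, all other edges cost 2.  Unreachable pairs get a finite sentinel
    (twice the largest finite path length)."""
    n = graph.n_nodes
    W = sp.lil_matrix((n, n))
    for r in RELATIONS:
        cost = 1.0 if r in PRIORITIZED_RELATIONS else 2.0
        A = graph.adjacency(r)
        for u, v in zip(*A.nonzero()):
            cur = W[u, v]
            W[u, v] = cost if cur == 0 else min(cur, cost)
    W = W.tocsr()
    d = dijkstra(W, directed=False, indices=sources)
    finite = d[np.isfinite(d) & (d > 0)]
    mx = float(finite.max()) if finite.size else 1.0
    d[~np.isfinite(d)] = 2.0 * mx
    return d


def geodesic_distance(graph: HeteroGraph, u: int, v: int) -> float:
    return float(geodesic_distance_matrix(graph, sources=np.array([u]))[0, v])


def dirichlet_energy(H: np.ndarray, op: RelationWeightedOperator) -> float:
    """tr(H^T L H), the spectral smoothness of embeddings H."""
    H = np.asarray(H, dtype=np.float64)
    if H.ndim == 1:
        H = H[:, None]
    if H.shape[0] != op.n_nodes:
        raise ValueError(f"H has {H.shape[0]} rows for {op.n_nodes} nodes")
    L = op.laplacian()
    return float(np.sum(H * (L @ H)))


@dataclass
class DistanceCache:
    """Precomputed all-pairs distances plus the standardization statistics the
    aggregator uses before injecting them as attention features."""

    d_diff: np.ndarray
    d_geo: np.ndarray
    diff_mean: float
    diff_std: float
    geo_mean: float
    geo_std: float

    def z_diff(self, values: np.ndarray) -> np.ndarray:
        return (values - self.diff_mean) / self.diff_std

    def z_geo(self, values: np.ndarray) -> np.ndarray:
        return (values - self.geo_mean) / self.geo_std


def build_distance_cache(graph: HeteroGraph, basis: SpectralBasis) -> DistanceCache:
    d_diff = diffusion_distance_matrix(basis)
    d_geo = geodesic_distance_matrix(graph)
    src, dst, _ = graph.directed_edge_list()
    if len(src):
        ed, eg = d_diff[src, dst], d_geo[src, dst]
    else:  # degenerate edgeless graph
        ed = eg = np.array([0.0, 1.0])
    return DistanceCache(
        d_diff=d_diff,
        d_geo=d_geo,
        diff_mean=float(ed.mean()),
        diff_std=float(max(ed.std(), 1e-6)),
        geo_mean=float(eg.mean()),
        geo_std=float(max(eg.std(), 1e-6)),
    )
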