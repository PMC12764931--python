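"""Relation-aware, distance-weighted attention propagation (K layers).

Each directed edge (u -> v) carries a relation embedding e_vu and the two
standardized SPSE distances d_geo(v, u), d_diff(v, u).  Attention logits are

    alpha_vu  propto  exp(LeakyReLU(a^T [W h_v || W h_u || e_vu || d_geo || d_diff]))

normalized per destination node and head; the update is

    h_v^(k+1) = sigma(W_s h_v + sum_u alpha_vu W R_t(e_vu) h_u).

Heads are concatenated in hidden layers; at the last layer the per-head
attention weights are averaged (shared value projection).  Train mode applies
seeded Bernoulli edge-drop per layer and fan-out subsampling per relation;
eval mode is deterministic over full neighborhoods.  `propagate_view` runs
the same layers on a reindexed node/edge subset, which is how contrastive
subgraph views are encoded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kg import RELATIONS, HeteroGraph
from .nn import Linear, Module, Tensor, concat
from .spectral import DistanceCache

__all__ = ["AggregatorConfig", "HetAggregator"]


@dataclass
class AggregatorConfig:
    layers: int = 6
    heads: int = 8
    d: int = 512
    leaky_slope: float = 0.2
    edge_drop: float = 0.1
    fan_out: int = 10
    use_distance_features: bool = True
    use_diffusion_distance: bool = True
    rel_emb_dim: int = 8
    omega_mode: str = "uniform"  # | learned (softmax-constrained relation scaling)

    @classmethod
    def desk(cls, d: int = 64, layers: int = 3, **overrides) -> "AggregatorConfig":
        base = dict(d=d, layers=layers, heads=4)
        base.update(overrides)
        return cls(**base)


class _Layer(Module):
    def __init__(self, d: int, heads: int, rel_dim: int, rng: np.random.Generator):
        super().__init__()
        self.W_s = Linear(d, d, rng, bias=False)
        self.W = Linear(d, d, rng, bias=False)
        self.R = [Linear(d, d, rng, bias=False) for _ in range(len(RELATIONS))]
        # attention vector a, one column per head over [Wh_v || Wh_u || e || d_geo || d_diff]
        feat = 2 * d + rel_dim + 2
        self.a = Tensor(
            (rng.normal(0, 1.0, size=(feat, heads)) / np.sqrt(feat)).astype(np.float32),
            requires_grad=True,
        )


def _scatter_rows(p: Tensor, positions: np.ndarray, n_rows: int) -> Tensor:
    """Place rows of `p` at `positions` in a zero (n_rows, d) tensor."""
    data = np.zeros((n_rows, p.shape[1]), dtype=np.float32)
    data[positions] = p.data

    def backward(g):
        if p.requires_grad:
            p._accumulate(g[positions])

    return Tensor._make(data, (p,), backward)


class HetAggregator(Module):
    """K-layer propagation over a fixed heterogeneous graph."""

    def __init__(
        self,
        graph: HeteroGraph,
        cache: DistanceCache | None,
        config: AggregatorConfig,
        d_in: int,
        rng: np.random.Generator,
    ):
        super().__init__()
        c = config
        if c.d % c.heads:
            raise ValueError("hidden size must divide heads")
        self.config = c
        self.n_nodes = graph.n_nodes
        src, dst, rel = graph.directed_edge_list()
        self.src, self.dst, self.rel = src, dst, rel
        dg = np.zeros(len(src), dtype=np.float32)
        dd = np.zeros(len(src), dtype=np.float32)
        if c.use_distance_features and cache is not None and len(src):
            dg = cache.z_geo(cache.d_geo[dst, src]).astype(np.float32)
            if c.use_diffusion_distance:
                dd = cache.z_diff(cache.d_diff[dst, src]).astype(np.float32)
        self.edge_dist = np.stack([dg, dd], axis=1)  # (E, 2)
        self.rel_table = Tensor(
            rng.normal(0, 0.1, size=(len(RELATIONS), c.rel_emb_dim)).astype(np.float32),
            requires_grad=True,
        )
        self.in_proj = Linear(d_in, c.d, rng)
        self.out_proj = Linear(c.d, c.d, rng)
        self.layers_ = [_Layer(c.d, c.heads, c.rel_emb_dim, rng) for _ in range(c.layers)]
        if c.omega_mode == "learned":
            self.omega_logits = Tensor(np.zeros(len(RELATIONS), dtype=np.float32), requires_grad=True)
        else:
            self.omega_logits = None
        self.last_attention: list | None = None

    # ------------------------------------------------------------------
    def _sample_edges(self, idx: np.ndarray, dst: np.ndarray, rel: np.ndarray,
                      rng: np.random.Generator):
        """Apply edge-drop then per-(destination, relation) fan-out capping."""
        c = self.config
        if c.edge_drop > 0:
            keep = rng.random(len(idx)) >= c.edge_drop
            idx, dst, rel = idx[keep], dst[keep], rel[keep]
        if c.fan_out and c.fan_out > 0:
            key = dst * len(RELATIONS) + rel
            order = rng.permutation(len(idx))
            seen: dict[int, int] = {}
            keep = np.zeros(len(idx), dtype=bool)
            for pos in order:
                k = int(key[pos])
                cnt = seen.get(k, 0)
                if cnt < c.fan_out:
                    keep[pos] = True
                    seen[k] = cnt + 1
            idx = idx[keep]
        return idx

    def _run_layers(
        self,
        h: Tensor,
        src: np.ndarray,
        dst: np.ndarray,
        rel: np.ndarray,
        edge_dist: np.ndarray,
        n_nodes: int,
        training: bool,
        rng: np.random.Generator | None,
        collect_attention: bool = False,
    ) -> Tensor:
        c = self.config
        heads, d_k = c.heads, c.d // c.heads
        omega = (
            self.omega_logits.softmax(axis=0) * float(len(RELATIONS))
            if self.omega_logits is not None
            else None
        )
        self.last_attention = [] if collect_attention else None
        h = self.in_proj(h)
        for k, layer in enumerate(self.layers_):
            idx = np.arange(len(src))
            if training and rng is not None and len(idx):
                idx = self._sample_edges(idx, dst, rel, rng)
            s, t, r = src[idx], dst[idx], rel[idx]
            Wh = layer.W(h)
            if len(idx):
                parts = []
                for ri in range(len(RELATIONS)):
                    m = r == ri
                    if not m.any():
                        continue
                    p = layer.W(layer.R[ri](h)).gather_rows(s[m])
                    if omega is not None:
                        p = p * omega[ri]
                    parts.append((np.flatnonzero(m), p))
                e_emb = self.rel_table.gather_rows(r)
                feats = concat(
                    [Wh.gather_rows(t), Wh.gather_rows(s), e_emb, Tensor(edge_dist[idx])],
                    axis=-1,
                )
                logits = (feats @ layer.a).leaky_relu(c.leaky_slope)  # (E, heads)
                alpha = logits.segment_softmax(t, n_nodes)
                if collect_attention:
                    self.last_attention.append((idx.copy(), alpha.data.copy()))
                msg = Tensor(np.zeros((len(idx), c.d), dtype=np.float32))
                for pos, p in parts:
                    msg = msg + _scatter_rows(p, pos, len(idx))
                if k == len(self.layers_) - 1:
                    weighted = msg * alpha.mean(axis=1, keepdims=True)  # average heads
                else:
                    mh = msg.reshape(len(idx), heads, d_k)
                    weighted = (mh * alpha.reshape(len(idx), heads, 1)).reshape(len(idx), c.d)
                agg = weighted.segment_sum(t, n_nodes)
                h = (layer.W_s(h) + agg).elu()
            else:  # isolated view: only the self term
                h = layer.W_s(h).elu()
            if not np.all(np.isfinite(h.data)):
                raise FloatingPointError(f"non-finite embedding after layer {k}")
        return self.out_proj(h)

    def __call__(
        self,
        H0,
        mode: str = "eval",
        rng: np.random.Generator | None = None,
        collect_attention: bool = False,
    ) -> Tensor:
        """Propagate expanded features H0 (ndarray or Tensor) for K layers."""
        h = H0 if isinstance(H0, Tensor) else Tensor(np.asarray(H0, dtype=np.float32))
        if not np.all(np.isfinite(h.data)):
            raise ValueError("non-finite input features")
        return self._run_layers(
            h, self.src, self.dst, self.rel, self.edge_dist, self.n_nodes,
            training=(mode == "train"), rng=rng, collect_attention=collect_attention,
        )

    def propagate_view(self, H0, node_ids: np.ndarray, edge_idx: np.ndarray) -> Tensor:
        """Run the layers on a node subset with a restricted directed-edge set
        (indices into the full edge list); returns one row per view node."""
        out, offsets = self.propagate_views(H0, [(node_ids, edge_idx)])
        return out

    def propagate_views(self, H0, views: list) -> tuple[Tensor, np.ndarray]:
        """Propagate several (node_ids, edge_idx) views at once as one
        block-diagonal graph (views never exchange messages).  Returns the
        stacked embeddings and the row offset of each view."""
        all_nodes, all_src, all_dst, all_rel, all_dist = [], [], [], [], []
        offsets = np.zeros(len(views) + 1, dtype=np.int64)
        for i, (node_ids, edge_idx) in enumerate(views):
            node_ids = np.asarray(node_ids, dtype=np.int64)
            edge_idx = np.asarray(edge_idx, dtype=np.int64)
            local = -np.ones(self.n_nodes, dtype=np.int64)
            local[node_ids] = np.arange(len(node_ids)) + offsets[i]
            src, dst = local[self.src[edge_idx]], local[self.dst[edge_idx]]
            ok = (src >= 0) & (dst >= 0)
            all_nodes.append(node_ids)
            all_src.append(src[ok])
            all_dst.append(dst[ok])
            all_rel.append(self.rel[edge_idx][ok])
            all_dist.append(self.edge_dist[edge_idx][ok])
            offsets[i + 1] = offsets[i] + len(node_ids)
        h = H0 if isinstance(H0, Tensor) else Tensor(np.asarray(H0, dtype=np.float32))
        h = h.gather_rows(np.concatenate(all_nodes))
        out = self._run_layers(
            h,
            np.concatenate(all_src),
            np.concatenate(all_dst),
            np.concatenate(all_rel),
            np.concatenate(all_dist),
            int(offsets[-1]),
            training=False,
            rng=None,
        )
        return out, offsets
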