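"""Full dual-task DTI model: encoders + spectral features + aggregator + heads.

The propagation trunk follows the training algorithm's data flow: expanded
node features H0 = [X || Phi~] are propagated by the relation-aware
aggregator to give graph embeddings H; the pair representation adds each
entity's aggregated embedding to its encoder output,

    h_d = enc_drug(SMILES) + W_g H[d],     h_t = enc_prot(seq) + W_g' H[t],

so the spectral machinery, the aggregator and both encoders all sit on the
prediction path.  Cross-view fusion yields the joint vector consumed by one
logistic head per focal task.  A projection head over pair embeddings of
subgraph views supports the contrastive objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aggregator import AggregatorConfig, HetAggregator
from .calibration import PredictionHead
from .encoders import (
    DrugEncoder,
    EncoderConfig,
    FusionBlock,
    ProteinEncoder,
    smiles_to_graph,
)
from .kg import HeteroGraph
from .nn import Linear, MLP, Module, Tensor, concat
from .spectral import DistanceCache, SpectralBasis, expand_features

__all__ = ["ModelConfig", "DTIModel"]


@dataclass
class ModelConfig:
    encoder: EncoderConfig
    aggregator: AggregatorConfig
    use_spectral_features: bool = True
    n_tasks: int = 2
    head_hidden: int = 256
    proj_dim: int = 128

    @classmethod
    def desk(cls, d: int = 64, layers: int = 3, n_tasks: int = 2, **overrides) -> "ModelConfig":
        return cls(
            encoder=EncoderConfig.desk(d=d),
            aggregator=AggregatorConfig.desk(d=d, layers=layers),
            n_tasks=n_tasks,
            head_hidden=min(256, 4 * d),
            **overrides,
        )


def _scatter_vector(values: Tensor, positions: np.ndarray, n: int) -> Tensor:
    """Place a (m,) tensor at integer positions of a zero (n,) tensor."""
    data = np.zeros(n, dtype=np.float32)
    data[positions] = values.data

    def backward(g):
        if values.requires_grad:
            values._accumulate(g[positions])

    return Tensor._make(data, (values,), backward)


class DTIModel(Module):
    def __init__(
        self,
        graph: HeteroGraph,
        basis: SpectralBasis | None,
        cache: DistanceCache | None,
        config: ModelConfig,
        seed: int = 0,
        operator=None,
    ):
        super().__init__()
        self.graph = graph
        self.config = config
        #: dense Laplacian for the spectral smoothness regularizer (optional)
        self.laplacian_dense = operator.dense_laplacian() if operator is not None else None
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0xD71)))
        ec = config.encoder
        if config.use_spectral_features and basis is not None:
            self.H0 = expand_features(graph.X, basis)
        else:
            self.H0 = np.asarray(graph.X, dtype=np.float32)
        # column standardization before the input projection: the spectral
        # coordinates are unit-norm over all nodes (entries ~ 1/sqrt(n)) and
        # would otherwise be dwarfed by the raw feature columns
        mu = self.H0.mean(axis=0)
        sd = np.maximum(self.H0.std(axis=0), 1e-6)
        self.H0 = ((self.H0 - mu) / sd).astype(np.float32)
        self.cache = cache
        self.mols = {
            int(i): smiles_to_graph(graph.records[i]["smiles"], k=ec.k_local)
            for i in graph.nodes_of_type("drug")
        }
        self.seqs = {int(i): graph.records[i]["sequence"] for i in graph.nodes_of_type("protein")}

        self.drug_encoder = DrugEncoder(ec, rng)
        self.protein_encoder = ProteinEncoder(ec, rng)
        self.fusion = FusionBlock(ec, rng)
        self.aggregator = HetAggregator(graph, cache, config.aggregator, self.H0.shape[1], rng)
        self.graph_proj_d = Linear(config.aggregator.d, ec.d, rng)
        self.graph_proj_t = Linear(config.aggregator.d, ec.d, rng)
        self.heads = [
            PredictionHead(3 * ec.d, rng, hidden=config.head_hidden) for _ in range(config.n_tasks)
        ]
        self.proj = MLP([2 * config.aggregator.d, config.aggregator.d, config.proj_dim], rng)

    # ------------------------------------------------------------------
    def propagate(self, mode: str = "eval", rng: np.random.Generator | None = None) -> Tensor:
        return self.aggregator(self.H0, mode=mode, rng=rng)

    def encode_pairs(
        self,
        drugs: np.ndarray,
        prots: np.ndarray,
        H: Tensor,
        rng: np.random.Generator | None = None,
    ):
        """Fused pair embeddings for aligned drug/protein node-id arrays."""
        drugs = np.asarray(drugs, dtype=np.int64)
        prots = np.asarray(prots, dtype=np.int64)
        u_d, inv_d = np.unique(drugs, return_inverse=True)
        u_p, inv_p = np.unique(prots, return_inverse=True)
        h_d_u, atoms_u, amask_u = self.drug_encoder([self.mols[int(i)] for i in u_d], rng=rng)
        h_t_u, res_u, rmask_u = self.protein_encoder([self.seqs[int(i)] for i in u_p], rng=rng)
        h_d = h_d_u.gather_rows(inv_d) + self.graph_proj_d(H.gather_rows(drugs))
        h_t = h_t_u.gather_rows(inv_p) + self.graph_proj_t(H.gather_rows(prots))
        atoms = atoms_u.gather_rows(inv_d)
        residues = res_u.gather_rows(inv_p)
        return self.fusion(h_d, atoms, amask_u[inv_d], h_t, residues, rmask_u[inv_p])

    def pair_logits(
        self,
        drugs: np.ndarray,
        prots: np.ndarray,
        tasks: np.ndarray,
        H: Tensor,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Per-pair logits from the task-specific heads, shape (B,)."""
        fused = self.encode_pairs(drugs, prots, H, rng=rng)
        B = len(drugs)
        out = Tensor(np.zeros(B, dtype=np.float32))
        for t in range(self.config.n_tasks):
            m = np.flatnonzero(np.asarray(tasks) == t)
            if m.size == 0:
                continue
            logit = self.heads[t].logits(fused.joint.gather_rows(m), rng=rng).reshape(len(m))
            out = out + _scatter_vector(logit, m, B)
        return out

    def predict(
        self, drugs: np.ndarray, prots: np.ndarray, tasks: np.ndarray, chunk: int = 256
    ) -> np.ndarray:
        """Eval-mode probabilities; deterministic, full neighborhoods."""
        self.eval()
        H = self.propagate(mode="eval")
        out = np.zeros(len(drugs), dtype=np.float64)
        for a in range(0, len(drugs), chunk):
            sl = slice(a, min(a + chunk, len(drugs)))
            logits = self.pair_logits(drugs[sl], prots[sl], np.asarray(tasks)[sl], H)
            out[sl] = 1.0 / (1.0 + np.exp(-logits.data.astype(np.float64)))
        self.train()
        return out

    def view_projection(self, H_view: Tensor, d_local: int, t_local: int) -> Tensor:
        """l2-normalized contrastive projection of a view's (drug, target) pair."""
        pair = concat([H_view[d_local], H_view[t_local]], axis=-1).reshape(1, -1)
        z = self.proj(pair).reshape(self.config.proj_dim)
        norm = ((z * z).sum() + 1e-12) ** 0.5
        return z * (norm ** -1.0)

    def view_projections(self, H_views: Tensor, d_rows: np.ndarray, t_rows: np.ndarray) -> Tensor:
        """Batched l2-normalized projections for many (drug, target) view rows."""
        pair = concat([H_views.gather_rows(d_rows), H_views.gather_rows(t_rows)], axis=-1)
        z = self.proj(pair)
        norm = ((z * z).sum(axis=1, keepdims=True) + 1e-12) ** 0.5
        return z * (norm ** -1.0)

    def drug_embeddings(self) -> dict:
        """Aggregated drug-node embeddings (eval mode), for similarity scoring."""
        self.eval()
        H = self.propagate(mode="eval").data
        self.train()
        return {int(i): H[int(i)] for i in self.graph.nodes_of_type("drug")}
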