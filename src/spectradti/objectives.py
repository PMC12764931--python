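"""Training objectives and loop: supervised BCE, graph co-contrastive
InfoNCE over meta-path subgraph views, first-order episodic meta-learning,
spectral smoothness regularization, and the composite loss

    L = L_dti + beta * L_cont + gamma * L_meta + eta * L_spec

optimized with AdamW (cosine-annealed learning rate, global gradient
clipping) and early stopping on validation AUPR.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from .kg import HeteroGraph
from .model import DTIModel
from .metrics import aupr, auc_roc
from .nn import AdamW, Tensor, clip_grad_norm, cosine_lr, stack
from .spectral import DistanceCache

logger = logging.getLogger(__name__)

__all__ = [
    "LossWeights",
    "ContrastiveBatch",
    "MetaEpisode",
    "TrainConfig",
    "TrainResult",
    "infonce_loss",
    "bce_with_logits",
    "composite_loss",
    "spectral_loss",
    "sample_contrastive_views",
    "meta_episode_loss",
    "train",
]

#: relations admissible in meta-path-constrained subgraph sampling
METAPATH_RELATIONS = (0, 2, 3)  # drug_target, drug_pathway, pathway_target


@dataclass
class LossWeights:
    beta: float = 0.5  # contrastive
    gamma: float = 0.3  # meta
    eta: float = 1e-3  # spectral (within the stated [1e-4, 1e-2] range)


@dataclass
class ContrastiveBatch:
    anchors: Tensor  # (B, dim), l2-normalized
    positives: Tensor  # (B, dim)
    temperature: float = 0.07
    extra_negatives: Tensor | None = None  # (M, dim)


def infonce_loss(batch: ContrastiveBatch) -> Tensor:
    """Mean per-anchor InfoNCE with in-batch negatives (cosine similarity on
    pre-normalized projections)."""
    A, P = batch.anchors, batch.positives
    B = A.shape[0]
    tau_inv = 1.0 / batch.temperature
    s_pos = (A * P).sum(axis=1) * tau_inv  # (B,)
    s_aa = (A @ A.T) * tau_inv  # (B, B)
    offdiag = 1.0 - np.eye(B, dtype=np.float32)
    # detached per-row max for numerical stability
    m = np.maximum(s_pos.data, np.where(offdiag > 0, s_aa.data, -np.inf).max(axis=1, initial=-np.inf))
    extras = None
    if batch.extra_negatives is not None:
        extras = (A @ batch.extra_negatives.T) * tau_inv
        m = np.maximum(m, extras.data.max(axis=1))
    mT = Tensor(m)
    denom = (s_pos - mT).exp() + ((s_aa - mT.reshape(B, 1)).exp() * Tensor(offdiag)).sum(axis=1)
    if extras is not None:
        denom = denom + (extras - mT.reshape(B, 1)).exp().sum(axis=1)
    loss = (mT + denom.log() - s_pos).mean()
    return loss


def bce_with_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy from logits."""
    y = np.asarray(y, dtype=np.float32)
    absx = logits.relu() + (-logits).relu()
    return (logits.relu() - logits * Tensor(y) + (1.0 + (-absx).exp()).log()).mean()


def composite_loss(l_dti, l_cont, l_meta, l_spec, weights: LossWeights):
    """L_dti + beta L_cont + gamma L_meta + eta L_spec; aborts on non-finite
    components, naming the offender."""
    comps = {"dti": l_dti, "contrastive": l_cont, "meta": l_meta, "spectral": l_spec}
    for name, c in comps.items():
        v = c.data if isinstance(c, Tensor) else np.asarray(c)
        if not np.all(np.isfinite(v)):
            raise FloatingPointError(f"non-finite loss component: {name}")
    w = weights
    return l_dti + w.beta * l_cont + w.gamma * l_meta + w.eta * l_spec


def spectral_loss(H: Tensor, L_dense: np.ndarray, normalize: bool = True) -> Tensor:
    """Dirichlet energy tr(H^T L H) of the aggregated embeddings, divided by
    the embedding size so eta stays scale-free across problem sizes."""
    LH = Tensor(L_dense.astype(np.float32)) @ H
    e = (H * LH).sum()
    if normalize:
        e = e * (1.0 / float(H.data.size))
    return e


# ------------------------------------------------------------------ views
@dataclass
class ContrastiveViews:
    anchor_nodes: np.ndarray
    anchor_edges: np.ndarray  # indices into the aggregator's directed edge list
    positive_nodes: np.ndarray
    negative_edges: np.ndarray  # anchor edges with ~20% dropped
    keep_prob: dict  # node -> keep probability used for the positive resample


def sample_contrastive_views(
    pair: tuple,
    graph: HeteroGraph,
    cache: DistanceCache | None,
    edge_arrays: tuple,
    seed: int,
    hops: int = 2,
    edge_drop: float = 0.2,
    max_neighbors_per_hop: int = 8,
    max_nodes: int = 48,
) -> ContrastiveViews:
    """Meta-path-constrained 2-hop subgraph views around a (drug, target) pair.

    The anchor is the subgraph reached within `hops` steps along the
    drug-target / drug-pathway / pathway-target relations; the positive view
    resamples anchor nodes with keep-probability decreasing in their
    diffusion distance to the pair (the pair itself is always kept); the
    negative view drops ~20% of the anchor's edges."""
    d, t = pair
    src, dst, rel = edge_arrays
    rng = np.random.default_rng(np.random.SeedSequence((seed, int(d), int(t))))
    allowed = np.isin(rel, METAPATH_RELATIONS)
    nodes = {int(d), int(t)}
    frontier = set(nodes)
    for _ in range(hops):
        next_frontier: set[int] = set()
        for f in sorted(frontier):
            nbrs = dst[allowed & (src == f)]
            nbrs = np.unique(nbrs)
            if len(nbrs) > max_neighbors_per_hop:  # hub cap, seeded
                nbrs = rng.choice(nbrs, size=max_neighbors_per_hop, replace=False)
            next_frontier.update(int(x) for x in nbrs)
        frontier = next_frontier - nodes
        nodes |= frontier
        if not frontier or len(nodes) >= max_nodes:
            break
    node_arr = np.array(sorted(nodes)[:max_nodes], dtype=np.int64)
    node_arr = np.unique(np.concatenate([node_arr, [int(d), int(t)]]))
    in_view = np.isin(src, node_arr) & np.isin(dst, node_arr) & allowed
    anchor_edges = np.flatnonzero(in_view)
    if len(node_arr) <= 2:
        logger.warning("isolated pair (%d, %d): minimal contrastive view", d, t)

    keep_prob = {}
    kept = []
    if cache is not None and len(node_arr) > 2:
        dd = np.minimum(cache.d_diff[node_arr, d], cache.d_diff[node_arr, t])
        scale = max(float(np.median(dd[dd > 0])) if (dd > 0).any() else 1.0, 1e-6)
        probs = np.exp(-dd / scale)
        for n, p in zip(node_arr, probs):
            pk = 1.0 if n in (d, t) else float(p)
            keep_prob[int(n)] = pk
            if rng.random() < pk:
                kept.append(int(n))
    else:
        kept = [int(x) for x in node_arr]
        keep_prob = {int(n): 1.0 for n in node_arr}
    for must in (int(d), int(t)):
        if must not in kept:
            kept.append(must)
    positive_nodes = np.array(sorted(set(kept)), dtype=np.int64)

    if len(anchor_edges):
        neg_keep = rng.random(len(anchor_edges)) >= edge_drop
        negative_edges = anchor_edges[neg_keep]
    else:
        negative_edges = anchor_edges
    return ContrastiveViews(
        anchor_nodes=node_arr,
        anchor_edges=anchor_edges,
        positive_nodes=positive_nodes,
        negative_edges=negative_edges,
        keep_prob=keep_prob,
    )


# ------------------------------------------------------------------ meta
@dataclass
class MetaEpisode:
    key: str  # e.g. "task:0" (target family) or "group:approved"
    support: np.ndarray  # row indices into the current batch
    query: np.ndarray
    inner_steps: int = 2
    alpha_inner: float = 0.01


def meta_episode_loss(
    head,
    support_joint: Tensor | None,
    support_y: np.ndarray,
    query_joint: Tensor,
    query_y: np.ndarray,
    inner_steps: int = 2,
    alpha_inner: float = 0.01,
):
    """First-order episodic adaptation of a prediction head.

    A clone of the head is adapted on the (detached) support set with AdamW
    at the inner step size; the returned query BCE is differentiable with
    respect to the adapted clone's parameters and the query embeddings, so
    first-order meta-gradients reach both the trunk and -- once the caller
    transfers the clone's gradients -- the original head.  Returns
    (query_loss, clone)."""
    clone = copy.deepcopy(head)
    if support_joint is None or len(support_y) == 0:
        logger.warning("empty support set: returning unadapted query loss")
        q = bce_with_logits(clone.logits(query_joint).reshape(len(query_y)), query_y)
        return q, clone
    sup = support_joint.detach()
    opt = AdamW(clone.parameters(), lr=alpha_inner, weight_decay=0.0)
    for _ in range(inner_steps):
        clone.zero_grad()
        loss = bce_with_logits(clone.logits(sup).reshape(len(support_y)), support_y)
        loss.backward()
        opt.step()
    clone.zero_grad()
    q = bce_with_logits(clone.logits(query_joint).reshape(len(query_y)), query_y)
    return q, clone


# ------------------------------------------------------------------ trainer
@dataclass
class TrainConfig:
    base_lr: float = 1e-4
    weight_decay: float = 1e-2
    batch_size: int = 64
    max_epochs: int = 100
    grad_clip: float = 1.0
    patience: int = 10
    seed: int = 0
    steps_per_epoch: int | None = None  # cap for desk-scale runs
    temperature: float = 0.07
    contrastive_pairs: int = 4
    episodes_per_step: int = 2
    support_size: int = 8
    query_size: int = 8
    inner_steps: int = 2
    alpha_inner: float = 0.01
    weights: LossWeights = field(default_factory=LossWeights)
    task_fractions: dict | None = None  # task id -> training-data fraction


@dataclass
class TrainResult:
    history: list
    best_state: dict
    best_epoch: int
    best_val_aupr: float


def _epoch_metrics(model: DTIModel, drugs, prots, tasks, labels, idx) -> tuple[float, float]:
    probs = model.predict(drugs[idx], prots[idx], tasks[idx])
    y = labels[idx]
    if y.min() == y.max():  # degenerate validation fold
        return float("nan"), float("nan")
    return aupr(probs, y), auc_roc(probs, y)


def train(
    model: DTIModel,
    pairs: list,
    tasks: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    config: TrainConfig,
) -> TrainResult:
    """Run the training loop on one fold; returns the best checkpoint by
    validation AUPR and the per-epoch history."""
    if len(val_idx) == 0:
        raise ValueError("empty validation set: no early-stopping signal")
    cfg = config
    w = cfg.weights
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x7A11)))
    drop_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xED6E)))
    view_seed = int(
        np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xC0))).integers(2**31 - 1)
    )
    drugs = np.array([p.drug for p in pairs], dtype=np.int64)
    prots = np.array([p.protein for p in pairs], dtype=np.int64)
    labels = np.array([p.label for p in pairs], dtype=np.float32)
    tasks = np.asarray(tasks, dtype=np.int64)

    if cfg.task_fractions:
        keep = []
        for i in train_idx:
            frac = cfg.task_fractions.get(int(tasks[i]), 1.0)
            if rng.random() < frac:
                keep.append(i)
        train_idx = np.array(keep, dtype=np.int64)

    params = model.parameters()
    opt = AdamW(params, lr=cfg.base_lr, weight_decay=cfg.weight_decay)
    steps_per_epoch = int(np.ceil(len(train_idx) / cfg.batch_size))
    if cfg.steps_per_epoch:
        steps_per_epoch = min(steps_per_epoch, cfg.steps_per_epoch)
    total_steps = steps_per_epoch * cfg.max_epochs
    edge_arrays = (model.aggregator.src, model.aggregator.dst, model.aggregator.rel)
    history: list[dict] = []
    best = (-np.inf, 0, None)
    step = 0
    model.train()

    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(train_idx)
        ep_losses = {"dti": [], "contrastive": [], "meta": [], "spectral": [], "total": []}
        for b in range(steps_per_epoch):
            batch = perm[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            if len(batch) == 0:
                continue
            H = model.propagate(mode="train", rng=drop_rng)
            fused = model.encode_pairs(drugs[batch], prots[batch], H, rng=drop_rng)

            # -- supervised dual-task BCE (mean of per-task BCEs present)
            task_losses = []
            for t in range(model.config.n_tasks):
                m = np.flatnonzero(tasks[batch] == t)
                if m.size == 0:
                    continue
                lg = model.heads[t].logits(fused.joint.gather_rows(m), rng=drop_rng).reshape(len(m))
                task_losses.append(bce_with_logits(lg, labels[batch][m]))
            l_dti = task_losses[0] if len(task_losses) == 1 else (
                sum(task_losses[1:], task_losses[0]) * (1.0 / len(task_losses))
            )

            # -- contrastive views
            if w.beta > 0 and cfg.contrastive_pairs > 0:
                n_con = min(cfg.contrastive_pairs, len(batch))
                sel = rng.choice(len(batch), size=n_con, replace=False)
                view_list, locals_ = [], []
                for i in sel:
                    pi = batch[i]
                    views = sample_contrastive_views(
                        (drugs[pi], prots[pi]), model.graph, model.cache, edge_arrays,
                        seed=view_seed + step,
                    )
                    la = {int(n): j for j, n in enumerate(views.anchor_nodes)}
                    lp = {int(n): j for j, n in enumerate(views.positive_nodes)}
                    view_list += [
                        (views.anchor_nodes, views.anchor_edges),
                        (views.positive_nodes, views.anchor_edges),
                        (views.anchor_nodes, views.negative_edges),
                    ]
                    locals_.append(
                        (la[drugs[pi]], la[prots[pi]], lp[drugs[pi]], lp[prots[pi]])
                    )
                Hv, offs = model.aggregator.propagate_views(model.H0, view_list)
                ad = np.array([offs[3 * j] + l[0] for j, l in enumerate(locals_)])
                at = np.array([offs[3 * j] + l[1] for j, l in enumerate(locals_)])
                pd_ = np.array([offs[3 * j + 1] + l[2] for j, l in enumerate(locals_)])
                pt = np.array([offs[3 * j + 1] + l[3] for j, l in enumerate(locals_)])
                nd = np.array([offs[3 * j + 2] + l[0] for j, l in enumerate(locals_)])
                nt = np.array([offs[3 * j + 2] + l[1] for j, l in enumerate(locals_)])
                cbatch = ContrastiveBatch(
                    anchors=model.view_projections(Hv, ad, at),
                    positives=model.view_projections(Hv, pd_, pt),
                    temperature=cfg.temperature,
                    extra_negatives=model.view_projections(Hv, nd, nt),
                )
                l_cont = infonce_loss(cbatch)
            else:
                l_cont = Tensor(0.0)

            # -- episodic meta-learning (episodes keyed by target family/task)
            clones = []
            if w.gamma > 0 and cfg.episodes_per_step > 0:
                metas = []
                avail_tasks = [
                    t for t in range(model.config.n_tasks)
                    if (tasks[batch] == t).sum() >= cfg.support_size + 2
                ]
                for e in range(cfg.episodes_per_step):
                    if not avail_tasks:
                        break
                    t = avail_tasks[e % len(avail_tasks)]
                    rows = np.flatnonzero(tasks[batch] == t)
                    rows = rng.permutation(rows)
                    sup = rows[: cfg.support_size]
                    qry = rows[cfg.support_size : cfg.support_size + cfg.query_size]
                    if len(qry) == 0:
                        continue
                    q, clone = meta_episode_loss(
                        model.heads[t],
                        fused.joint.gather_rows(sup),
                        labels[batch][sup],
                        fused.joint.gather_rows(qry),
                        labels[batch][qry],
                        inner_steps=cfg.inner_steps,
                        alpha_inner=cfg.alpha_inner,
                    )
                    metas.append(q)
                    clones.append((t, clone))
                if metas:
                    l_meta = sum(metas[1:], metas[0]) * (1.0 / len(metas))
                else:
                    l_meta = Tensor(0.0)
            else:
                l_meta = Tensor(0.0)

            # -- spectral smoothness on the aggregated embeddings
            if w.eta > 0 and model.laplacian_dense is not None:
                l_spec = spectral_loss(H, model.laplacian_dense)
            else:
                l_spec = Tensor(0.0)

            total = composite_loss(l_dti, l_cont, l_meta, l_spec, w)
            model.zero_grad()
            total.backward()
            # first-order transfer: adapted-clone gradients flow to the heads
            for t, clone in clones:
                hp = model.heads[t].parameters()
                for kname, pc in clone.parameters().items():
                    if pc.grad is not None:
                        if hp[kname].grad is None:
                            hp[kname].grad = pc.grad.copy()
                        else:
                            hp[kname].grad += pc.grad
            clip_grad_norm(params, cfg.grad_clip)
            opt.step(lr=cosine_lr(cfg.base_lr, step, total_steps))
            step += 1
            for k, v in (("dti", l_dti), ("contrastive", l_cont), ("meta", l_meta),
                         ("spectral", l_spec), ("total", total)):
                ep_losses[k].append(float(v.data))

        val_aupr, val_auc = _epoch_metrics(model, drugs, prots, tasks, labels, val_idx)
        entry = {
            "epoch": epoch,
            **{k: float(np.mean(v)) if v else 0.0 for k, v in ep_losses.items()},
            "val_aupr": val_aupr,
            "val_auc": val_auc,
        }
        history.append(entry)
        logger.info("epoch %d: %s", epoch, entry)
        if val_aupr > best[0]:
            best = (val_aupr, epoch, model.state_dict())
        elif epoch - best[1] >= cfg.patience:
            logger.info("early stop at epoch %d (best %d)", epoch, best[1])
            break

    if best[2] is not None:
        model.load_state_dict(best[2])
    return TrainResult(
        history=history, best_state=best[2] or model.state_dict(),
        best_epoch=best[1], best_val_aupr=float(best[0]),
    )
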