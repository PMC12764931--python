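"""Dual-view encoders: pharmacophore-masked molecular graph transformer for
drugs, token-level sequence transformer for proteins, cross-attention fusion.

Drug attention logits receive two additive biases: a subpocket mask M_sp that
emphasizes pharmacophore atoms (H-bond donors/acceptors, aromatic centers)
and a low-rank bilinear form B_eig over the top-k eigenvectors of the drug's
local (combinatorial) Laplacian.  Readout is gated global pooling whose score
is conditioned on the pharmacophore indicator.  The protein side uses
trainable token embeddings plus sinusoidal positions and a prepended
classification token; per-residue states are retained for fusion.  A learned
gate alpha blends the projected concatenation [h_d || h_t] with the
cross-attended h_fuse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Embedding,
    Linear,
    LayerNorm,
    Module,
    MultiHeadAttention,
    Tensor,
    TransformerBlock,
    concat,
    sinusoidal_positions,
)

__all__ = [
    "MolecularGraph",
    "EncoderConfig",
    "FusedPairEmbedding",
    "SmilesParseError",
    "smiles_to_graph",
    "DrugEncoder",
    "ProteinEncoder",
    "FusionBlock",
]

_ELEMENTS = ["C", "N", "O", "P", "S", "F", "Cl", "Br", "I", "B", "*"]
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {ch: i for i, ch in enumerate(_AA)}
_UNK = len(_AA)  # X and anything unexpected


class SmilesParseError(ValueError):
    pass


@dataclass
class MolecularGraph:
    """Heavy-atom molecular graph with pharmacophore annotation and local
    Laplacian eigenvector coordinates."""

    smiles: str  # canonical form
    elements: list
    aromatic: np.ndarray  # bool per atom
    charges: np.ndarray
    n_hs: np.ndarray
    bonds: np.ndarray  # (B, 3): i, j, order (1.5 = aromatic)
    pharmacophore: np.ndarray  # (n, 3) bool: donor, acceptor, aromatic_center
    local_eigvecs: np.ndarray = field(default=None)  # (n, k)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def is_pharmacophore(self) -> np.ndarray:
        return self.pharmacophore.any(axis=1)


def _local_laplacian_eigvecs(n: int, bonds: np.ndarray, k: int) -> np.ndarray:
    """Lowest-k eigenvectors of the unnormalized bond-graph Laplacian,
    sign-fixed, zero-padded to width k."""
    L = np.zeros((n, n))
    for i, j, _ in bonds:
        i, j = int(i), int(j)
        L[i, i] += 1
        L[j, j] += 1
        L[i, j] -= 1
        L[j, i] -= 1
    vals, vecs = np.linalg.eigh(L)
    out = np.zeros((n, k), dtype=np.float32)
    kk = min(k, n)
    for m in range(kk):
        v = vecs[:, m]
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if nz.size and v[nz[0]] < 0:
            v = -v
        out[:, m] = v
    return out


def smiles_to_graph(smiles: str, k: int = 6) -> MolecularGraph:
    """Parse and canonicalize a SMILES string into a MolecularGraph.

    Pharmacophore rules: donor = N/O bearing at least one hydrogen,
    acceptor = any N/O, aromatic_center = aromatic atom.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    # canonical atom numbering: the same molecule always yields the same
    # graph regardless of how its SMILES was written
    ranks = list(Chem.CanonicalRankAtoms(mol))
    mol = Chem.RenumberAtoms(mol, sorted(range(mol.GetNumAtoms()), key=ranks.__getitem__))
    n = mol.GetNumAtoms()
    elements, aromatic, charges, n_hs = [], [], [], []
    pharm = np.zeros((n, 3), dtype=bool)
    for a in mol.GetAtoms():
        sym = a.GetSymbol()
        elements.append(sym if sym in _ELEMENTS else "*")
        aromatic.append(a.GetIsAromatic())
        charges.append(a.GetFormalCharge())
        nh = a.GetTotalNumHs()
        n_hs.append(nh)
        if sym in ("N", "O"):
            pharm[a.GetIdx(), 1] = True  # acceptor
            if nh >= 1:
                pharm[a.GetIdx(), 0] = True  # donor
        if a.GetIsAromatic():
            pharm[a.GetIdx(), 2] = True
    bonds = np.array(
        [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), 1.5 if b.GetIsAromatic() else b.GetBondTypeAsDouble())
            for b in mol.GetBonds()
        ],
        dtype=np.float64,
    ).reshape(-1, 3)
    return MolecularGraph(
        smiles=canonical,
        elements=elements,
        aromatic=np.array(aromatic),
        charges=np.array(charges, dtype=np.float64),
        n_hs=np.array(n_hs, dtype=np.float64),
        bonds=bonds,
        pharmacophore=pharm,
        local_eigvecs=_local_laplacian_eigvecs(n, bonds, k),
    )


@dataclass
class EncoderConfig:
    """Hyperparameters for both views.

    Reference scale is hidden size 512 with 4-layer 8-head transformers and a
    2048-wide feed-forward (dropout 0.1); :meth:`desk` is the shrunk profile
    used for CPU-scale experiments.
    """

    d: int = 512
    drug_layers: int = 4
    drug_heads: int = 8
    protein_layers: int = 4
    protein_heads: int = 8
    ffn: int = 2048
    dropout: float = 0.1
    eig_rank: int = 4
    k_local: int = 6
    use_subpocket_mask: bool = True
    use_eig_bias: bool = True
    fusion: str = "cross_attention"  # | concat
    #: average-pool residue states in blocks of this size before cross-view
    #: fusion (1 = no pooling); the desk profile uses 4 to bound pair cost
    fusion_residue_stride: int = 1

    @classmethod
    def desk(cls, d: int = 64, **overrides) -> "EncoderConfig":
        base = dict(
            d=d, drug_layers=1, drug_heads=4, protein_layers=1, protein_heads=4,
            ffn=2 * d, dropout=0.1, fusion_residue_stride=4,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class FusedPairEmbedding:
    h_d: Tensor
    h_t: Tensor
    h_fuse: Tensor
    gate: Tensor  # in (0, 1)
    joint: Tensor  # [h_d || h_t || blend]


class DrugEncoder(Module):
    """Graph transformer over atoms with M_sp and B_eig attention biases."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        c = config
        self.config = c
        self.element_emb = Embedding(len(_ELEMENTS), c.d, rng)
        self.feat_proj = Linear(6, c.d, rng)
        self.eig_proj = Linear(c.k_local, c.d, rng)
        self.blocks = [
            TransformerBlock(c.d, c.drug_heads, c.ffn, c.dropout, rng) for _ in range(c.drug_layers)
        ]
        self.out_norm = LayerNorm(c.d)
        # one learnable mask scalar per pharmacophore class (donor/acceptor/aromatic)
        self.mask_scalars = Tensor(np.full(3, 0.5, dtype=np.float32), requires_grad=True)
        # low-rank bilinear eigen bias, symmetric at initialization (V starts at U)
        U0 = rng.normal(0, 0.3, size=(c.k_local, c.eig_rank)).astype(np.float32)
        self.bias_U = Tensor(U0.copy(), requires_grad=True)
        self.bias_V = Tensor(U0.copy(), requires_grad=True)
        self.pool_score = Linear(c.d, 1, rng)
        self.pool_pharm = Tensor(np.array([1.0], dtype=np.float32), requires_grad=True)
        self.pool_proj = Linear(c.d, c.d, rng)

    # -- biases --------------------------------------------------------------
    def attention_bias(self, mols: list, pad: int) -> tuple[Tensor, np.ndarray]:
        """Batched M_sp + B_eig, shape (B, pad, pad), plus the atom mask."""
        B = len(mols)
        mask = np.zeros((B, pad), dtype=bool)
        pharm_any = np.zeros((B, pad), dtype=np.float32)
        pharm_cls = np.zeros((B, pad, 3), dtype=np.float32)
        eig = np.zeros((B, pad, self.config.k_local), dtype=np.float32)
        for b, m in enumerate(mols):
            n = m.n_atoms
            mask[b, :n] = True
            pharm_any[b, :n] = m.is_pharmacophore
            pharm_cls[b, :n] = m.pharmacophore
            kk = min(self.config.k_local, m.local_eigvecs.shape[1])
            eig[b, :n, :kk] = m.local_eigvecs[:, :kk]

        zero = Tensor(np.zeros((B, pad, pad), dtype=np.float32))
        bias = zero
        if self.config.use_subpocket_mask:
            # per-atom score = sum of class scalars over active classes;
            # M_sp[i, j] = s_i + s_j when both atoms are pharmacophoric
            s = (Tensor(pharm_cls) * self.mask_scalars).sum(axis=-1)  # (B, pad)
            both = pharm_any[:, :, None] * pharm_any[:, None, :]
            msp = (s.reshape(B, pad, 1) + s.reshape(B, 1, pad)) * Tensor(both)
            bias = bias + msp
        if self.config.use_eig_bias:
            phiU = Tensor(eig) @ self.bias_U  # (B, pad, rank)
            phiV = Tensor(eig) @ self.bias_V
            bias = bias + phiU @ phiV.swapaxes(1, 2)
        return bias, mask

    def __call__(self, mols: list, rng: np.random.Generator | None = None):
        """Encode a list of molecules; returns (h_d (B, d), atom states
        (B, pad, d), atom mask)."""
        c = self.config
        pad = max(m.n_atoms for m in mols)
        B = len(mols)
        elem_idx = np.zeros((B, pad), dtype=np.int64)
        feats = np.zeros((B, pad, 6), dtype=np.float32)
        for b, m in enumerate(mols):
            n = m.n_atoms
            elem_idx[b, :n] = [_ELEMENTS.index(e) for e in m.elements]
            feats[b, :n, 0] = m.aromatic
            feats[b, :n, 1] = m.charges
            feats[b, :n, 2] = m.n_hs / 4.0
            feats[b, :n, 3:6] = m.pharmacophore
        bias, mask = self.attention_bias(mols, pad)
        kk = min(c.k_local, pad)
        eig = np.zeros((B, pad, c.k_local), dtype=np.float32)
        for b, m in enumerate(mols):
            eig[b, : m.n_atoms, : min(c.k_local, m.local_eigvecs.shape[1])] = m.local_eigvecs[
                :, : min(c.k_local, m.local_eigvecs.shape[1])
            ]
        h = (
            self.element_emb.W.gather_rows(elem_idx.ravel()).reshape(B, pad, c.d)
            + self.feat_proj(Tensor(feats))
            + self.eig_proj(Tensor(eig))
        )
        for blk in self.blocks:
            h = blk(h, bias=bias, key_mask=mask, rng=rng)
        h = self.out_norm(h)
        # gated global pooling conditioned on the pharmacophore indicator
        pharm_any = np.zeros((B, pad), dtype=np.float32)
        for b, m in enumerate(mols):
            pharm_any[b, : m.n_atoms] = m.is_pharmacophore
        score = self.pool_score(h).reshape(B, pad) + Tensor(pharm_any) * self.pool_pharm
        g = score.softmax(axis=-1, mask=mask)  # (B, pad)
        h_d = (g.reshape(B, pad, 1) * self.pool_proj(h)).sum(axis=1)
        return h_d, h, mask


class ProteinEncoder(Module):
    """Sequence transformer with trainable token embeddings, sinusoidal
    positions and classification-token pooling.  Externally supplied
    per-residue embeddings (e.g. from a protein language model) may be passed
    instead of raw sequences via `residue_embeddings`."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        c = config
        self.config = c
        self.token_emb = Embedding(_UNK + 1, c.d, rng)
        self.cls = Tensor(rng.normal(0, 0.02, size=(1, 1, c.d)).astype(np.float32), requires_grad=True)
        self.blocks = [
            TransformerBlock(c.d, c.protein_heads, c.ffn, c.dropout, rng)
            for _ in range(c.protein_layers)
        ]
        self.out_norm = LayerNorm(c.d)
        self.in_proj: Linear | None = None  # set lazily for external embeddings

    def __call__(
        self,
        sequences: list,
        rng: np.random.Generator | None = None,
        residue_embeddings: list | None = None,
    ):
        c = self.config
        B = len(sequences)
        if any(len(s) == 0 for s in sequences):
            raise ValueError("empty protein sequence")
        pad = max(len(s) for s in sequences)
        if residue_embeddings is not None:
            emb = np.zeros((B, pad, c.d), dtype=np.float32)
            for b, e in enumerate(residue_embeddings):
                emb[b, : len(e)] = e[:, : c.d]
            tok = Tensor(emb)
        else:
            idx = np.zeros((B, pad), dtype=np.int64)
            for b, s in enumerate(sequences):
                idx[b, : len(s)] = [_AA_INDEX.get(ch, _UNK) for ch in s]
            tok = self.token_emb.W.gather_rows(idx.ravel()).reshape(B, pad, c.d)
        tok = tok + Tensor(sinusoidal_positions(pad, c.d)[None])
        cls = self.cls * Tensor(np.ones((B, 1, 1), dtype=np.float32))
        h = concat([cls, tok], axis=1)
        mask = np.ones((B, pad + 1), dtype=bool)
        for b, s in enumerate(sequences):
            mask[b, 1 + len(s) :] = False
        for blk in self.blocks:
            h = blk(h, key_mask=mask, rng=rng)
        h = self.out_norm(h)
        h_t = h[:, 0, :]
        residues = h[:, 1:, :]
        return h_t, residues, mask[:, 1:]


def _pool_tokens(states: Tensor, mask: np.ndarray, stride: int):
    """Masked average pooling of token states in blocks of `stride`."""
    if stride <= 1:
        return states, mask
    B, T, d = states.shape
    Tp = int(np.ceil(T / stride)) * stride
    w = np.zeros((B, Tp), dtype=np.float32)
    w[:, :T] = mask
    if Tp > T:
        states = concat([states, Tensor(np.zeros((B, Tp - T, d), dtype=np.float32))], axis=1)
    num = (states * Tensor(w[:, :, None])).reshape(B, Tp // stride, stride, d).sum(axis=2)
    cnt = w.reshape(B, Tp // stride, stride).sum(axis=2)
    pooled = num * Tensor((1.0 / np.maximum(cnt, 1.0))[:, :, None])
    return pooled, cnt > 0


class FusionBlock(Module):
    """Single cross-attention block plus the learned blend gate."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        c = config
        self.config = c
        heads = c.drug_heads
        self.d2p = MultiHeadAttention(c.d, heads, rng)  # drug tokens attend residues
        self.p2d = MultiHeadAttention(c.d, heads, rng)
        self.gate_w = Linear(3 * c.d, 1, rng)
        self.concat_proj = Linear(2 * c.d, c.d, rng)

    def __call__(
        self,
        h_d: Tensor,
        atom_states: Tensor,
        atom_mask: np.ndarray,
        h_t: Tensor,
        residue_states: Tensor,
        residue_mask: np.ndarray,
    ) -> FusedPairEmbedding:
        c = self.config
        B = h_d.shape[0]
        if c.fusion == "concat":
            h_fuse = Tensor(np.zeros((B, c.d), dtype=np.float32))
            gate = Tensor(np.ones((B, 1), dtype=np.float32))
            blend = self.concat_proj(concat([h_d, h_t], axis=-1))
        else:
            residue_states, residue_mask = _pool_tokens(
                residue_states, residue_mask, c.fusion_residue_stride
            )
            da = self.d2p(atom_states, residue_states, residue_states, key_mask=residue_mask)
            pa = self.p2d(residue_states, atom_states, atom_states, key_mask=atom_mask)
            # masked mean pooling of both attended token sets
            am = atom_mask.astype(np.float32)
            rm = residue_mask.astype(np.float32)
            d_pool = (da * Tensor(am[:, :, None])).sum(axis=1) * Tensor(
                (1.0 / np.maximum(am.sum(axis=1), 1.0))[:, None]
            )
            p_pool = (pa * Tensor(rm[:, :, None])).sum(axis=1) * Tensor(
                (1.0 / np.maximum(rm.sum(axis=1), 1.0))[:, None]
            )
            h_fuse = (d_pool + p_pool) * 0.5
            gate = self.gate_w(concat([h_d, h_t, h_fuse], axis=-1)).sigmoid()
            blend = gate * self.concat_proj(concat([h_d, h_t], axis=-1)) + (1.0 - gate) * h_fuse
        joint = concat([h_d, h_t, blend], axis=-1)
        return FusedPairEmbedding(h_d=h_d, h_t=h_t, h_fuse=h_fuse, gate=gate, joint=joint)
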