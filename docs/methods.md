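# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, and what the synthetic benchmark does and does
not demonstrate.

## Problem setting

Given a heterogeneous knowledge graph with drug, protein and pathway nodes
joined by four undirected relations (drug–target, drug–drug, drug–pathway,
pathway–target), the package predicts binary drug–target interactions (DTI)
for two focal kinase tasks jointly (dual-task heads over a shared trunk),
calibrates the predicted probabilities with graph-geometric penalties, and
scores candidate drug combinations with an additive text-derived safety
penalty.

## Spectral machinery

**Relation-weighted operator.** 𝒢 = Σ_r ω_r D_r^{-1/2} A_r D_r^{-1/2} with
per-relation degree normalization; rows of a relation in which a node is
isolated contribute zero (0/0 ≔ 0). Defaults: ω_r = 1/4 each. With
Σ ω_r = 1 the spectrum of 𝒢 lies in [−1, 1] and L = I − 𝒢 in [0, 2]. The
operator kind (normalized adjacency vs normalized Laplacian) is a flag; all
eigen-quantities are reported in Laplacian convention internally.

**Eigenbasis.** Per connected component, the lowest-frequency eigenpairs of
L, allocated proportionally to component size (minimum one per component,
largest-remainder rounding), block-concatenated. Eigenvectors are unit-norm
and sign-fixed (first nonzero coordinate positive). Feature expansion uses
Φ̃ = col_norm(|Φ|), which is sign-unambiguous; quantities sensitive to
basis rotation inside degenerate eigenspaces (raw coordinates) are never
compared across runs — only diffusion distances, which are invariant.

**Diffusion distance.** d²(u,v;t) = Σ_m e^{−2tλ_m}(φ_m(u) − φ_m(v))² with
λ_m the *Laplacian* eigenvalues. The heat-kernel weight e^{−2tλ} requires
λ ≥ 0 and damps high-frequency modes; reading λ as adjacency eigenvalues
would invert the geometry. With the full basis this equals the Euclidean
distance between rows of e^{−tL} (verified against `scipy.linalg.expm` to
1e−8); truncation lower-bounds it. Default t = 1.0. Cross-component pairs
receive a finite dominating sentinel: twice the largest finite
within-component distance, recomputed per basis. Meta-path geodesics cost 1
on drug–pathway and pathway–target edges and 2 elsewhere, so a
drug→pathway→target chain (length 2) ties a direct drug–target edge —
pathway-mediated proximity is prioritized. Unreachable pairs get the same
2× sentinel construction. Both distances are z-scored over observed edges
before entering attention features.

**Dirichlet energy.** tr(HᵀLH), computed exactly by the library function.
Inside the composite loss it is divided by the number of embedding entries
(n·d) so the weight η is transferable across problem sizes; η defaults to
1e−3 within the stated [1e−4, 1e−2] range.

## Encoders

**Drug view.** Heavy-atom molecular graphs come from RDKit with canonical
atom renumbering, so the same molecule always produces the identical graph
regardless of SMILES spelling — this is what makes the encoder exactly
permutation-invariant. Pharmacophore perception: donor = N/O with ≥ 1 H,
acceptor = N/O, aromatic center = aromatic atom. Attention logits receive
two additive biases: the subpocket mask M_sp[i,j] = s_i + s_j (s = sum of
learnable per-class scalars) when both atoms are pharmacophoric, else 0;
and B_eig = (ΦU)(ΦV)ᵀ, a rank-4 bilinear form over the top-k (default 6)
eigenvectors of the unnormalized bond-graph Laplacian, initialized
symmetric (V = U at init). Readout is gated pooling whose score adds a
learnable pharmacophore-indicator term.

**Protein view.** Trainable token embeddings (20 amino acids + unknown) with
sinusoidal positions and a prepended classification token; pooled h_t is
the final CLS state. The interface also accepts externally supplied
per-residue embeddings so a pretrained protein language model can be
plugged in; at desk scale the trainable embeddings stand on their own.

**Fusion.** One cross-attention block in each direction (atoms↔residues),
masked-mean pooled and averaged into h_fuse; a learned logistic gate α
blends the projected concatenation with h_fuse: blend = α·P[h_d‖h_t] +
(1−α)·h_fuse. The head consumes [h_d ‖ h_t ‖ blend]; at α→1 this is exactly
the concatenation ablation, at α→0 exactly the cross-attended fusion. At
desk scale residue states are average-pooled in blocks of 4 before fusion
(`fusion_residue_stride`), bounding the per-pair attention cost.

**Pipeline wiring.** The aggregator propagates H⁰ = [X ‖ Φ̃] (static node
features plus spectral coordinates), column-standardized before the input
projection — the spectral coordinates are unit-norm over all nodes (entries
of order 1/√n) and would otherwise be dwarfed by the raw feature columns,
leaving them unused within a short training budget; encoder outputs and aggregated node
embeddings are then combined per entity, h_d = enc(SMILES) + W_g H[d] and
likewise for proteins, before fusion. This follows the training algorithm's
data flow literally while keeping the spectral machinery, the graph
aggregator and both encoders on the prediction path, which is what the
SPSE and aggregator ablations require to be meaningful.

## Aggregator

K layers of relation-aware attention: α_vu ∝ exp(LeakyReLU(aᵀ[Wh_v ‖ Wh_u ‖
e_vu ‖ ẑ_geo ‖ ẑ_diff])) per head, update h_v ← ELU(W_s h_v + Σ α_vu W R_t
h_u). Conventions chosen where unspecified: heads concatenated in hidden
layers and averaged (shared value projection) at the last; LeakyReLU slope
0.2; edge-drop is Bernoulli per layer per step (seeded); fan-out caps
incoming edges per (destination, relation) at 10 in train mode; eval mode
uses full neighborhoods and is bitwise deterministic. The library default
depth is K = 6; the desk profile uses K = 3 (both documented settings of
the reference design — the depth is exposed as configuration). Learned
relation weights are available as a softmax-constrained scaling of
per-relation messages (`omega_mode: learned`); the spectral operator itself
always uses the configured fixed ω_r, since eigendecomposition is not
differentiated through.

## Objectives

ℒ = ℒ_dti + β ℒ_cont + γ ℒ_meta + η ℒ_spec, with β = 0.5, γ = 0.3,
η = 1e−3. ℒ_dti is the mean of per-task BCEs over the tasks present in the
batch (dual heads, shared trunk); per-task data-fraction masks support
asymmetric-ablation protocols.

**Contrastive.** For sampled batch pairs, the anchor view is the
2-hop subgraph around {d, t} constrained to meta-path relations
(drug–target, drug–pathway, pathway–target), with seeded per-hop neighbor
capping (8 per node, ≤ 48 nodes) so pathway hubs do not pull in entire
communities; the positive view resamples anchor nodes with keep-probability
exp(−d_diff/median) (the pair always kept); the perturbed view drops 20% of
anchor edges and enters every denominator as an extra negative alongside
the in-batch anchors. Views are propagated as one block-diagonal graph;
projections are a 2-layer perceptron to 128 dims, ℓ2-normalized, τ = 0.07.

**Meta-learning.** First-order episodic adaptation (FOMAML): episodes are
keyed by target family (the two tasks); a deep-copied clone of the task
head is adapted on the detached support embeddings with inner AdamW
(α = 0.01, 2 steps, support/query 8/8, 2 episodes per step), the query BCE
of the adapted clone is added to the loss, and the clone's gradients are
transferred to the original head after backprop. Only the heads adapt in
the inner loop; the trunk receives first-order meta-gradients through the
query embeddings. Full-network inner adaptation is a straightforward
extension but is not worth its step cost at this scale.

**Optimization.** AdamW, cosine-annealed learning rate, decoupled weight
decay 1e−2, global gradient clipping at 1.0, batch 64, early stopping on
validation AUPR with patience 10. Library default base LR is 1e−4 (100
epochs); the desk profile uses 3e−3 over 30 epochs × 8 capped steps per
epoch (~240 steps), enough for the supervised loss to plateau before the
best-epoch checkpoint is chosen — with fewer steps per epoch the noisy
early validation AUPR occasionally freezes an undertrained checkpoint.

## Calibration and combination scoring

p′ = p · exp(−λ₁ d_geo − λ₂ d_diff), so probabilities are only ever damped
and ranking within fixed distances is preserved. (λ₁, λ₂) minimize 15-bin
equal-width ECE on the validation fold over the grid {0, 0.01, 0.05, 0.1,
0.2}², ties toward smaller λ₁+λ₂. Auditing reports ECE, Brier, the
reliability table, and an isotonic-regression comparison that is never
applied to outputs.

Combination design: s_multi(d) = min(p′ for the two focal targets) —
coverage limited by the weaker arm (product and mean are selectable);
agents are oriented to the target where their calibrated probability is
higher; S_pair = 0.4 p′₁ + 0.4 p′₂ + 0.2 σ(cos(h_d, h_d′)) − ψ on the
aggregated drug embeddings; S_Bliss = 1 − (1−p′₁)(1−p′₂). The safety
penalty ψ uses the printed default weights (serious 3, moderate 1, QT 2
escalating to 3 for dual-QT or torsade, CYP conflict 2 strong / 1 moderate,
P-gp/BCRP 1, hepatotoxicity 1); contraindication is a hard drop, reported
for audit but never summed. Severity counts are distinct interaction
sentences containing a serious-/moderate-class marker; CYP conflicts
require the same CYP family on the inhibitor and substrate roles. The
shipped lexicon is an illustrative fixture, not a clinical resource.

## Synthetic benchmark

The generator emulates the ingested schema with a known ground truth:
protein families have latent centers (proteins = center + noise, σ = 0.3,
family motif of length 8 planted in an 80–200-residue sequence with a
family-biased residue composition); pathways are "about" 1–2 families;
drugs inherit their primary pathway's latent center (+ noise, σ = 0.4);
a pair is positive iff the latent dot product exceeds a threshold
calibrated on an independent Monte-Carlo draw to hit the target positive
rate (default 0.2). SMILES come from 30 validated hydrocarbon templates
with amide/hydroxyl/aromatic substituents switched by the latent signs;
drug–drug texts embed one labeled risk motif at the configured rate. One
seed drives hierarchical graph/text/label streams; output is byte-identical
per (config, seed).

What passing the end-to-end experiment shows: the implementation can
recover a planted, structured signal through all of its components, the
spectral features and distance biases help on held-out proteins, and the
whole pipeline is deterministic and leakage-free (held-out positives'
drug–target edges are removed from the propagation graph before the
spectral precomputation). What it does not show: performance on real
pharmacology — real chemical space, binding promiscuity, assay noise,
database biases and family definitions are all much harder than the
planted rule.

**Study conditions** (the acceptance experiment): 300 drugs, 40 proteins in
5 families, 12 pathways, 2 focal families; ~860 labeled pairs after 2:1
negative sampling and a 900-pair cap; unseen-protein 5-fold split, one fold
per seed; model d = 64, K = 3, 1-layer encoders, 30 epochs; 5 seeds for the
full model and 5 for the no-SPSE ablation. One training run takes ~45 s on
one CPU core.

## Numerical choices

float32 throughout the network (reductions on float64 inputs preserve
float64, which the oracle tests use); dense symmetric eigensolver below 500
nodes, iterative sparse above (tol 1e−9); eigenpairs sorted by eigenvalue
with sign fixing; ECE bins equal-width; empty-bin terms contribute zero;
degenerate validation folds (one class) report NaN metrics rather than
failing; empty neighborhoods fall back to the self term; zero-column
feature matrices and pathway-free graphs are supported end to end.

## Known limitations

No stereochemistry or 3D conformers; no pretrained protein language model
weights (interface only); second-order meta-gradients not implemented;
full-batch spectral precomputation assumes desk-scale graphs (all-pairs
distance caches are dense); the negative sampler's "balanced" strategy
equalizes entity appearance only approximately (±1 after rounding) when
candidate pools are small.
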