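# Methods

`stcontrast` identifies spatial domains in spot-resolved transcriptomics by
learning a joint representation of three modalities — gene expression,
spatial position, and histology-image patches — with self-supervised
contrastive learning, then clustering that representation. This note
describes the model, its assumptions, the tunable parameters, the synthetic
test-bed, and the numerical choices made where the design was open.

## Model

**Inputs.** A slice is a spot × gene count matrix `X`, spot pixel
coordinates, and (optionally) an RGB image. Preprocessing selects the top
`n_hvg = 3000` genes by normalized dispersion (Seurat-flavor ranking on a
log-normalized copy), scales each spot to a library size of 10⁴, and applies
`log(1 + x)`. The pipeline order is HVG selection → normalization → log.
Patches are squares matched to the spot diameter (112 px for ST/Visium,
30 px for Xenium, configurable otherwise), zero-padded at image borders.

**Graphs.** Two graphs are built from the data:

* the *spatial graph* `G`: each spot is connected to its `k = 6` nearest
  neighbors by Euclidean pixel distance (edges symmetrized by union; ties
  break to the lower spot index);
* the *similarity adjacency* `A`: among each spot's 6 nearest spatial
  neighbors, the single neighbor with the most similar expression profile
  (cosine by default; Pearson/Euclidean configurable) gets a symmetric edge.
  `A` drives the neighbor-smoothing augmentation.

**Gene encoder.** A two-layer mean-aggregation graph network
(GraphSAGE-style) over `G` with minibatch neighborhood sampling: per batch,
`B = 256` seed spots are drawn, with up to `fanout = (6, 6)` first- and
second-order neighbors sampled uniformly without replacement. Layer 0
updates every seed and sampled first-order node from the mean of its own
input feature and its sampled children's; layer 1 updates each seed from its
own layer-0 output and its sampled neighbors'. (The seed's first-order input
is its layer-0 output — the canonical two-layer reading.) Activation is ELU;
the embedding dimension is `d = 64`.

**Image encoder.** A frozen backbone maps each patch to a fixed feature
vector; a trainable two-layer MLP head refines it to dimension `d`. The
backbone is pluggable; the shipped default is a fixed-seed, randomly
initialized two-layer convolutional extractor over an adaptively pooled
patch, concatenated with per-channel color statistics. Random convolutional
features preserve exactly the color/coarse-texture contrasts that spot-level
patches carry; the frozen contract (identical output for identical input,
zero gradient) is what the rest of the model relies on and is enforced by a
checksum test.

**Fusion.** With a scalar weight `k_emb ∈ (0, 1)`, the fused representation
is `h_f = W_f · concat(k_emb · h_ST, (1 − k_emb) · h_img)`. `k_emb` is tuned
by reinforcement learning (below); `W_f` is trainable.

**Objectives.** Three losses are minimized jointly, `L = L_con + γ₂ (L_rec_b
+ γ₁ L_rec_a)` with `γ₁ = γ₂ = 1`:

* *adjacency reconstruction* `L_rec_a`: for spot pairs connected in the
  batch subgraph, the predicted connection probability is
  `sigmoid(h_f_i · h_f_j)`; the loss averages `(1 − p)²` over edges
  (restricted to positive pairs, since the k-NN graph is sparse). It is
  evaluated on seed–seed edges because fused embeddings exist only for
  seeds under minibatch sampling.
* *expression reconstruction* `L_rec_b`: a two-layer graph-convolution
  decoder (symmetric degree-normalized adjacency with self-loops, ELU hidden
  layer of width 256, linear output) maps `h_f` back to expression space;
  the loss is the squared error. The library-level `expression_loss`
  operation returns the plain sum over entries; the optimizer uses its
  per-entry mean so the three components share a scale under unit γ weights.
* *contrastive* `L_con`: InfoNCE at temperature `τ = 0.5` with tuple-
  disturbed negatives (below), `n_neg = 16` negatives per anchor, per-pair
  form `softplus((s⁻ − s⁺)/τ)` averaged over pairs — algebraically the
  two-term InfoNCE with the temperature inside the exponential.

**Positive views.** The gene view is augmented at the embedding level:
`(h_i + mean of A-neighbors present in the batch)/2` (isolated spots pass
through), then unit Gaussian noise on a random 30% of embedding dimensions
(drawn once per call, shared across the batch), then row-mean imputation of
missing values. The image view re-encodes an augmented patch: horizontal and
vertical flips each with probability 0.3, Gaussian blur with probability
0.3, and a rotation drawn uniformly from [0°, 360°) with reflect padding.
Pixel-value jitter is deliberately avoided — it would distort the tissue
semantics the patch carries.

**Tuple-disturbed negatives.** Each spot is a two-view tuple
`(W_ST (k_emb h_ST), W_img ((1−k_emb) h_img))` with a pseudo-label from
seeded K-means on the initial image embeddings (computed once, before
training; `K_pseudo` defaults to the target domain count). For an anchor, a
pseudo-label-mismatched sample `h_j` is drawn uniformly from the batch
(falling back to any other spot with a warning if no mismatch exists), and
with probabilities `(α₀, α₁, α₂)` either the whole tuple or exactly one view
is replaced by `h_j`'s. Single-view disturbance forces the model to exploit
the disturbed (often weaker) modality. Anchors, positives and negatives are
all fused with the shared `W_f`, so the contrastive space coincides with the
clustering space.

**Reinforcement-learning hyper-parameter tuning.** Two Gaussian policies
with fixed scales (`σ = 0.3`) and learning rate `η = 0.05` tune the raw
(unconstrained) parameters behind `α` (softmax projection onto the simplex)
and `k_emb` (logistic projection into (0, 1), clamped one ulp inside the
interval). Training alternates: on even epochs `B_rl` candidate `α` values
are sampled, on odd epochs candidate `k_emb` values (`B_rl = 4` by default;
the acceptance conditions use 2). Each candidate trains one epoch from a
shared snapshot of model-plus-optimizer state; its reward is the relative
gain in *cross-modal agreement* — the ARI between seeded K-means labelings
of the image-modality and gene-modality embeddings — over the current model
(a near-zero baseline ARI falls back to the absolute difference). The
best-reward candidate's weights are kept, and the policy mean moves by the
REINFORCE rule `μ ← μ + η·(1/B_rl)·Σ R_i (x_i − μ)/σ²` with the projection
treated as part of the environment. All candidates within an epoch share
one minibatch/augmentation random stream (common random numbers), so reward
differences isolate the hyper-parameter's effect; without this the weak but
real modality-balance signal is swamped by stream noise. Rejected
candidates' gradients are discarded.

## Multi-slice integration

Slices are never spatially registered. Images are horizontally concatenated
(gap 50 px), coordinates translated accordingly, expression matrices
concatenated on the gene intersection. A global similarity matrix `A*` links
each spot symmetrically to its 6 most expression-similar spots in every
other slice; within-slice blocks reuse each slice's own `A`. Because single
spot profiles are noisy, cross-slice similarities are computed on matching
features: expression averaged twice over the spatial 6-NN neighborhood and
then per-gene standardized within each slice (which also cancels additive
per-gene batch offsets). The *encoder graph* for integration is the union of
the within-slice spatial graph and `A*` — feature extraction itself mixes
matched spots across slices, which is what removes batch effects during
training; augmentation smoothing and contrastive positives likewise span
slices through `A*`.

## Spatial-domain assignment

Clustering runs Leiden (RB-configuration) on a 15-NN graph of the fused
embedding. With a known domain count `K`, the resolution is found by binary
search starting from the bracket [0.01, 3.0] (the upper bound doubles until
`K` is bracketed), terminating on an exact hit or after 50 evaluations and
returning the closest count (ties prefer the lower resolution). Without
`K`, a 59-point grid (0.1 to 3.0, step 0.05) is swept and the labeling with
the highest mean silhouette coefficient on the embedding is kept —
silhouette is this package's reading of a "structural clustering" score;
degenerate labelings are skipped and ties prefer the lower resolution.

An optional refinement pass (off by default; intended for broad-domain
tissue, not fine-grained structures) reassigns each spot to the modal label
within radius `r` (default 1.5 × median nearest-neighbor distance, covering
the first neighbor shell); it is a single synchronous pass, ties keep the
current label, and it can never introduce a new label.

Metrics: ARI and NMI against ground truth when available, Davies-Bouldin on
the embedding otherwise. Denoised expression `X̂` is the decoder applied to
the full-data fused embedding over the full spatial graph. UMAP, PAGA and
marker-gene ranking are thin scanpy wrappers carrying no bespoke logic.

## Synthetic test-bed

`make_tissue` places spots on an `n_side × n_side` grid (16 px pitch)
partitioned into `K` contiguous horizontal bands. Counts are Poisson-Gamma
(negative binomial, shape 2.0) around a heterogeneous per-gene baseline;
each band elevates its own block of 10 program genes by `exp(effect)`;
Bernoulli dropout (30%) and log-normal spot-level jitter (σ = 0.3) add the
sparsity and overdispersion typical of spot-level data. The image gives each
spot's neighborhood a domain base color mixed with uniform pixel noise at
weight `1 − image_signal`. `make_multislice` replicates the layout with
independent counts, an additive per-gene N(0, batch_shift_sd²) shift on the
log scale of the means, and optional cropping to partial spatial overlap.

The defaults (30 × 30 grid, K = 4, 200 genes, effect 2.0, image_signal 0.7)
are the study conditions the tests and the acceptance script run under;
30 training epochs with 2 RL candidates keep a full run around a minute on
one CPU. What the generator does *not* emulate: real H&E morphology
(textures, nuclei), platform-specific artifacts, irregular tissue borders,
or continuous domain gradients. Passing tests therefore demonstrate that the
machinery recovers planted structure under realistic noise — not performance
on real tissue.

## Numerical and engineering choices

* **No deep-learning framework.** The model runs on a small in-package
  reverse-mode autodiff engine over numpy (dense matmuls, ELU/sigmoid/
  softplus, reductions, concatenation, row gathering) with an Adam
  optimizer. Aggregation and graph-convolution operators are constant
  matrices, so a forward pass is a short matmul chain; gradients are
  verified against central differences in the test suite.
* **Determinism.** One seed drives everything: generator, neighbor
  sampling, augmentation, pseudo-labels, RL sampling, K-means and Leiden.
  Two runs with the same config and seed produce bit-identical embeddings
  (single-threaded).
* **Stability.** The per-pair contrastive term is computed as a softplus of
  a score difference (no explicit exponentials of large scores); the
  logistic projection clamps away from 0/1; edgeless batch subgraphs
  contribute zero adjacency loss with a warning; trailing minibatches
  smaller than B/8 are skipped.
* **Tie-breaks.** All similarity and distance ties resolve to the lower
  spot index; resolution ties to the lower resolution.
* **Gene-only mode.** Without an image the fusion weight is pinned at
  ~1, the image branch sees zero features, and pseudo-labels come from the
  initial gene embeddings instead.

## Known limitations

* The frozen random-convolution backbone captures color and coarse texture;
  tissue with morphology-only (color-free) domain cues would need a real
  pretrained histology backbone plugged in.
* The cross-modal-ARI reward is weakly informative when one modality is
  pure noise; the learned fusion weight then drifts in the right direction
  but with high variance across seeds.
* Refinement is a single majority-vote pass, not iterated to convergence.
* The decoder reconstructs the preprocessed (log-normalized) expression,
  not raw counts.
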