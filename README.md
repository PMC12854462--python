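# stcontrast

Multimodal contrastive learning for **spatial-domain identification** in
spatial transcriptomics.

Spot-resolved assays (ST, 10x Visium, Xenium) measure gene expression at
spatially indexed locations, usually alongside an H&E histology image. A
central analysis step is partitioning the spots into *spatial domains* —
coherent tissue regions such as cortical layers or tumor compartments.
Expression alone is noisy and sparse; histology alone is ambiguous;
`stcontrast` fuses both, plus spatial context, into one embedding and
clusters that.

The package is aimed at computational biologists analyzing spot-level data:
single slices, or several adjacent/overlapping slices integrated **without
any spatial alignment**, with built-in batch-effect handling.

## Method at a glance

- A two-layer mean-aggregation graph encoder over the spatial k-NN graph
  (k = 6) embeds expression; a frozen convolutional backbone plus a
  trainable MLP head embeds per-spot image patches.
- The fused representation is `h_f = W_f · concat(k_emb·h_ST, (1−k_emb)·h_img)`,
  where the fusion weight `k_emb ∈ (0,1)` balances the modalities.
- Training jointly minimizes
  `L = L_con + γ₂(L_rec_b + γ₁ L_rec_a)`:
  an InfoNCE contrastive loss with **tuple-disturbed negatives** (a
  pseudo-label-mismatched sample replaces the whole tuple with probability
  α₀, or exactly one modality view with probabilities α₁/α₂ — forcing the
  model to use weak modalities), a graph-reconstruction loss
  `sigmoid(h_f_i·h_f_j)` on connected pairs, and a graph-convolutional
  decoder's expression-reconstruction loss.
- The hyper-parameters `α` and `k_emb` are tuned online by REINFORCE:
  candidate values are sampled from Gaussian policies, each trains the model
  one epoch, and the reward is the relative gain in agreement (ARI) between
  clusterings of the two unimodal embeddings.
- Domains come from Leiden clustering of `h_f`, with a binary search on the
  resolution when the domain count is known and a silhouette-scored sweep
  (0.1–3.0, step 0.05) when it is not; an optional radius-`r` majority-vote
  pass smooths boundaries. The decoder doubles as an expression denoiser.

Multiple slices are integrated by concatenating images side by side,
translating coordinates, and adding a global similarity graph `A*` that
links each spot to its 6 most expression-similar spots in every other
slice; the encoder, augmentation and contrastive sampling all operate on
the combined graph, so batch effects are corrected during training itself.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Generate a synthetic three-band tissue (the built-in generator ships with
the package), fit the model, and inspect the results:

```python
from stcontrast import TissueSpec, make_tissue, SpatialDomainModel, RunConfig
from stcontrast.config import PolicyConfig

ds = make_tissue(TissueSpec(n_side=15, K=3, n_genes=100, seed=0))
cfg = RunConfig(n_domains=3, epochs=4, seed=0, policy=PolicyConfig(n_candidates=2))
res = SpatialDomainModel(ds, cfg).fit()
print(res.summary())
```

```
Spatial domain identification results
=============================================
spots                       225
genes (post-HVG)            100
epochs                      4
embedding dim               64
fusion weight k_emb         0.5010
negative mixture alpha      (0.332, 0.334, 0.335)
domains found               3
Leiden resolution           0.3837
ARI                         0.9866
NMI                         0.9785
DB                          1.3821
```

The three planted bands are recovered almost exactly (ARI 0.99 against the
generator's labels); `k_emb ≈ 0.50` says both modalities contributed
equally, and the near-uniform `α` means no disturbance type dominated the
negatives. `res.embedding` holds the fused per-spot representation,
`res.labels_` the domain assignment, and `res.predict_expression()` the
decoder-denoised expression matrix.

Multi-slice integration works the same way:

```python
from stcontrast import make_multislice
slices = make_multislice(TissueSpec(batch_shift_sd=1.0, seed=0), n_slices=2)
res = SpatialDomainModel.from_slices(slices, cfg).fit()
```

## Command line

```bash
stcontrast synth --out data/ --seed 0                 # synthetic dataset
stcontrast train --data data/ --out run/ --n-domains 4
stcontrast cluster --run run/ --out run/              # (re-)cluster embedding
stcontrast integrate --data s0/ --data s1/ --out run/ # alignment-free fusion
stcontrast denoise --run run/
stcontrast evaluate --labels run/labels.csv --truth data/labels.csv
```

Every run directory contains a `manifest.json` (resolved config, config
hash, seed, package version) sufficient to reproduce it.

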