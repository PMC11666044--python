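# Methods

## Problem setting

The package classifies subjects of a memory-clinic cohort into normal
control (NC), mild cognitive impairment (MCI), and Alzheimer's disease (AD)
from two modalities: amyloid-PET brain volumes (voxel values expressed as
uptake ratios against a cerebellar reference) and six numeric clinical
indicators — age, years of education, MMSE (cognition, 0–30), CDR-SB
(dementia severity sum-of-boxes, ≥ 0), GDS (global deterioration scale,
1–7), and SGDepS (short geriatric depression scale, ≥ 0). Classification is
node-level on a *population graph*: subjects are nodes, edges encode
inter-subject similarity, and a graph convolutional network (GCN) propagates
label information transductively — test subjects sit in the graph during
training, but only training-node labels enter the loss.

## Imaging feature extraction (3-D DenseNet-BC)

Volumes pass through an initial 3×3×3 convolution producing 2k channels,
then four dense blocks separated by transition layers. Each dense-block
layer applies BN → ReLU → 1×1×1 conv (bottleneck, b·k maps) → BN → ReLU →
3×3×3 conv (k maps) to the concatenation of everything before it, so a block
entered with m channels leaves with m + L·k. A transition layer compresses
to floor(θ·m) channels (1×1×1 conv after BN–ReLU) and halves each spatial
axis by 2×2×2 average pooling with stride 2. After global average pooling,
two fully-connected layers (256 and 64 units) feed the classification head.

Defaults: growth rate k = 32, block layout (3, 6, 12, 8), compression
θ = 0.5, initial channels 2k, dropout 0.2 after each FC layer, Adam at
learning rate 1e−4 with weight decay 1e−5, batch size 32, at most 500
epochs, early stopping with patience 20. The trained network is then used
as a feature extractor: the **post-ReLU activations of the first
fully-connected layer** (256 values by default) are the per-subject imaging
features. Choices the architecture description leaves open, fixed here:

- bottleneck multiplier b = 4 (the standard DenseNet-BC value),
  configurable;
- floor() when θ·m is non-integral;
- global pooling before FC1 is *average* pooling;
- ReLU is applied to FC1 before extraction;
- weight initialisation is fan-in-scaled Gaussian from a recorded seed.

The builder rejects volumes whose axes are not multiples of 2^(blocks−1)
(each transition halves the grid; the minimum stated in the error). Binary
tasks use a single-logit sigmoid head with binary cross-entropy; the
three-class task uses a softmax head with categorical cross-entropy.

## Feature fusion and standardization

Imaging and clinical blocks are standardized column-wise with mean and
*population* SD estimated on the training rows only; columns constant on
the training rows are flagged and mapped to zero. The fused node feature
vector is the concatenation [imaging, clinical] (262-wide at defaults).
Standardization precedes both fusion and edge assignment, so no test-row
statistic ever reaches the model.

## Edge assignment

Two rules convert pairwise affinities into edges, each blending the
imaging-block and clinical-block affinity matrices with a usage ratio
β ∈ [0, 1] (β = 1: imaging only; β = 0: clinical only):

- **Cosine (weighted)**: blended cosine similarity kept as the edge weight
  wherever it is ≥ α_CS; comparisons are inclusive. Rows with norm < 1e−12
  get cosine 0 against all others (guard for degenerate features).
- **Euclidean (binary)**: per-feature distances ‖z_i − z_j‖ / p (dividing
  by the feature count p keeps blocks of different width comparable);
  pairs are connected wherever the blended distance is ≤ q_ED, the α_ED-th
  percentile — linear-interpolation definition — of the strictly
  upper-triangular blended distances, α_ED ∈ (0, 100]. The cutoff q_ED is
  recorded on the graph config.

Self-loops: both rules would always connect a node to itself (self-cosine 1,
self-distance 0), and the GCN normalisation Â = D̃^{−1/2}(A + I)D̃^{−1/2}
separately adds the identity. Applying both would double-weight self-loops
in the cosine graph, so adjacency matrices are stored with a **zero
diagonal** and exactly one unit self-loop is added during normalisation.
Edge accounting (`edge_composition`) reports self-edges as present, so the
possible-edge count for a same-label group of size n is n + n(n−1)/2 and
n₁·n₂ across labels; with class sizes 76/155/237 the six denominators are
2926, 11780, 18012, 12090, 36735, 28203. Degrees in D̃ are weighted sums,
the literal reading of the degree definition.

## GCN and training regimen

Z = head(Â · ReLU(Â X W⁽⁰⁾) · W⁽¹⁾), no biases, dropout on each layer's
input. Binary tasks use a single-logit sigmoid head (scores ≥ 0.5 map to
the more advanced stage; the boundary case is the positive class);
multiclass argmax ties break to the lowest class index. Training is
full-batch with the cross-entropy masked to training nodes, Adam with
weight decay 1e−5 (decay added to the gradient, the common Adam-L2
convention), at most 500 epochs, early stopping after 20 epochs without
validation-loss decrease, restoring the best-validation-epoch weights.
Internally the loss is computed from logits (log-softmax / softplus) for
numerical stability; the public `masked_loss` accepts probabilities and
clamps at 1e−12.

With Â = I the GCN training loop is numerically identical — same seeded
initialisation, same Adam trajectory — to a bias-free one-hidden-layer MLP
trained with the same regimen; the test suite uses this as a cross-model
oracle, and the MLP baselines share the same full-matrix masked-loss code
path (with biases enabled by default).

## Nested cross-validation

A stratified 5-fold outer split partitions the cohort; with each outer fold
held out for testing, a stratified 4-fold inner split of the remainder
yields four (train, validation) pairs, giving 20 (train, val, test) triples.
Every hyperparameter candidate — including β and the edge threshold — is
trained on all 20; the candidate with the lowest mean inner validation loss
wins, and the report averages the test metrics of the winner's 20
already-trained models, so each outer fold is tested four times by models
that never saw it. SVM and random-forest baselines have no epoch-wise loss;
their selection loss is the validation error rate (1 − accuracy), without
early stopping. Candidates that fail on any fold are excluded with a
warning rather than silently.

Metrics: accuracy, and for binary tasks precision, recall, F1
(2·P·R/(P+R)), and AUC computed from the positive-class scores, the
positive class being the more advanced stage. Zero-denominator precision or
recall is reported as 0 with a flag. Multiclass reports accuracy plus the
confusion matrix pooled over the 20 models (per-model matrices retained).

A leakage audit is part of the test suite: with the split plan held fixed,
flipping the labels of subjects that appear only as test cases changes
neither the candidate validation losses nor the selected hyperparameters.

## Synthetic cohorts

The generator targets the statistical structure the method exploits, not
anatomical realism:

- **Clinical indicators**: class-conditional Gaussians with the per-class
  means and SDs of the motivating hospital cohort (e.g. MMSE 27.65 ± 1.72 /
  25.11 ± 2.99 / 19.28 ± 4.23 for NC/MCI/AD; class sizes default to
  76/155/237 so stratification runs against realistic imbalance), clipped
  post-draw to instrument ranges (MMSE ∈ [0, 30], CDR-SB ∈ [0, 18],
  GDS ∈ [1, 7], SGDepS ∈ [0, 15], age > 0, education ≥ 0). The source
  tables state no bounds; clipping keeps values clinically meaningful, and
  moment-recovery tests run pre-clipping.
- **Latent imaging features**: isotropic Gaussians (SD `noise_sd`, default
  1.0) around centroids at `separation` × (0, 0.5, 2.0) along a fixed unit
  direction, so the NC–MCI gap is a quarter of the NC–AD gap — NC and MCI
  overlap heavily while AD separates, the geometry a PCA of real amyloid-PET
  features shows. `separation = 0` collapses all classes onto one
  distribution (the chance-level control); the default 2.0 makes AD clearly
  separable. Dimension defaults to 256 to match the extractor width;
  tests use 8–16.
- **Volumes**: 0.5 background plus Gaussian noise, a spherical cortical
  shell (normalised radius 0.30–0.45) carrying the class signal plus
  subject jitter, and a small "cerebellum" sphere held at mean 1 so values
  read as uptake ratios. Class signals default to 1.1/1.3/1.6 (NC/MCI/AD),
  an uptake-ratio-like progression. No partial-volume or scanner effects
  are modelled.

What passing tests therefore show: the pipeline's contracts, leakage
behaviour, and qualitative multimodal phenomena (clinical-dominant β,
variant ordering) under the assumed class geometry — not headline accuracy
on real restricted cohorts.

## Problem sizes used in tests and the acceptance script

The qualitative-replication experiment uses 120 subjects (20/40/60,
mirroring the real class imbalance), 16 latent imaging dimensions,
separation 1.0 with noise SD 1.0 (so the NC–MCI centroid gap is 0.5 SD —
heavily overlapped — and NC–AD is 2 SD), a 16-unit GCN, Euclidean edges at
α_ED = 31 (the published multiclass threshold), and a β grid
{0.05, 0.1, 0.3, 0.5, 0.7, 0.9} spanning the imaging/clinical trade-off
with the same refinement floor (0.05) the original search used. The
extractor trains only at tiny configurations (k ≤ 4, two dense blocks,
8³–16³ volumes) — the channel-bookkeeping and training-regimen contracts
are size-invariant. The full 64³/k = 32 network builds and runs forward but
no test trains one.

## Numerical and design notes

- All model arithmetic is float64 on a purpose-built numpy reverse-mode
  autodiff core (`popgcn.nn`); every primitive's adjoint is validated
  against central finite differences. Seeded runs are bit-reproducible on
  a given platform.
- α_ED is a percentile *rank*; the quantile uses numpy's linear
  interpolation. One consistent reading of the self-loop accounting was
  chosen (single self-loop, see above) and is applied uniformly to
  normalisation and edge accounting.
- The graph hyperparameters (β, α) are tuned jointly with the GCN
  hyperparameters in the same inner-loop grid.
- The β-sweep reports, at each β, the per-β best threshold α (selected by
  validation loss) and the corresponding 20-model mean ± SD test accuracy;
  β = 0 and β = 1 rows coincide with the clinical-only and imaging-only
  variants by construction.
- The robustness harness adds Gaussian noise only to the standardized
  clinical columns of test-mask rows, then **rebuilds the adjacency** from
  the perturbed features before re-predicting with frozen weights — edges
  derive from the same standardized vectors, so freezing them would
  understate the perturbation. The frozen training-time cutoff q_ED is
  reused. SD 0 reproduces the baseline metrics exactly.
- When a feature extractor is trained inside the evaluation loop it is
  retrained per inner-loop record on that record's training portion (the
  conservative anti-leakage reading); pre-computed latent features skip
  this step.
- Reslicing to the network's input grid uses center-aligned trilinear
  interpolation (src = (i + 0.5)·S/T − 0.5, edge-clamped).

## Known limitations

- The generator's Gaussian latent clouds lack the manifold structure,
  covariance anisotropy, and site effects of real extracted PET features;
  absolute accuracies on synthetic cohorts do not transfer to real data.
- Full-batch transductive training scales as O(N²) memory in the adjacency;
  cohorts beyond a few thousand subjects would need neighbour sampling,
  which is out of scope.
- Only numeric clinical indicators participate in edge assignment;
  categorical indicators (sex, ApoE4) would need a Kronecker-delta or
  one-hot rule, not implemented.
- The cosine rule can connect many cross-class pairs when class clouds
  differ in radius but not direction (it sees only angles); the Euclidean
  rule is the safer default for multiclass staging, and the edge-composition
  report makes the difference measurable.
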