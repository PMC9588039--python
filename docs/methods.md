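# Methods

`surfgcn` predicts a scalar behavioral trait from registered brain surface
meshes with a residual spectral graph-convolutional network, and maps the
mesh regions driving the prediction with graph Grad-CAM.  This note records
the model, its assumptions, the parameters that matter, the synthetic
validation design, and the numerical and design choices a maintainer would
want to know about.

## Input representation

Each subject is a set of triangulated surfaces registered vertex-to-vertex
to a shared template: inner (white) and outer (pial) cortical surfaces per
hemisphere, plus up to seven subcortical structures per hemisphere
(amygdala, accumbens, caudate, hippocampus, pallidum, putamen, thalamus).
All subjects share one triangulation; only vertex coordinates differ.  The
combined template graph G = (V, E, A) is the disjoint union of the
per-structure triangulation graphs (block-diagonal adjacency; a cortical
hemisphere contributes one node block carrying both inner and outer
coordinates).  Edges get unit weights by default — connectivity is what the
spectral filters consume — with an optional inverse-edge-length weighting.

Node features are the subject's own Cartesian coordinates: 6 per cortical
node (inner xyz, outer xyz), 3 per subcortical node, or a 9-wide combined
layout where subcortical rows fill columns 0–2 and cortical rows columns
3–8, the rest zero.  Coordinates are min–max normalized to [0, 1] per
subject and per axis over all vertices of the active mode; a zero-range axis
maps to 0.  Whether normalization should be per subject or per cohort is
genuinely open; per subject was chosen because it makes a subject's encoding
independent of who else is in the batch.  Rigid (rotation + translation)
alignment to the template is available via a Kabsch solution constrained to
proper rotations, so mirror images are never introduced.

Raw trait scores are Gaussianized by rank before training (quantile
normalization): rank i of n maps to the standard-normal quantile at
(i + 0.5)/n.  A `sampled` variant replaces ranks with sorted seeded
standard-normal draws; it is provided for completeness but makes targets
seed-dependent, so the deterministic map is the default.  Normalization is
fit on the full cohort by default (matching common practice for rank
transforms); a leakage-safe alternative is to fit on training folds only —
for a monotone rank map the difference is negligible at these cohort sizes.

## Spectral convolution

A graph filter is a degree-(K−1) polynomial of the scaled Laplacian
L̃ = 2L/λ_max − I, where L = I − D^{−1/2} A D^{−1/2} is the normalized
Laplacian (spectrum in [0, 2], so L̃'s spectrum lies in [−1, 1], the interval
where Chebyshev polynomials of the first kind are numerically stable):

    y = Σ_{k=0}^{K−1} T_k(L̃) x θ_k,   T_0 = I, T_1 = L̃,
    T_k = 2 L̃ T_{k−1} − T_{k−2}.

The three-term recurrence evaluates this with K−1 sparse matrix products per
layer and never materializes T_k(L̃); a layer with F_in inputs and F_out
outputs has F_in·F_out·K trainable coefficients plus an F_out bias (the bias
is standard in this architecture family and excluded from the coefficient
count).  The filter is K-localized: output at a vertex depends only on its
(K−1)-hop neighborhood.  Default K = 3.  λ_max is computed to near machine
precision (dense eigensolve for small graphs, Lanczos above), capped at 2
for the normalized kind; an exact λ_max keeps the scaled spectrum strictly
inside [−1, 1], which a loosely converged iterative estimate does not.
Edgeless graphs use the convention λ_max = 2 (L̃ = −I).  Zero-degree
vertices get an all-zero normalized-Laplacian row (eigenvalue 0).  A dense
spectral-decomposition path (`spectral_oracle`) implements the filter
through the explicit graph Fourier transform; it exists only as an
independent test oracle and refuses graphs above a small size bound.

## Pooling hierarchy

Each residual block halves the node count, so a coarsening hierarchy is
built once per template: greedy heavy-edge matching (Graclus-style,
normalized-cut weight w_ij(1/d_i + 1/d_j)), with unmatched vertices paired
to inserted *fake* nodes so every level halves exactly, and a
sibling-contiguous reordering placing the children of supernode p at
positions 2p, 2p+1.  Max pooling is then a stride-2 reduction in which fake
children take −∞ and can never win; a pair of two fakes yields 0.  Fake
nodes carry no edges and zero features.  Coarsening is seeded and
deterministic; all subjects share the hierarchy.  Coarse maps return to full
resolution by parent-copy down the hierarchy followed by one pass of a
row-stochastic one-ring smoothing operator (self weight 1/2, neighbors
share 1/2 by inverse distance) — a convex combination, so upsampled values
stay within the coarse map's range.  The smoothing approximates linear
interpolation on the structures' sphere parameterizations.

## Network

Pre-activation residual architecture on the hierarchy:

    Pre-Conv (level 0)
    → [ResBlock_i at level i−1 → MaxPool to level i]  for i = 1..B
    → ResBlock (post, at level B)
    → BN → ReLU → flatten → dropout → fully connected → 1 scalar

Each residual block is two (BN → ReLU → ChebConv) subblocks with an identity
shortcut, or a K = 1 Chebyshev projection when channel widths change; the
shortcut is added *before* pooling so both paths live at one resolution.
Batch-norm statistics are per channel over batch and vertices, momentum 0.9
running averages in evaluation mode.  The closing BN → ReLU before the head
follows the pre-activation convention and is needed for stable optimization
of the unnormalized flatten scale.  The number of residual blocks follows
`len(channels) − 2`; the reference configuration uses four blocks
(2^4 node reduction) and widths (32, 32, 64, 64, 128, 128), which are a
package configuration choice.

Two further input-side choices matter for optimization and are this
package's own:

- **Mean-input subtraction.**  The training-fold mean feature map is stored
  on the model and subtracted from every input (the mean-image subtraction
  of classic CNN pipelines).  Without it the static template component
  dominates every mini-batch gradient (a rank-one common-mode term) and
  learning stalls at any practical learning rate.  The [0, 1] feature
  encoding itself is unchanged.
- **Near-zero head initialization.**  The FC layer starts near zero so
  initial predictions sit at the normalized-target mean, avoiding a long
  recentering transient under Adam's per-coordinate step sizes.

All layers are implemented directly on numpy/scipy with hand-written
backward passes, validated against central finite differences (relative
error < 1e−7 in double precision).  Single precision is the training
default (roughly half the memory traffic); the Chebyshev layer evaluates
its basis once per pass and reuses it for the coefficient gradient, and
L̃'s symmetry gives the input gradient by the same recurrence.

## Training

Loss: L = MSE + λ₁·reg − λ₂·corr, with reg the squared l2 norm of filter
and FC weights (BN parameters and biases excluded) and corr the Pearson
correlation between predictions and targets within the mini-batch, guarded
to 0 when either side has zero variance (including batches of one).  The
correlation term counteracts regression-to-the-mean shrinkage: an MSE-only
regressor prefers predictions compressed toward the target mean, and
rewarding correlation pushes back.  Defaults λ₁ = λ₂ = 1e−4; the reg
gradient is applied as weight decay, the corr gradient analytically.

Optimization: Adam, learning rate 5e−4 decayed by 0.99 every 10 steps,
batch 32, at most 100 epochs — the default, sized for large pediatric
cohorts; a preset with batch 50, λ₁ = 5e−4, 80 epochs covers smaller adult
cohorts.  Early stopping monitors inner-validation MSE with patience 5 and
restores the best parameters.  Augmentation (probability p_a = 0.5 per
sample) applies three Euler rotations uniform in ±20° about the structure
set's centroid plus i.i.d. Gaussian coordinate noise (σ = 0.02 mm), always
*before* min–max normalization.

Model selection is nested cross-validation: six outer folds for held-out
testing; within each outer training set, five inner folds each train one
member model (early-stopped on its inner fold), and the outer test
prediction is the arithmetic mean of the five members.  "Ensembling" is
prediction averaging, not weight averaging — weight averaging is ill-defined
across batch-norm statistics.  Fold sizes differ by at most one, remainders
to the lowest-indexed folds; 8,070 subjects give outer test folds of exactly
1,345, and 1,097 give 183 test / 914 inner-training.  Evaluation reports
MSE, Pearson R with a Fisher-z 95% CI, and a 95% prediction interval from
the regression of targets on predictions.  Input-mode comparisons use paired
t-tests across folds with Benjamini–Hochberg adjustment.

## Saliency

Graph Grad-CAM on the deepest convolution (the post residual block's final
conv): channel weights α^k are the node-averaged gradients of the prediction
with respect to that layer's feature maps, and the relevance map is
M = ReLU(Σ_k α^k A^k), computed over real (non-fake) nodes, upsampled to
full resolution, averaged over a fold's test subjects (ensemble members'
maps are averaged per subject, consistent with prediction averaging), and
compared between runs by Pearson correlation across vertices, optionally
restricted to the cortical or subcortical block.  Maps are min–max scaled
only for rendering; statistics use raw values.

**Known limitation.**  On the synthetic benchmark below, this formulation
does not localize the planted effect, and the analysis says the failure is
structural rather than a defect of training: (i) the prediction head is a
flat flatten-plus-FC readout, not global average pooling, so the spatially
informative per-node gradients are exactly what the node-averaging in α^k
destroys (measured α ≈ 1e−4 with mixed signs while per-node input-gradient
saliency concentrates on the planted region at ~20× chance); (ii) the
planted effect is symmetric — bump amplitudes are zero-mean Gaussian and the
score is linear in the amplitude — so subject-specific activation deviations
flip sign with the amplitude and cancel in subject- and fold-averaged maps,
the ReLU leaving only a weak variance effect.  Alternative map sources
(every conv depth, rectified head inputs) and weighting schemes
(prediction-weighted averaging, cross-subject dispersion) were evaluated and
do not change the conclusion.  Fold-averaged maps should therefore be read
as descriptive of the network's activation landscape, not as evidence of
where predictive information resides; per-node gradient methods are the
better localization tool for this architecture.

## Synthetic validation design

The generator emulates registered template meshes: subdivided icospheres
stand in for the hemispheres (default depth 3, 642 vertices each, emitted
as inner/outer pairs at radii 48/51 mm) and the fourteen subcortical
structures (default depth 1, 42 vertices, radii 5–10 mm), giving a
1,872-node combined template.  Per subject: (a) a smooth nuisance
deformation — ten random low-order (degree ≤ 4) real spherical harmonics
with seeded coefficients, radial displacement SD 1.0 mm, drawn independently
per structure (inner/outer cortex share one field); (b) a localized radial
Gaussian bump on the left cortex (geodesic radius 20 mm, σ = radius/2,
truncated at 2× radius) whose amplitude a ~ N(0, 2.0 mm) determines the
score y = β·a + ε, β = 1 per mm, ε ~ N(0, 0.4) — noise at 20% of the signal
SD, so the oracle amplitude–score correlation is 0.98.  The mm-scale
deformations reflect that inter-subject surface variability after rigid
registration is of millimeter to centimeter order.  Default cohort size 300.

What the generator does *not* emulate: cortical folding and its
curvature-correlated variability, structure-specific shape priors, scanner
or segmentation noise, and any nonlinear or multivariate trait structure.
Passing the recovery benchmark therefore shows the pipeline can extract a
localized linear morphology–score signal at realistic amplitude; it does not
certify performance on real cohorts.

The reference study (`surfgcn.experiments.run_planted_signal_study`) runs
the full nested 6×5 cross-validation on this cohort with a small model —
two residual blocks, channels (8, 8, 16, 16), two pooling levels, dropout
off — and a schedule sized for a single CPU: Adam at 1e−3, at most 20
epochs, patience 5, jitter-only augmentation (p_a = 1, rotations off —
global ±20° rotations would swamp a mm-scale planted signal at this cohort
size; jitter SD 0.5 mm matches the nuisance scale).  Problem sizes
throughout the examples and tests are chosen so the whole suite runs on one
CPU in minutes.  With seed 1 this study reaches held-out ensemble Pearson
R ≈ 0.81 pooled over the six outer folds.

## Numerical notes and degenerate inputs

- Adjacency symmetry is enforced to 1e−10 and Laplacians symmetrized
  exactly; normalized-Laplacian spectra are validated to [0, 2] ± 1e−8.
- Pearson computations guard zero variance (loss term → 0 with zero
  gradient; evaluation and spatial correlation raise instead, since a
  silent 0 would be misleading there).
- Min–max normalization maps zero-range axes to 0; augmentation happens
  before normalization so rotations do not leak into the feature range.
- Ties in max pooling resolve to the left sibling; coarsening ties follow
  the seeded visiting order — both deterministic.
- Checkpoints store parameters, running statistics, the model configuration,
  compute dtype, and a template checksum; ensembles verify configuration
  and checksum agreement before averaging.
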