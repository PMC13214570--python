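# Methods

## Problem setting

The package models a two-stage analysis of co-registered multispectral MRI:
each voxel carries a high-dimensional feature vector (diffusion, CEST,
susceptibility and anatomical channels in the real-data setting; abstract
channels here), and the goal is to predict, voxel by voxel, a *normative*
dopamine-transporter (DaT) binding-potential atlas from those features using
healthy controls (HC) only. Patients (PD) are never trained on; their
predicted binding is read as a deviation from the healthy reference, and a
putamen-specific reduction is the expected disease signature.

The pipeline is: per-subject spatial detrending and standardization → a
contrastive voxel embedder with adversarial bias removal → a feed-forward
regressor onto the standardized atlas → leave-one-HC-out cross-validation →
ROI group statistics and ROC analysis.

## Synthetic cohorts

No public cohort of this kind exists, so every stage is exercised on seeded
synthetic cohorts (`datnorm.synthetic`). For subject *s*, voxel *v*, channel
*c*:

```
f[s,v,c] = (1 + γ[s,c]) · ( T[v,c] + a(v) · β[c] · atten(s,v) )
           + b_s(v) · u[s,c]            # polynomial bias field
           + r_s(v) · w[s,c]            # residual (non-polynomial) bias
           + ε,   ε ~ N(0, σ²)
```

* **Grid and ROIs.** A fixed slab lattice (x, y ∈ [−1, 1], z ∈ [−0.3, 0.3],
  default 1500 voxels) shared by all subjects, with ellipsoidal
  putamen-like, caudate-like and control regions. Registration error is not
  simulated: the common space is exact by construction.
* **Atlas `a(v)`.** A smooth nonnegative field peaking near 4 in the
  putamen-like region and 3.5 in the caudate-like region on a 0.3
  background, plus a mild seeded random smooth component — the contrast
  pattern of a striatal binding-potential map. It enters the features
  standardized (zero mean, unit variance over the grid).
* **Tissue component `T`.** Five latent smooth spatial factors mixed into
  channels by a seed-fixed random matrix; gives the embedder non-trivial
  structure to preserve.
* **Atlas-linked loading `β`.** Sparse: 25% of channels carry the
  DaT-relevant signal, with random signs and magnitudes near 1.
* **Disease effect.** `atten = 1 − disease_attenuation` for PD voxels inside
  the affected ROI (default: putamen-like only, attenuation 0.3 — the order
  of early-stage putaminal deficit relative to within-cohort variability
  we target at this scale); 1 elsewhere. The effect is ROI-restricted by
  construction, so caudate-like and control regions are null regions.
* **Subject nuisance structure.** Three components, each per subject:
  multiplicative per-channel gains (sd 0.1); an additive degree-4 polynomial
  spatial field times a per-channel weight (sd 0.5) — *exactly* removable by
  the preprocessing; and a *residual* bias: a smooth spatial field
  orthogonalized against the degree-4 polynomial basis, times a
  per-channel direction (sd 0.2). The residual term models the nonlinear
  inhomogeneity that survives polynomial detrending in real data — it is
  precisely the cue the adversarial heads exist to suppress; without it,
  preprocessing alone would leave nothing subject-specific for the
  embedder to hide, and the adversarial mechanism would be untestable.
* **Ages.** Uniform per group (HC 22–69, PD 48–73); HCs under 40 are
  flagged "young" to support the age-restricted control analysis. The
  planted effect is age-independent by construction.
* **Optional nuisance knobs** (all neutral by default): a per-subject
  smooth *multiplicative* intensity field (the receive-field-like
  distortion the augmentation family simulates; untouched by additive
  detrending or per-channel z-scoring), a loading-overlap fraction that
  rotates the residual-bias channel direction into the atlas loading
  (scanner bias contaminating signal channels), and biological
  tissue-state noise on the atlas-linked component. These exist for
  robustness and ablation experiments; the default study conditions keep
  them off so the planted-effect analyses stay interpretable.

What the generator does **not** emulate: MR physics (no Bloch/CEST
simulation — channels are abstract), inter-subject registration error,
realistic channel covariance of 7T multispectral data, and any coupling
between age and tissue signal. Passing tests therefore demonstrate that the
pipeline recovers the *kind* of structure it assumes — a spatially
restricted attenuation of an atlas-linked component under subject-specific
nuisance — not that it would perform identically on real 7T data.

## Preprocessing

Per subject and channel, a least-squares fit on the full tensor monomial
basis of total degree ≤ 4 in three variables (35 terms; stars-and-bars
count C(7,3)) is subtracted. Coordinates are affinely mapped per axis to
[−1, 1] over the subject's slab bounding box for conditioning; the solve is
SVD-based (`lstsq`), not explicit normal equations. Residuals are z-scored
per subject *and channel* (channels have incommensurable units; pooling
would let high-variance channels dominate), with the population (divide by
n) convention throughout. Zero-variance channels are flagged degenerate and
dropped. The atlas target is standardized over the analysis mask with an
invertible affine map retained so predictions are reported on the original
binding-potential scale.

## Augmentation

Two stochastic views per voxel, five transforms in fixed order, every
magnitude scaling linearly with a ramped strength (linear, 0.2 → 1.0 over
training): per-voxel global gain (±10%) and offset (sd 0.05); smooth
low-rank per-channel gain (Legendre polynomials of order 1–3 over channel
index, coefficient sd 0.05); a monotone gamma-like warp (log-range ±0.2)
applied on a per-channel min-max normalized copy so it is defined for
signed z-scored inputs; additive Gaussian noise (sd 0.1); feature dropout
(rate 0.3). At strength 0 the output equals the input exactly. All
magnitudes are configuration, not constants.

## Embedder

An MLP encoder (hidden blocks: linear → ReLU → layer norm → dropout 0.3)
maps features to L2-normalized 16-D embeddings. Training minimizes

```
L = L_InfoNCE(τ = 0.07) + 20 · L_coordinate + 20 · L_subject
```

where the InfoNCE positive for each of the 2N in-batch samples is its
sibling view and the denominator runs over all 2N − 1 other samples
(cosine similarity). The two adversarial heads (three hidden blocks:
linear → layer norm → ReLU → dropout 0.3) predict, respectively, the
voxel's per-axis empirical-quantile coordinate bin (16 bins per axis,
edges from the pooled training subjects; the coordinate loss is the mean
over the three axes) and the subject identity. The heads are attached
through a gradient-reversal layer: they are optimized to minimize their own
weighted losses, while their gradients reach the encoder multiplied by −λ
(λ = 1, adversarial pressure controlled by the weights instead). Everything
is optimized with decoupled-weight-decay Adam (weight decay 10⁻²) and
trained in float32; heads are discarded and the encoder frozen afterwards.

Two profiles are provided:

* **full** — hidden [2048]×4, heads [512]×3, batch 16384, 4000 steps,
  lr 10⁻⁴: the production-scale configuration for real cohorts.
* **desk** — hidden [64]×2, heads [64]×3, batch 256, 150 steps, encoder lr
  10⁻³, head lr 10⁻²: the configuration used by the test suite and the
  acceptance script so a full leave-one-out run completes in seconds per
  fold on one CPU. With 26× fewer steps than the full profile, the production-
  scale learning rate leaves both the encoder undertrained and — more
  importantly — the adversarial heads too weak to exert any pressure
  through the reversal layer (their cross-entropy stays at chance because
  they never learn, not because the encoder hides anything, and a
  converged post-hoc probe still reads subject identity). The desk
  profile therefore raises both rates so the minimax game actually plays
  out within the step budget; the head rate is kept one order above the
  encoder rate so the adversary stays near its best response. The
  bias-removal analysis uses a desk variant with 500 steps and batch 512
  (InfoNCE cost grows quadratically with batch size, which caps what one
  CPU can afford).

## Regressor

The regressor shares the adversarial-head architecture with a scalar output
and minimizes mini-batch MSE on frozen embeddings of training-HC voxels
against the standardized atlas value at each voxel's grid coordinate
(nearest-grid sampling). AdamW (lr 10⁻³, weight decay 10⁻²) with cosine
annealing to zero over the configured epochs, no restarts. Full profile:
[512]×3, batch 4096, 30 epochs. Desk profile: [64]×3, batch 1024, 30
epochs — at desk data volumes the number of optimizer updates, not the
epoch count, limits fit quality, so the smaller batch is deliberate.

## Cross-validation and aggregation

One fold per HC: the embedder is trained on the remaining HCs only
(coordinate-bin edges included, recomputed per fold to avoid leakage), the
regressor on those same HCs' embeddings, and predictions are emitted for
the held-out HC and every PD subject. Per-fold seeds derive from
(global seed, fold index) via `numpy.random.SeedSequence`, so folds are
independent but reproducible, and fold jobs share no mutable state (they
may be run in parallel by callers). Each fold records a manifest of the
subjects actually present in its training table; the leakage audit asserts
on manifests, not on the plan. PD predictions are aggregated across folds
voxel-wise by mean *and* median; each HC is predicted only by its own fold.
For the "median" analyses the median is taken across folds first and ROI
summaries are means of those aggregates.

## Statistics

ROI summaries are per-subject means (and medians) of voxel predictions;
striatum = voxel-weighted union of putamen and caudate. Group differences:
two-sided Welch's t (HC − PD orientation), Benjamini–Hochberg q-values
across the tested ROI family (default putamen, caudate, striatum; m is
configurable and recorded), Hedges' g (pooled-sd Cohen's d times
J = 1 − 3/(4·df − 1)) with a 95% CI from a seeded percentile bootstrap
(10⁴ resamples; asymmetric by design — a Wald CI is available by flag).
ROC analysis treats HC as negative and PD as positive with the *negated*
ROI summary as score (lower predicted binding ⇒ more PD-like), so AUC > 0.5
for a deficit and reported thresholds stay on the binding-potential scale.
Thresholds are scanned at midpoints between consecutive distinct scores;
the operating point maximizes the Youden index with ties broken toward
higher specificity; balanced accuracy is (sensitivity + specificity)/2
exactly. AUC equals the Mann–Whitney pairwise form with half-credit ties.
The age-restricted control analysis reuses predictions unchanged and merely
filters the HC sample entering the statistics.

## Numerical and testing choices

* Training runs in float32 for speed; inference re-normalizes embeddings in
  float64. All gradients are validated against central finite differences,
  and InfoNCE/cross-entropy/BH/AUC against independent brute-force oracles.
* Degenerate inputs fail loudly: constant atlas, zero-variance channels,
  rank-deficient polynomial designs (the collinear axis is named), single
  training subject, non-finite losses.
* The multi-seed end-to-end checks (10 seeds; 8 HC / 4 PD, 1500
  voxels/subject, 40 channels) use desk-profile problem sizes chosen so the
  whole suite runs on one CPU; their pass conditions are counts over seeds
  (e.g., putamen q < 0.05 in ≥ 8/10 runs with a 0.3 attenuation, no
  putamen significance in ≥ 9/10 null runs), not point estimates.
* The training-progress check holds augmentation strength constant: under
  the default ramp the contrastive task hardens over training and the raw
  trace can rise even as the encoder improves.

## Known limitations

* Desk-scale learning rates differ from the full profile (see above); the
  full profile follows the production configuration but is not exercised
  end-to-end by the CPU test suite.
* The bootstrap CI for Hedges' g is percentile-based; with n as small as
  4 per group its coverage is approximate.
* The synthetic null ("attenuation 0") shares every nuisance component
  with the effect cohorts; it does not probe robustness to nuisance
  structure the generator lacks (registration error, heavy-tailed noise,
  age-correlated tissue change).
* On these synthetic cohorts the ablations do not reproduce the ordering
  expected on real data (contrastive + adversarial > no-adversarial >
  raw-feature regression). With mild subject nuisance the raw 40-channel
  regressor is genuinely competitive — cross-subject structure is shared
  and nearly noise-free, which real multispectral data are not — and with
  nuisance harsh enough to defeat it, the desk-scale adversary (which
  removes subject information only partially; compare the linear-probe
  accuracies in the bias-removal analysis) cannot protect the main
  pipeline either, so all routes degrade together. The adversarial
  benefit that *is* reproducible at this scale is measured directly on
  the embeddings: subject-probe accuracy near chance with the heads,
  clearly above chance without them.
* Per-subject z-scoring couples ROIs: a putamen-restricted attenuation
  slightly rescales every channel of an affected subject, which can
  nudge unaffected high-binding regions (caudate) toward significance in
  some seeds. The control (extrastriatal) region is the cleaner null.
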