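# Methods

This note documents the models and procedures `rsbn` implements, the
defaults and why they were chosen, and what the synthetic-data evaluation
does and does not establish.

## The generative and analysis model

The analysis treats each resting-state network (RSN) as one node with a
scalar time series and models the joint distribution of the nine node
signals at a single timepoint as a **linear-Gaussian structural equation
model (SEM)** on a directed acyclic graph (DAG):

    x_j = Σ_{i ∈ pa(j)} w_ij x_i + ε_j ,   ε_j ~ N(0, σ_j²) independent.

This is exactly the distributional family of the Gaussian Bayesian network
used for learning, so the simulator and the learner share assumptions by
design.  The implied covariance is Σ = (I − Wᵀ)⁻¹ D (I − Wᵀ)⁻ᵀ with
D = diag(σ_j²); the simulator is validated against this closed form
(elementwise agreement within 2% in correlation units at T = 50 000).

Samples are i.i.d. across timepoints.  Real fMRI is temporally
autocorrelated; an optional AR(1) innovation mode (`ar_coefficient`,
default 0, innovations rescaled to keep marginal variances) exists purely to
stress-test the learner against that violation.  There is no hemodynamic
convolution, physiological noise, or realistic head motion — the rendered
4-D volumes are geometric fixtures (sphere signals plus white background
noise with smooth synthetic confound traces), not biophysical simulations.

### Cohort defaults

The default synthetic cohort mirrors the study design the packaged
ground-truth networks come from: **20 subjects × 2 conditions (EC/EO) ×
230 timepoints at TR = 2 s** (240 acquired volumes minus 10 discarded for
signal equilibration).  Condition-specific ground truths are the packaged
edge lists; all error variances are 1 so that the generating DAG is
identifiable beyond its Markov equivalence class (unequal variances can be
set to study equivalence-class behaviour).  Per-subject variability is
Gaussian jitter (sd 0.1) applied to nonzero weights only, keeping every
subject's structure identical to the group truth; no subject-level
generative model is established for such data, and jitter on the scale of
the smaller published weights (0.14–0.44) is a conservative middle ground —
large enough that recordings differ materially, small enough that conditions
remain the dominant factor.  Randomness derives from one master seed through
`SeedSequence(master_seed, spawn_key=(subject, condition))`, so any
recording is reproducible in isolation.

## Node extraction

* **Sphere masks**: a voxel belongs to a node's sphere when its centre
  (voxel indices mapped through the image affine) lies within `radius_mm`
  of the node's MNI peak.  Voxel-centre inclusion is the simplest rule and
  the common toolbox behaviour; masks are clipped at the grid boundary and
  an empty mask is an error naming the node.  Node signals are arithmetic
  means over mask voxels.
* **Band-pass filter** (0.01–0.08 Hz default): implemented as a single
  orthogonal projection — an ideal rectangular filter on the discrete
  Fourier bins, minus whatever of the constant/linear-trend directions
  survives inside the band.  Making the whole operation one projection
  (rather than detrend followed by FFT masking) gives exact idempotence,
  which is asserted to 1e−8.
* **Nuisance regression**: node series are residualized against an intercept
  plus the nine confounds (global mean, white matter, CSF, six motion
  parameters).  Regression is applied *after* sphere averaging: both
  operations are linear in the voxel data, so regress-then-average equals
  average-then-regress exactly (tested to 1e−8); doing it at node level is
  cheaper and equivalent.  Confounds are band-pass filtered together with
  the data first, so regression cannot reintroduce stop-band energy.
  Collinear confound columns are dropped with a logged warning.
* **Motion QC** (> 1 mm translation or > 1° rotation) is reported as a flag,
  never auto-applied; exclusion is the caller's decision.

## Structure learning

All learning happens on **standardized** data (each column z-scored with
denominator N).  This removes intercepts, makes weights comparable across
subjects and conditions, and is why every regression in the learner is fit
without an intercept.  Standardization rescales the error variances, so
recovery claims are always up to the Markov equivalence class (CPDAG:
skeleton plus v-structures), which is invariant to scaling.

1. **Candidate parents** per target node: the lasso path of the target on
   all other nodes over 50 log-spaced penalties from the critical value
   (smallest λ with empty support) down to 1% of it; each support on the
   path is refit by least squares and scored with the per-family Gaussian
   BIC; the best support becomes the candidate set.  Screening only prunes
   the search space — the BIC, not the lasso, decides the structure.
2. **Score**: decomposable Gaussian BIC per family,
   `−(N/2)(1 + log 2π σ̂²) − ((|pa|+1)/2) log N`, with σ̂² the ML
   (denominator N) residual variance and the parameter count `|pa| + 1`
   (weights plus the variance).  Higher is better.  Numerically singular
   parent designs score −∞ inside the search and raise when scored
   directly.
3. **Search**: greedy best-first hill climbing over DAGs with add, delete
   and reverse moves, restricted to the symmetrized candidate skeleton,
   accepting the single best strictly-improving move per step; ties resolve
   to the lexicographically first (source, target) move, so the search is
   deterministic.  After the empty-graph climb, 10 seeded restarts each
   draw a random node order, locally optimize it with single-node insertion
   moves (an order is scored by its per-node best candidate-parent
   subsets), and climb from the order-optimal DAG — a random acyclic
   subgraph of the candidate skeleton.  Plain uniform random subgraph
   restarts proved unreliable on nine-node problems (the greedy move set
   stalls in basins that coordinated two-edge changes would escape);
   order-based restarts reached the exhaustively verified optimum on every
   benchmarked dataset at the same restart count.
4. **Weights**: given the structure, per-family least squares without
   intercept; non-edges are exactly 0; noise scales are ML residual
   standard deviations (floored at the smallest positive float so that
   exactly deterministic families remain representable).

**Group networks** concatenate per-recording standardized series within a
condition and learn once on the pooled rows — chosen over averaging
per-subject networks because the analysis reports a single network with one
weight per edge, and concatenation estimates exactly that.  **Subject
features** learn one full network per recording and flatten its 9 × 9
weight matrix row-major into 81 features (diagonal identically zero,
absent edges zero) — the one construction that naturally yields a fixed
81-dimensional vector per recording.  **Edge significance** is a
cross-subject one-sample two-sided t-test of each edge's weights against
zero, uncorrected, α = 0.05; a zero-variance column has no t statistic and
reports p = 1 when identically zero (p = 0 for a nonzero constant).

### Known behaviour at the default scale

At N = 4600 (20 × 230 pooled samples, unit variances, no jitter) the
BIC-optimal DAG coincides with the generating equivalence class on most but
not all cohort seeds: the weakest published edges (|w| ≈ 0.2) sit near the
BIC detection boundary, where the penalty (log N)/2 ≈ 4.2 occasionally
favours a slightly different local structure.  This is a property of the
score at that sample size, not of the search — the search is verified to
match exhaustive enumeration on four-node problems and to reach the
attainable optimum on all benchmarked nine-node datasets.  Two-node
sub-problems are never orientable from Gaussian observational data alone;
reported single directions inside an equivalence class follow from the
search's deterministic tie-breaking.

## State discrimination

Features are the 81 directed edge weights per recording.  **RFE**: z-score
columns, fit a linear soft-margin SVC (C = 1, the conventional default; the
linear kernel is fixed), remove the feature with the smallest absolute
hyperplane coefficient (ties remove the higher column index), repeat; the
ranking is the reverse elimination order.  One feature is removed per
round.  **Accuracy curve**: for k = 1…81, leave-one-out accuracy of the
top-k features.  The default cross-validation unit is the **subject** (both
recordings held out together), respecting within-subject dependence;
per-recording LOO (`by_sample`) is provided for protocol compatibility.
Standardization statistics always come from the training fold only.

The default protocol computes the ranking once on all samples and then
cross-validates each subset.  That ranking has seen every sample, so the
curve is optimistically biased — this is the conventional procedure for
this analysis and is what the acceptance evaluation uses; `nested=True`
recomputes the ranking inside every training fold, removing the selection
bias at extra cost.  Null calibration (identical generating networks for
both conditions) confirms the *protocol as tested* stays inside the
within-subject label-permutation 95% band.

## Numerical choices and degenerate inputs

* Zero-variance columns: error (named node) at standardization; constant
  feature columns get exactly zero SVC weight and drop out of RFE first.
* Strict-improvement threshold 1e−9 in the climb; subset refits cached by
  (node, parent-set) on the Gram matrix, so family cost is O(|pa|³)
  independent of N.
* A jittered weight that lands exactly on 0 is nudged to the smallest
  positive float to keep the subject's structure fixed (measure-zero
  event).
* All TSV/JSON writers use fixed float formats; rerunning a configuration
  reproduces byte-identical artifacts.

## Problem sizes used in the shipped evaluation

Simulation-based checks run at the study's own scale (20 × 2 × 230) where
the claim concerns that scale (classification, group networks, null
calibration), at T = 50 000 for asymptotic parameter checks, and at
four nodes/50 datasets for exhaustive-search comparisons (543 labelled
DAGs).  The radius-sensitivity harness and image-rendering tests use small
bounding grids around the node spheres rather than a whole-brain grid; the
extraction code path is identical.

## Limitations

* The simulator shares the learner's assumptions; passing tests show the
  pipeline is correct and internally consistent, not that the model is
  adequate for real haemodynamic data (autocorrelation, HRF, non-Gaussian
  artefacts, spatially correlated noise are all absent).
* Group learning by concatenation assumes a common structure across
  subjects; heterogeneous cohorts would call for hierarchical approaches.
* Directionality claims are bounded by Markov equivalence; only colliders
  orient edges from observational data.
* No multiple-testing correction on the 72 edge t-tests (by design, to
  match the significance convention the fixtures encode).
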