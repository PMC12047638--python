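# Methods

## The scientific question and the overall procedure

The package asks whether the neural representation of visual stimuli is
shared across brains and across awareness states. Two observations motivate
the design. First, decodability alone does not characterize *how* content is
represented; representational similarity analysis (RSA) against an explicit
feature model does. Second, within-subject inference over a single highly
sampled observer does not license claims about a common code; training a
model on one subject and testing it on a different subject does. Both
pipelines therefore always cross subjects: with `n` subjects there are
`n(n−1)` ordered (train, test) pairs — 42 for the 7-subject design — and
three scenarios: within-conscious (train and test on trials rated "clear
experience"), within-unconscious (both "no experience"), and
conscious→unconscious generalization. "Glimpse" ratings are intermediate and
excluded from both conditions.

## Encoding-based searchlight RSA

For a pair (A → B): a linear encoding model is fit on subject A's
training-condition trials, mapping each trial's item feature vector
`x ∈ R^d` to the response of every voxel. The estimator is ridge regression
on standardized features, solved in closed form per voxel:
`W = (ZᵀZ + λI)⁻¹ Zᵀ Y_c`, with the per-voxel intercept absorbing the
response mean. The paper-level procedure does not name the estimator; ridge
is the field-standard choice for voxelwise encoding, is deterministic, and
remains stable when trials are fewer than feature dimensions. The default
penalty is λ = 1 on standardized features. Because the ridge solution is
separable across voxels, one whole-brain fit per training subject is
mathematically identical to refitting inside every searchlight sphere;
sphere slices of the predicted response matrix are taken downstream.

Predicted responses for the items subject B actually saw in the test
condition, and B's observed responses averaged per item, each yield an
items × items RDM per sphere with entries `1 − r` (Pearson between pattern
rows). The two RDMs' strictly-lower triangles (length `n(n−1)/2`, 4560 for
96 items) are compared by Spearman rank correlation (average ranks on ties),
and the coefficient is written to the sphere center. Feature responses are
standardized with training statistics only; voxel responses are left on
their native scale (per-voxel affine changes do not affect
correlation-based RDMs; cross-voxel scale differences do enter the RDM, as
they do in standard practice).

## Cross-subject searchlight decoding

For a pair (A → B), each sphere trains a per-feature standardizer (mean/sd,
locked at test time; zero-variance features pass through centered) followed
by an L1-regularized linear SVM (squared hinge, the standard convex
formulation that admits an L1 penalty; deterministic dual=False solver,
tolerance 1e−4). `penalty_strength` is a regularization strength with
`C = 1/penalty_strength`, so the default 1.0 is C = 1 and strong penalties
drive weights to exact zeros. Performance is ROC AUC computed from
continuous decision values — thresholded labels would make AUC degenerate —
so 0.5 is chance regardless of class imbalance; class imbalance is logged,
not corrected.

## Searchlight geometry

A sphere is the set of integer voxel offsets whose physical distance from
the center is at most `radius_mm` (default 6 mm), derived from the NIfTI
voxel size; with 2 mm voxels this is the "3-voxel" sphere, and a
radius-in-voxels override exists. Every in-mask voxel is a center; spheres
are truncated at the mask (no padding, no minimum size — a sphere always
contains its center). Centers are processed independently, so output is
bit-identical under any iteration order or thread chunking. A sphere whose
statistic is undefined (e.g. constant patterns in pure-zero tissue) is
recorded as missing in a validity mask rather than aborting the map.

## Group inference: TFCE + sign-flip max-statistic permutation

The per-scenario stack of pair maps is tested one-sample, one-sided against
the null value (0 for Spearman correlations, 0.5 for AUC). The statistic is
the threshold-free cluster enhancement of the mean centered map:
`TFCE(p) = Σ_{h ∈ (0, v_p]} e(h)^E h^H dh`, with `e(h)` the size of the
suprathreshold 26-connected component containing `p`. Defaults are the
field-standard `H = 2`, `E = 0.5`, and a 100-step staircase with thresholds
at step midpoints, so an isolated voxel of value `v` integrates to `v³/3`
within a fraction of a percent. Negative values contribute nothing, and the
transform is monotone: raising any voxel never lowers any TFCE score.

Each permutation flips the sign of every centered map independently and
records the image-wide maximum TFCE; voxelwise familywise-corrected p-values
are `(1 + #{max ≥ observed}) / (n_perm + 1)`, or exact ranks when the
`2^n` sign assignments are enumerated exhaustively (automatic when
`2^n ≤ n_perm`; with Monte Carlo draws the smallest attainable p is
`1/(n_perm + 1)`). Whether the original analysis permuted mean maps or
t-maps, and its permutation count, are not specified; this implementation
uses mean maps (variance-normalized TFCE input is deliberately out of
scope) and defaults to 5000 permutations.

## The synthetic-data generator

`simulate_dataset` emulates the study conditions: 7 subjects; 96 items, the
first half animate (category is a deterministic function of item id, with 10
notional subcategories folded into the two-class structure); 6 sessions × 9
blocks × 32 trials = 288 trials/session and 1728 per subject, items balanced
up to rounding; 300-dimensional item features drawn with an equicorrelation
block structure (within-animate correlation 0.5, within-inanimate 0.3,
between 0) so the model RDM shows the two-category block pattern with the
animate block tighter. Awareness labels are i.i.d. per trial from
`awareness_probs`, default (0.55, 0.15, 0.30) — the experiment's staircase
targeted a high proportion of unaware trials but published no proportions,
so the split was fixed once at a plausible value. The category response is
correct with awareness-dependent probability (0.5 / 0.7 / 0.95), putting
unaware-trial d′ at zero in expectation — the "null perceptual sensitivity"
regime; d′ uses the log-linear (+0.5) correction only when a hit or
false-alarm rate is exactly 0 or 1.

Volumes are trial-level response maps on a shared grid (default 24³, 3 mm
voxels, ellipsoidal brain mask): inside a cuboid signal region each voxel's
response is a linear map of the trial's item features plus Gaussian noise;
elsewhere pure noise. Per-subject weight maps mix a common map with
subject-specific ones via `shared_fraction` (1 = identical encoding across
subjects); weights are scaled by `weight_scale/√d` so `noise_sd` is
interpretable as the inverse per-voxel SNR. All randomness derives from a
single seed through per-subject seed sequences, making designs and volumes
bit-reproducible and independent of subject processing order.

What the generator does *not* emulate: hemodynamics and time-series
structure (volumes are trial-level responses, sidestepping the unstated
single-trial estimation step of the original analysis), the adaptive
staircase, masking, reaction times, spatial autocorrelation of fMRI noise,
and inter-regional structure. Passing recovery tests therefore demonstrates
the correctness and calibration of the *analysis machinery* under the
planted model, not performance on real BOLD data.

## Feature extraction backends

The downstream pipelines consume only an items × dimensions feature matrix.
The reference head architecture — a frozen convolutional backbone, adaptive
global pooling, a 300-unit hidden layer with SELU activation (features are
post-activation), per-unit binary cross-entropy over one-hot targets, SGD,
early stopping after 5 non-improving epochs, inputs resized to 128 × 128 × 3
— is specified by `BackboneSpec`, but pretrained-network training is not
executed here: backends are pluggable, and the tested backend is a
deterministic two-layer toy CNN with fixed seeded weights whose forward pass
is verified by hand. The train/validation split ratio of the original
fine-tuning is unstated and is left to the backend.

## Problem sizes used by the test suite

The suite verifies each stage at desk scale, chosen once: unit tests use
10–14 voxel grids with ~a dozen items; the type-I simulation uses a 10³ grid,
4 subjects (12 pair maps), 50 replicates and 500 permutations; the
end-to-end recovery runs both pipelines on a 24³ grid with 4 subjects, 24
items, 60 feature dimensions, 144 trials per subject, fully shared weights
and noise sd equal to the per-voxel signal sd, with 1000 permutations.

## Numerical choices and degenerate inputs

Pearson rows with zero variance are rejected naming the offending item
(norm guard 1e−12); RDMs are exactly symmetrized and clipped to [0, 2];
asymmetric matrices beyond 1e−8 are rejected by `lower_triangle`. A constant
lower triangle or a single-class test set yields NaN with a warning rather
than an arbitrary number. Affine mismatches beyond 1e−4 between volumes and
masks are errors naming both affines. Subject pairs lacking trials in a
required condition, or with fewer than 3 common items, are skipped with a
warning, and incomplete per-condition item coverage shrinks that pair's RDM
to the common item set.

## Known limitations

- **Pair-map dependence breaks exact type-I control for the RSA pipeline.**
  The group test treats the `n(n−1)` pair maps as exchangeable independent
  units, as the published procedure does. They are not independent: every
  training subject's encoding model predicts a similar, feature-driven
  representational geometry, so for a fixed test subject the expected RSA
  value depends on that subject's noise realization, and maps sharing a test
  subject are positively correlated even under a global null. Sign-flipping
  then underestimates the variance of the mean map and the familywise error
  of the RSA pipeline exceeds its nominal level (the suite's type-I test
  exposes exactly this). The permutation machinery itself is exact — on
  independent sign-symmetric null maps the empirical familywise rate matches
  the nominal 5% (verified in the group-statistics tests) — and the decoding
  pipeline is immune, because a decoder trained on label-free noise has
  expected AUC exactly 0.5 for any fixed test set. Conclusions drawn from
  the encoding-RSA group maps should be read with this caveat; a
  subject-level (rather than pair-level) resampling scheme would restore
  exchangeability but is a deliberate departure from the replicated
  procedure and is left as an extension point.
- Registration to a common space is assumed done; all subjects must share
  one grid and mask.
- Euclidean, Mahalanobis, and Riemannian RDM metrics, surface-based
  searchlights, nonlinear decoders and within-subject cross-validation are
  out of scope (extension points).
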