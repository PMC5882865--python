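# Methods

## Problem setting

23 migratory insect species are to be identified from up to four
morphometric features: mass (mg), wingbeat frequency (Hz), body
length-to-width ratio (unitless) and body length (mm). The first three are
retrievable by current entomological radar; body length is included to
quantify the value of a prospective extra observable. The only published
inputs are per-species summary statistics (mean, standard deviation,
observed min–max range of each feature), bundled with the package as
`src/dtsvm/data/table1.csv`.

Three rows of the source table required care in transcription. The total
specimen count (5,532) and the global mass range (5.2–519 mg) stated in the
source's prose uniquely resolve two ambiguous quantity/range cell boundaries
(T: 892 specimens, mass 59.9–75.3 mg; U: 1,574 specimens, mass 5.2–23.8 mg).
One row (E) has a printed mass range (37.1–152.0 mg) that formally contains
its mean but is ~41 standard deviations wide on the low side; it is stored
as printed and flagged `range_suspect`, which exempts it from the
range-contains-mean validation. Ranges play no role in cohort generation
(only means and standard deviations do), so the flag does not affect
results.

## Synthetic cohorts

Each species is extended to a fixed-size cohort (default 5,000 samples, the
study value) by sampling each feature from a normal distribution with the
species' mean and standard deviation. Per-species covariances of the raw
specimens are not published, so features are drawn **independently** by
default; a per-species correlation matrix can be supplied by users holding
raw data (`GenerationConfig.correlation_mode`). Draws that would be
non-positive are resampled rather than clipped, preserving the distribution
shape near zero without a point mass (relevant only for the lightest
species, whose mass mean sits ~5σ above zero). Truncation of draws to the
observed ranges is available (`truncate_to_range`) but off by default: the
source's distribution plots of the constructed samples are smooth Gaussians,
indicating untruncated generation.

Reproducibility: each (species, feature) pair draws from a substream keyed
by the master seed, a hash of the species label and the feature's canonical
index. Consequences: cohorts are identical regardless of which other species
are generated, and a 3-feature cohort equals the corresponding columns of
the 4-feature cohort at the same seed, making feature-set comparisons
sample-matched by construction.

The 50/50 train/test split is stratified per class with an odd sample going
to training.

What the generator does **not** emulate: within-species feature
correlations (mass and body length are strongly correlated in real insects),
non-Gaussian tails, seasonal/physiological drift of wingbeat frequency, and
any radar-specific retrieval bias. Passing accuracies therefore demonstrate
that the method recovers the study's results under its stated generative
model, not field performance on real radar retrievals.

## Separability and tree construction

The inter-class separability factor between class groups i and j is
`dm_ij = d(m_i, m_j) / (σ_i + σ_j)`: Euclidean distance between class
centers over the sum of scalar spreads. Two conventions are fixed here
because a multivariate spread must become a scalar: the center is the
arithmetic mean (the k=1 K-means fixed point) and `σ_i² = tr Σ_i`, the trace
of the per-class sample covariance (n−1 normalisation) — the unique
rotation-invariant scalar consistent with the Euclidean numerator. ICSF is
invariant under common rescaling of all features.

Raw features span orders of magnitude (mass up to ~500 mg against a
unitless ratio below 13), which would make Euclidean distance
mass-dominated. Features are therefore z-scored on the training set before
ICSF computation and SVM training (the scaler is stored on the tree and
applied to test data); `standardize_features=False` gives strict raw-feature
behaviour.

The tree is built agglomeratively: compute all pairwise ICSFs, merge the
least-separable pair, recompute the merged group's statistics **from the
pooled samples** (not from sub-group summaries), repeat. Ties on the
minimal ICSF break on the lexicographically smallest merged label string,
making construction deterministic. Read top-down, the final merge is the
root, i.e. the most separable split is decided first.

A note on monotonicity: the greedy order does not guarantee that a parent's
merge ICSF dominates its descendants' — merging inflates a group's spread,
so later minima can dip below earlier merge values — and the 23-species
cohort indeed shows a few mild inversions below the root.
`DTSVMTree.merge_icsf_monotone()` reports the property; the root is always
the last (and on this data the largest) merge.

## Node classifiers

Each internal node holds a two-class SVM (scikit-learn `SVC`) trained on the
standardized training samples of the node's species set, labeled by child
side. Defaults: RBF kernel, `gamma = 0.5` and `C = 100`, unweighted classes.
The kernel width corresponds to a length-scale of one standard deviation on
standardized features — fine enough to track the curved boundaries between
heavily overlapping species, yet smooth enough that a sample lying beyond
the support vectors (common under 40% mass noise) is still routed by the
feature that actually separates its class instead of decaying to the
decision function's bias sign, a far-field artifact observed with narrower
kernels. `C = 100` is effectively a hard margin, appropriate because
generated cohorts contain no label noise. Against the computable
Bayes-optimal classifier of the diagonal-Gaussian model (mean accuracy
96.4%, minimum 83.1% on three features), the cascade with these defaults
reaches ~95.7% / ~79%, i.e. within a point of the ceiling; softer settings
(e.g. `C = 1`) underfit the most overlapping species by 5–15 accuracy
points. Inverse-frequency class weighting (`class_weight="balanced"`) is
available for the strongly imbalanced 1-vs-many nodes but measurably lowers
the minimum per-species accuracy on balanced test cohorts, so it is off by
default.

Prediction cascades each sample from the root through successive binary
decisions to a leaf. Identification accuracy is per-species recall
(confusion-matrix diagonal over row sum); the mean is unweighted across
species, matching balanced test cohorts.

## Measurement-error model

Radar imprecision is emulated at the feature level: additive Gaussian noise
on wingbeat frequency (σ in Hz) and multiplicative relative error
`x → x·(1+ε)` on mass, length-to-width ratio and body length, with ε normal
and calibrated so that the **realised** root-mean-square percent error
equals the stated RMSPE exactly (positivity resampling left-truncates ε at
−1; the pre-truncation σ is solved from the truncated-normal second moment —
a ~2% relative correction at the 40% level, negligible below 20%). A
mean-one log-normal multiplier with matching RMSPE is available as an
option. Errors are injected into **both** the training and testing halves,
and the tree is rebuilt and retrained on the noisy training data, so the
classifier never sees cleaner data than the test set. Noise streams are
keyed per (seed, species, feature), so the noise a sample receives does not
depend on which other rows are present.

Built-in cases: wingbeat σ = 1 Hz throughout; mass and length-to-width
RMSPE 40% / 20% / 10% (Cases I–III, 3 features); Case IV adds body length at
10% RMSPE (4 features). Independence of errors across features is assumed.

## Numerical and design choices

- Master seed → derived seeds: generation = seed, split = seed+1, noise
  streams hashed from (seed, case label, train/test half); all below 2³¹ and
  recorded in every report's metadata.
- A case's noise is keyed by its label, not its position in a grid, so
  running Case IV alone, in the standard quartet or in a custom sweep gives
  identical results.
- Degenerate inputs: identical zero-spread classes make ICSF undefined
  (error); distinct zero-spread classes give an infinite ICSF; a class with
  a single sample has σ = 0; zero-variance features are rejected at
  standardization with the feature named.
- Reports store accuracies at full precision; presentation rounds to two
  decimals.
- Cohort sizes: 5,000 samples/species for noise-free experiments (the study
  value; ~20 s on one CPU) and 1,000/species for the error cases, whose
  per-sample error process makes accuracy estimates insensitive to cohort
  size beyond a few hundred samples per class.

## Known limitations

- Independence of features within species is a simplification forced by the
  published inputs; real covariance structure would change (likely improve)
  separability for correlated feature pairs.
- Exact per-species accuracies depend on unpublished details (covariances,
  SVM settings) of the original study; only tolerance-level agreement is
  meaningful.
- Species W's wingbeat band (74–92 Hz) touches species B's (38–75 Hz), so
  under untruncated Gaussian cohorts a handful of W samples per thousand are
  genuinely confusable at 40% mass error; W's accuracy reaches 1.00 only at
  two-decimal precision in Cases I–II.
- There is no rejection class: a species outside the 23 training classes
  will be confidently mislabeled. Extending the cascade with an
  outlier/none-of-the-above gate is future work.
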