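# Methods

## The decoding problem

Each sample is the Fisher-z Pearson connectome of one six-minute meditation
block: with 90 ROIs there are 4005 upper-triangle edges per sample and at
most 72 samples per group, so the feature-to-sample ratio is extreme and
univariate screening inside cross-validation is essential. The decoder
answers: can the style of meditation being practiced (focused attention, FA,
vs open monitoring, OM) be read out from the connectome of a held-out
subject?

## Cross-validation scheme

The unit of splitting is the **subject**, not the sample. Each of the 200
repetitions assigns round-half-to-even(0.75 · n_subjects) subjects to
training (with at least one subject always held out) and all six of a
subject's samples travel together; this is the only choice that prevents
subject-identity leakage when multiple blocks per subject enter the design.
Within each repetition:

1. per-edge one-way ANOVA F (two classes, so F = t² with pooled variance) is
   computed on training rows only; constant features get F = 0, zero
   within-class variance with distinct means gives F = ∞ (sorted first);
2. the k = 200 largest-F edges are kept, ties broken by ascending edge id so
   selection is deterministic;
3. a linear soft-margin SVM (hinge loss, C = 1, libsvm) is fit on the
   selected features with FA encoded +1 — positive weights therefore mark
   edges whose higher connectivity pushes the decision toward FA;
4. accuracy is the fraction of correctly labelled held-out samples.

Features are not standardized by default (Fisher-z values share a scale); a
config flag enables it. Per-repetition RNG streams derive from the master
seed, so any repetition can be reproduced in isolation and the whole run is
bitwise reproducible.

## Statistical machinery

**Permutation test.** Condition labels are shuffled (default: within each
subject, which respects the exchangeability of blocks within subject and
preserves per-subject class balance; a `global` scheme is available) and the
*entire* CV chain — selection inside folds included — is rerun per
permutation. The default p-value is the add-one Monte-Carlo estimate
(#{null ≥ observed} + 1)/(n_perm + 1), which is a valid p-value at any
n_perm; the plain ratio convention is available as `correction="ratio"`.
Bonferroni (m = 2) covers the two per-group tests.

**Group comparison.** Mann-Whitney U on the two 200-fold accuracy
distributions (midrank ties; exact null for small tie-free samples,
asymptotic with tie correction otherwise). Because fold accuracies come from
overlapping training sets they are not independent; the same caveat applies
to the original procedure being replicated, and the test is interpreted as a
descriptive comparison of the two distributions.

**Bayesian comparison vs chance.** The correlated t-test: fold-accuracy
differences from the comparator get a Student-t posterior whose variance is
inflated by the Nadeau–Bengio factor (1/n + ρ/(1−ρ)); ρ defaults to the
test fraction 0.25. Degenerate zero-variance inputs return 0.5 (zero mean)
or 0/1 with a flag.

**Controls.** Bootstrap: the larger group is subsampled without replacement
to the smaller group's size and the full CV rerun per draw; the observed
accuracies are located as percentiles of the bootstrap distribution.
Age: features are replaced by residuals of a per-group regression on
[1, age] over all samples before decoding — a dataset-level cleanup whose
train/test leakage is inherent to the procedure and documented rather than
corrected.

## Relevance analysis

Selection probability of an edge = (#repetitions selecting it)/200; since
every repetition selects exactly k edges, the probabilities sum to exactly k
(a useful invariant test). Network relevance averages probabilities over
within- and between-network edge blocks; a single-ROI network has no within
block (NaN). Edges at probability 1 ("stable") enter the weight analysis:
each fold's weight vector is L2-normalized (the normalization is a design
choice; `max_abs` and `none` are available), each stable edge's normalized
weights are averaged across folds, sign > 0 tags the edge FA and < 0 OM, and
a per-edge one-sample t-test across folds (Bonferroni over stable edges)
quantifies departure from zero — again using dependent fold replicates by
design. Hemisphere statistics partition stable edges into intra-left /
intra-right / inter; edges with a midline endpoint go to an `other` class
and are excluded (the atlas labels some ROIs medially and no principled
left/right assignment exists for them). |weight| left vs right is compared
one-sided by Mann-Whitney; the intra-hemispheric *counts* are tested by
permuting the ROI hemisphere-label vector and recounting (add-one p). The
label-permutation construction of this count null is an interpretation: it
holds the stable edge set fixed and asks whether its concentration in one
hemisphere exceeds what arbitrary hemisphere labelings produce.

## Synthetic study generator

The generator emulates the study conditions, not the physiology: expert
n = 12 and novice n = 10 subjects, 2 conditions × 3 blocks, 88 volumes per
block at TR = 4.087 s. Each block is a stationary multivariate Gaussian
draw. The baseline correlation matrix has ρ_net = 0.35 on within-network
pairs (a typical within-network functional-connectivity level) and 0
elsewhere; each subject receives a symmetric Fisher-z jitter (sd 0.02,
shared across conditions) so subjects differ reproducibly. Condition
effects are planted in Fisher-z units, split symmetrically about the FA/OM
midpoint (+Δz/2 in FA, −Δz/2 in OM; sign flipped for OM-tagged effects) and
scaled per group; after perturbation the matrix is repaired to the nearest
SPD correlation matrix (eigenvalue clipping + diagonal renormalization), and
the achieved z-difference stays within 0.02 of the target. Defaults plant
20 random edges at Δz = 0.5 with group scales expert 1.0 / novice 0.15,
alternating FA/OM attribution — the regime used throughout the calibration
and power tests. Observation noise (sd 0.2 of signal sd) mildly attenuates
correlations; an optional AR(1) coefficient adds temporal smoothness without
changing the stationary covariance. Motion is random-walk drift (0.02 mm per
step, rotations scaled so their framewise-displacement contribution matches)
plus Bernoulli(0.05) translation spikes of 1 mm to exercise scrubbing; two
white-noise confound channels leak into every ROI with loading 0.1 to give
nuisance regression something real to remove. Ages are drawn from
N(37.9, 9.4²) for experts and N(33.0, 4.0²) for novices and carry no feature
effect by default; `age_confound_scale` injects a linear-in-age shift to
test the age control.

What the generator does **not** model: hemodynamic response convolution,
scanner noise spectra, physiological rhythms, spatial structure within ROIs,
or realistic effect-size distributions. Passing tests therefore demonstrate
that the pipeline is correct and calibrated under its own assumptions
(Gaussian, stationary, edge-sparse effects), not that real meditation
connectomes are decodable at any particular accuracy. In particular the
planted Δz = 0.5 is a deliberate strong-signal calibration choice that makes
ground-truth recovery testable; real effect sizes are unknown and plausibly
far smaller.

## Preprocessing choices

Order is fixed: nuisance regression → linear detrend → band-pass →
scrubbing. Filtering precedes scrubbing because the zero-phase filter
requires uniformly sampled input; whether the original analysis scrubbed
before or after filtering is not determinable, so the order is a documented
package decision. The band-pass is a Butterworth design (order 2 per edge,
i.e. a 4-pole band-pass) applied forward-backward (`sosfiltfilt`), giving
zero phase and a squared magnitude response; at TR = 4.087 s the 0.009–0.08
Hz band sits below the 0.1223 Hz Nyquist frequency, and infeasible
band/TR combinations raise a configuration error. Framewise displacement
uses the Power et al. formulation with a 50 mm head radius; volumes with
FD strictly greater than 0.5 mm are removed (no neighbor dilation), and a
block with fewer than 10 surviving volumes is flagged unusable and excluded
downstream. Pearson r is clipped to ±(1 − 1e−7) before atanh so degenerate
synthetic blocks stay finite.

## Numerical and accounting notes

- A published description of this design counts "six correlation matrices
  per participant … 36 samples for experts"; the arithmetic in its own
  parenthetical (3 matrices × 12 participants) shows 36 is the *per-class*
  count, and the package adopts that reading: 36/class (72 total) experts,
  30/class (60 total) novices.
- Edge k ↔ (i, j) uses row-major upper-triangle order (`np.triu_indices`);
  the mapping is bijective and exhaustively tested.
- Splits with a missing class on either side (possible only after heavy
  scrubbing) are redrawn from an offset stream, logged.
- The whole-dataset F-statistics reported for stable edges use
  df = (1, n_samples − 2); with the full expert design that is (1, 70) —
  a smaller published df simply reflects a smaller usable sample.

## Problem sizes in tests and the acceptance script

Calibration tests run the chain at reduced but statistically adequate sizes
chosen as package defaults for desk-scale verification: the null-calibration
study uses a 20-ROI toy parcellation, 40 volumes, 20 CV repetitions and 99
permutations over 50 seeds; the power/recovery study uses the full 90-ROI
default design with 200-repetition decoding for stable-edge analysis and
50-repetition CV inside 49 permutations over 20 seeds. The acceptance
script uses the full default study with 200-repetition decoding, 99
permutations and 50 bootstrap draws (50-repetition CV inside both loops).

## Known limitations

- Fold-level t-tests and Mann-Whitney comparisons treat dependent CV folds
  as replicates, replicating the interrogated procedure rather than
  correcting it; p-values from these are optimistic.
- The age regression is fit on all samples (dataset-level), so a small
  amount of test-set information leaks into the control analysis.
- The hemisphere count-permutation null and the weight normalization are
  reconstructions of under-specified procedures; both are config-switchable.
- The synthetic forward model's Gaussianity means heavy-tailed artifacts,
  global signal fluctuations and condition-dependent motion are untested.
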