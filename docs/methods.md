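# Methods

## Recurrence features

A window of N samples from one 3-axis accelerometer is a trajectory of
3-vectors in g-units; no time-delay embedding is applied, since the
three axes already span the phase space of interest.  The recurrence
matrix thresholds all pairwise Euclidean distances at ε with the
closed-ball convention Θ(0) = 1, which keeps the main diagonal (line of
identity) well defined.  Orientation invariance is exact: an orthogonal
re-mounting Q and the constant gravity offset g transform every sample
as a ↦ Q(a + g), which preserves pairwise distances, hence the matrix.
Acceleration is never converted to m/s²; ε lives in the same g-units as
the data.

Nine measures summarize each matrix.  RR is the fraction of the N²
cells that recur.  DET, L, ENTR and Lmax are functions of the histogram
P(ℓ) of maximal diagonal runs; LAM, TT and Vmax of the histogram P(v)
of maximal vertical runs; RATIO = DET/RR.  ENTR uses the natural
logarithm of the normalized length distribution over qualifying lines.

Conventions the literature leaves open, fixed here and configurable:

* **Minimum line lengths** ℓ_min = v_min = 2 — the smallest values for
  which "lines" differ from isolated recurrence points.
* **Line of identity**: included in RR (it is forced on by Θ(0) = 1)
  but excluded by default from the diagonal-line histogram, a
  Theiler-style exclusion that stops DET from being trivially inflated
  by self-matches.  All tests and oracles honor the flag when it is
  switched.
* **Degenerate cases**: when no qualifying line exists, DET, LAM, L,
  TT, ENTR, Lmax and Vmax are 0 — never NaN.  RR is always positive,
  so RATIO is always defined.
* The histograms count both triangles of the (symmetric) matrix, so
  every off-diagonal line appears once per triangle; this cancels in
  every ratio-type measure and is the standard way the sums over i, j
  are written.

The diagonal histogram is computed by laying all 2N−1 (or 2N−2)
diagonals end to end with zero separators and doing a single
vectorized run-length pass; verticals use the column-flattened matrix
with a zero guard row.  Both are tested exactly against exhaustive
per-diagonal / per-column Python scans, and all nine measures against
direct formula evaluation, to 1e-12.

The ε hyperparameter grid is the 16-point geometric sequence
{2·0.65^i, i = 0…15} ≈ [2.0 … 0.0031] g.

## Segmentation and labeling

Windows are T = 1 s long with 87 % overlap.  The step is converted to
whole samples as step = round((1 − overlap)·N) with N = round(T·rate):
8 samples at 60 Hz (86.7 % actual overlap), 12 at 90 Hz.  Windows are
defined in seconds so 60 Hz and 90 Hz recordings coexist; measures that
depend on N are normalized in the formulas themselves.

A window's ground truth comes from interval annotations.  The default
majority rule assigns the label covering the largest fraction of the
window, counting un-annotated time as the non-stereotyped `unknown`
class, with all ties resolved to `unknown` — conservative toward the
negative class at bout boundaries.  A `center` rule (label at the
window midpoint) is available.  Feature tables carry identity columns
(`participant, session, window, start_s, label`) and sensor-major
feature columns `<sensor>.<measure>`, 9 per sensor.

## Classifiers

* **Decision tree** — CART, Gini criterion, grown until all leaves are
  pure (scikit-learn).
* **Random forest** — an in-package bagged ensemble of such trees,
  ⌊√d⌋ candidate features per split, majority vote with ties to the
  lexicographically smallest class.  The forest retains each tree's
  bootstrap row set, so out-of-bag (OOB) quantities are exact.  The
  per-tree grid is n_trees ∈ {100, 250, 500}.
* **Linear SVM** — scikit-learn's SVC with a linear kernel (libsvm),
  one-vs-one for the 4-class problem, C ∈ {1, 100, 10⁴, 10⁵}.
  Features are z-scored with the training rows' mean and population
  standard deviation; zero-variance columns map to 0; test rows reuse
  the training parameters.  Trees consume raw features (they are
  scale-invariant).

**Balancing.**  Training folds are balanced once, before any
normalization: the target count is the largest SMM-class count; the
`unknown` majority is under-sampled without replacement, smaller SMM
classes are resampled with replacement, and a class already at the
target is kept verbatim.  If `unknown` ever falls below the target
(tiny training subsamples) it is resampled like a minority.  Empty
classes are dropped with a warning.  Test data always keeps its natural
distribution.

**Feature importance.**  For every tree, each feature is permuted among
that tree's OOB rows and the increase of the tree's OOB error recorded;
the importance score is the mean increase over trees divided by the
standard deviation of the per-tree increases (the raw mean when that
deviation is zero).  This is the classic OOB permutation importance;
it is not the Gini importance scikit-learn reports, which is why the
forest is implemented in-package with its bootstrap bookkeeping, and
why a stock random forest serves as an accuracy cross-check in the
tests rather than as the implementation.

**Model selection** maximizes mean validation accuracy over the
ε × configuration grid, breaking ties toward smaller ε and then smaller
capacity (fewer trees / smaller C).

## Evaluation protocols

* **Session k-fold** (within participant): one fold per recording
  session; training on balanced data from the remaining sessions,
  testing on the held-out session's natural distribution.
  Hyperparameters are selected inside the training sessions —
  leave-one-session-out when at least two remain, otherwise a seeded
  80/20 window split of the single training session.  A participant
  with one session raises (no folds exist).
* **Leave-one-participant-out**: pooled training rows from all other
  participants, uniformly subsampled to N_K = round(K·N) (minimum 1)
  for K ∈ {0.5^i, i = 0…14}, then balanced, then fit; scored on every
  window of the left-out participant.  Subsampling precedes balancing
  so the balancer sees the natural distribution.  Hyperparameters are
  fixed to the pair most frequently selected by the session k-fold.
  A subsample too degenerate to train on (a single class) predicts its
  majority label — such runs score near chance, which is the honest
  value of a one-example training set.
* **Sensor ablation**: the session k-fold repeated for each wrist
  alone, the torso alone, and all three sensors (d = 9, 9, 9, 27),
  reported per participant and averaged.
* **Metrics** are window-level: accuracy is the fraction correct on the
  natural test distribution; per-class precision/recall are reported
  with `None` (not 0) for classes absent from the truth or never
  predicted.

**Leakage guard.**  Evaluation code flags test tables, and every
fitting routine (balancing, z-score fitting, training) refuses flagged
rows, so train/test separation is enforced by construction rather than
by convention.

**Determinism.**  One master seed fans out through
`numpy.random.SeedSequence` to balancing, bagging, subsampling and
permutation importance; re-running any experiment with the same seed
produces byte-identical result files (sorted-key JSON, fixed-format
CSV).

## Synthetic cohort generator

The generator produces the statistical structure the method assumes,
not biomechanics.  Per session it places non-overlapping bouts with a
seeded renewal process (Poisson counts at the configured per-minute
rates, uniform starts, 0.5-s margin, overlap rejection; impossible
configurations raise rather than silently thin out).  Default
conditions, chosen to be a realistic desk-scale miniature of a
wearable-sensor study:

| parameter | rock | flap | flaprock |
|---|---|---|---|
| rate (min⁻¹) | 1.0 | 1.0 | 0.4 |
| duration (s) | 3–12 | 2–8 | 3–10 |
| frequency (Hz) | 0.4–1.5 | 2.5–5.0 | both |
| amplitude (g) | 0.3–0.8 | 0.3–1.0 | both |
| dominant sensor | torso | wrists | both |

— about a quarter of each session is labeled SMM, the rest is
background.  Bouts are amplitude-enveloped (Tukey) sinusoids along a
random 3-D axis with a 25 %-amplitude second harmonic; `flaprock`
superimposes one component from each band.  Cross-body mechanical
coupling is modeled by a 0.3 gain of the non-dominant sensor group.
Background is white Gaussian noise (sd 0.05 g) plus a slow smoothed
drift (sd 0.05 g); a constant 1-g gravity vector is added, and by
default one Haar-random orthogonal matrix per (session, sensor) rotates
the gravity-bearing signal.  Cohorts perturb each participant's bout
frequencies (±10 %) and amplitudes (±20 %) so participants differ while
sharing class structure.  The default cohort is 6 participants × 2
sessions × 120 s at 60 Hz.

What the generator does *not* emulate — and hence what passing tests do
not show about real recordings: colored sensor noise, posture changes
and gross non-SMM limb movement, annotation errors and boundary
disagreement between raters, drifting bout frequency within an episode,
and the extreme between-participant imbalance of real cohorts.  Results
on synthetic data validate the machinery and its invariances, not
clinical accuracy.

## Problem sizes used in tests and the acceptance script

Pipeline-scale runs select ε from a 4-point subset of the full grid
(indices 3, 5, 7, 9 → 0.549, 0.232, 0.098, 0.041 g), chosen from the
generator's scales: bout amplitudes 0.3–1 g down to the 0.05-g noise
floor (typical noise-only inter-sample distances ≈ 0.12 g).  Random
forests use 100 trees in pipeline runs; the full grids remain the
module defaults.  The torso-planted checks (wrist gains zeroed so only
the torso carries class signal) use 2-participant, 60-s cohorts across
multiple seeds.  The acceptance script runs the default cohort for the
k-fold and leave-one-participant-out protocols and three torso-planted
cohorts for ablation and importance.

## Known limitations

* The session k-fold's 2-session case selects hyperparameters on a
  single 80/20 split, a higher-variance choice than true nested CV.
* Under-sampling can remove ambiguous bout-boundary `unknown` windows
  from training, so even a test fold identical to its training fold is
  not guaranteed a perfect score (≈ 0.995 observed).
* Bout-level smoothing of window predictions is deliberately out of
  scope; all accuracies are window-level.
* The public-dataset adapter reads a documented local export layout;
  the released archive must be converted to it once, and the adapter is
  exercised only against a synthetic fixture of that layout.
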