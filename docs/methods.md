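# Methods

This note documents the model and procedures implemented in `neurosem`,
the assumptions they rest on, the default parameters and their rationale,
and the package's known limitations.

## 1. Synthetic study design

The generator emulates a concept-fMRI study: participants repeatedly
think about each of 45 physics concepts (spanning classical and
post-classical physics, including a 15-concept "elementary" subset that
both cohorts know) while activation is recorded; independent raters score
each concept on four semantic dimensions (*measurability*,
*mathematical formulation*, *periodicity*, *classical vs post-classical*).

### Geometry

The brain is a rectangular voxel grid (default 12×12×8 = 1152 voxels of
3.125 × 3.125 × 6.0 mm, so one voxel is 58.59 mm³ and a two-voxel cluster
rounds to 117 mm³). The grid is partitioned into four "lobes" (frontal,
parietal, temporal-fusiform, occipital) by x–y quadrant; an arbitrary
label map can be supplied instead. The grid sizes are package choices
tuned so each lobe can host the default 120-voxel stability selection
while staying fast; they are not anatomical claims.

### Planted structure

Each semantic dimension receives `clusters_per_dimension` (default 3)
face-connected clusters of 6–10 voxels grown by breadth-first search in
randomly chosen non-occipital lobes, with per-voxel loadings drawn from
Uniform(0.8, 1.2). Orthographic word length — a nuisance dimension the
analysis should isolate, not interpret semantically — gets 2 clusters
confined to the occipital lobe. Clusters never overlap across dimensions.

Concept scores are z-scored per dimension. Word-length scores are the
z-scored character counts of the concept labels; the classical/
post-classical dimension is a z-scored signed category indicator plus
Gaussian jitter; the rest are standard normal draws.

The "student" cohort shares the faculty topography except that
`round(group_effect × clusters_per_dimension)` clusters per semantic
dimension (default 2 of 3 at `group_effect = 0.5`) are relocated,
modelling expertise-dependent reorganization. Word-length topography is
shared, since orthography does not differ by expertise.

### Signal model

A trial's percent-signal-change (PSC) pattern is

```
psc[c, p, :] = S[c, :] @ (L + participant_perturbation).T + noise
```

with `S` the concept-by-dimension scores, `L` the voxel loading map of the
participant's group, a per-participant loading perturbation of sd
`participant_sd` (default 0.1), and i.i.d. Gaussian trial noise of sd
`noise_sd` (default 0.1, against planted loadings of ~1.0: a
high-signal regime in which decoding saturates, deliberately, so that
every analysis stage can be validated against ground truth). A raw
time-course mode produces a 1 Hz series (baseline 100, one trial per
10 s) from which the package's own PSC extraction (mean of the 4 samples
starting 5 s post-onset, relative to baseline) recovers the tensor
exactly.

Ratings are generated per rater as `clip(round(4 + 1.5 z + ε), 1, 7)`
with rater noise ε of sd 1.0, averaged over 6 raters. Word length is not
rateable (it is not a semantic property), and the generator refuses to
produce ratings for it.

### Randomness

All sampling uses `numpy.random.default_rng` seeded with
`[seed, stream_tag, ...]` spawn keys, so ground truth, each participant
and the ratings have independent, individually reproducible streams:
participant k's data are identical whether simulated alone or inside any
cohort.

## 2. Preprocessing and voxel selection

A voxel's **stability** is the mean pairwise Pearson correlation between
its 45-concept activation profiles across presentations. Voxels constant
in any presentation get a `-inf` sentinel and can never be selected.
Selection takes the top `n` stable voxels (ties broken by ascending
index, deterministically), either per lobe (factor analysis; default 120)
or whole-brain (classification; default 120). **Inside every
cross-validation fold, stability and selection are recomputed from
training data only** — the leakage-guard tests assert bit-identical
training artifacts under held-out perturbations.

## 3. Two-level exploratory factor analysis

*Individual level.* Per participant and lobe, the correlation matrix of
the 120 stable voxels' presentation-averaged profiles is factored by
single-pass principal-axis extraction: the diagonal is replaced by
squared-multiple-correlation (SMC) communality priors `1 − 1/diag(R⁻¹)`
(pseudo-inverse when singular, which is routine at 45 observations ×
120 variables), and loadings are the top eigenvectors scaled by the
square roots of their positive eigenvalues (up to 10 factors per lobe).
Loadings are varimax-rotated (Kaiser row normalization, SVD algorithm,
tolerance 1e-8); factor scores are regression estimates `Z R⁻¹ Λ`,
z-scored, with a 1e-6 ridge when `R` is singular.

*Group level.* The individual factor-score columns (participants × lobes
× factors vectors over the shared 45 concepts) are pooled and factored
the same way; factors whose post-rotation variance reaches
`variance_threshold` of the total input variance are retained. Columns
not loading above 0.4 on any retained factor feed a **secondary**
analysis of identical form, which is how the low-variance word-length
factor surfaces.

**Variance threshold (default 0.02).** At 45 observations and ~120
columns, the Marchenko–Pastur noise edge for a pure-noise correlation
matrix is `(1 + √(M/45))² ≈ 0.06 M` — larger than a 5 % cutoff, so *no*
fractional threshold can reject white noise at this aspect ratio, and a
5 % cutoff also discards the genuine occipital word-length factor
(~2.5 % of input variance). The default of 2 % keeps real low-variance
factors; rejection of noise is delegated to the replication and
validation steps (cross-participant factor alignment, behavioural rating
correlations, cluster replication), which is also how the tests exercise
it: the pure-noise null test uses an explicit threshold above the noise
edge for its size.

*Localization.* Each voxel's loading on each group factor is the Pearson
correlation between its mean profile (over the factor-analysis
participants) and the factor scores. Voxels stable in all those
participants are assigned to their strongest factor when |loading| > 0.4,
and assigned voxels are grouped into face-connected (6-connectivity;
26 optional) components of at least 2 voxels.

*Validation.* Factors are matched greedily (or exhaustively, as a test
oracle) to rating dimensions by maximum |r|; correlations are reported
over all 45 concepts and over the `k = 10` extreme concepts per factor.

## 4. Decoding

Gaussian naive Bayes with **pooled** within-class variance (few exemplars
per concept make per-class variances unstable; a per-class mode exists
and is cross-checked against scikit-learn in the tests) and uniform
priors. Variances are floored at `1e-6 ×` the feature's total variance.
Performance is **normalized rank accuracy** `(n − rank)/(n − 1)` with
average ranks for ties, so chance is exactly 0.5 in expectation — the
acceptance suite verifies 0.50 ± 0.01 over 10,000 random trials.

- *Within-participant:* every `C(6, 2) = 15` choose-two-presentations
  hold-out; train on the 4 training presentations' individual trials,
  test on the mean of the 2 held-out ones.
- *Cross-participant:* leave-one-participant-out on presentation-averaged
  profiles, with features selected by cross-participant profile
  consistency among the training participants.
- *Permutation test:* add-one estimator `p = (1 + #{null ≥ obs})/(1 + B)`.
  The within-participant null permutes the concept axis independently per
  presentation, because a single consistent relabelling leaves
  within-participant accuracy invariant; the cross-participant null draws
  one relabelling per participant. Under the null the p-values are
  uniform (KS-tested in the acceptance suite).
- *Category decoding:* classical vs post-classical mean signatures,
  leave-one-presentation-out, nearest-correlation assignment.

## 5. Forward model

Per retained cluster, the feature is the mean activation of the 5 most
stable voxels within the 3×3×3 cuboid around the cluster centroid
(clusters smaller than 5 voxels are excluded and reported). Ordinary
least squares maps the four rating dimensions (plus intercept) to each
cluster feature. Leave-one-concept-out evaluation reports the squared
Pearson correlation between predicted and observed cluster vectors and
the normalized rank of the held-out concept among all concepts' predicted
patterns by correlation distance. With noiseless linear data this is
exact (R² = 1, rank accuracy 1, weights recovered to 1e-6), which the
acceptance suite asserts.

## 6. Group comparison

Both cohorts are analysed on the 15 shared elementary concepts. Per
cohort: per-participant per-lobe factor analyses, a group factor analysis
(up to 4 factors), and per-participant cluster maps restricted to each
participant's stable voxels. A cluster enters the union set if it
replicates — same factor, centroid within 1 voxel (Chebyshev, in voxel
units) — in at least `group_min_participants` (default 4) participants of
its cohort; overlapping survivors from the two cohorts merge. Each
cluster contributes the mean of its 6 most stable member voxels per
participant; leave-one-participant-out Gaussian naive Bayes predicts
cohort membership.

The **stepwise concept search** scores every single concept, then extends
all subsets whose accuracy did not drop below the running best,
deduplicating subsets and capping the frontier at `beam_width = 16`
(deterministic: sorted by accuracy, then lexicographic index set). The
search stops when every extension strictly decreases accuracy or accuracy
reaches 1.0 (no extension can improve on it); final ties resolve to the
lexicographically smallest index set. The cap and early stop are
termination guards absent from a textbook description of stepwise
selection, which stalls on accuracy plateaus; with `beam_width=None` the
uncapped search is used as the test oracle against exhaustive enumeration
on ≤ 5 concepts.

## 7. Numerical and design decisions

- SMC priors fall back to the pseudo-inverse for singular correlation
  matrices; factor-score regression falls back to a 1e-6 ridge. Both
  paths are logged.
- Varimax fixes column signs (largest-|loading| entry positive) for
  reproducible output; with Kaiser normalization the criterion is
  maximized in the row-normalized metric.
- Eigenvalues below 1e-10 are treated as non-positive; requesting more
  factors than positive eigenvalues reduces the count with a warning.
- All tie-breaks (voxel selection, factor alignment, stepwise search) are
  deterministic, so identical seeds give byte-identical reports.
- Cluster volumes and centroids are computed in physical mm using the
  diagonal affine of the grid.

## 8. What the generator does and does not emulate

It emulates: stable, replicated, spatially clustered dimension tuning;
participant-level topographic variability; expertise-dependent cluster
relocation; an orthographic nuisance factor confined to visual cortex;
noisy bounded-scale ratings; trial-level noise and a raw time-course
acquisition path.

It does **not** emulate: hemodynamic convolution or temporal
autocorrelation (the time-course mode uses a boxcar), spatially
correlated noise, head motion or registration error, anatomical lobe
shapes, overlapping/distributed (non-clustered) codes, or
dimension-correlated noise. Consequently the default regime is easier
than real data — by design, since the package's purpose is validating
analysis code against known ground truth, not simulating realistic
difficulty. Raising `noise_sd`/`participant_sd` produces graded,
non-saturated regimes.
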