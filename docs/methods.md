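# Methods

This note records the statistical model behind `connscreen`, the choices
made where the design was genuinely open, and what the synthetic-data
validation does and does not establish.

## Connectivity estimation

Connectivity between two ROI time series is the sample distance
correlation in its original V-statistic (biased, non-negative) form:
pairwise absolute-difference matrices are double-centred (row means,
column means and grand mean removed), dCov² is the mean elementwise
product, and dCor = sqrt(dCov² / sqrt(dVar²_x · dVar²_y)). A constant
series has zero distance variance; its correlation with anything is
defined as 0 and logged as a warning rather than raised, since a flat
segment is degenerate data, not a programming fault. The unbiased
U-statistic variant is deliberately not offered: "distance correlation"
without qualification means the V-statistic, and its non-negativity keeps
the [0, 1] interpretation of the connectivity tensor.

Finite-sample dCor is biased upward, and the bias depends on series
length. Conditions of different durations are therefore compared via
subsampling: each estimate uses exactly `m = 30` randomly chosen volumes
(uniform, without replacement, the same indices applied to both series),
repeated `reps = 100` times per run × condition; estimates from all runs
are pooled and their median taken. Both `m` and `reps` are configurable;
the defaults are the emulated study's settings. Subsample indices are
sorted before use — a subsample is a set of time points, so this changes
nothing statistically, but it makes the `m = n` boundary case reproduce
the full-sample estimate bit-for-bit.

Whether the repetitions draw indices independently per ROI pair or share
one index set across all pairs is ambiguous in the underlying design.
Shared draws are the default (`share_indices=True`): the per-edge marginal
distribution of the estimator is identical, and sharing lets one
repetition's all-pairs dCor be computed as a single Gram product over the
centred distance matrices, which is what makes full-scale runs feasible.
The literal per-pair mode remains available for fidelity checks at small
ROI counts; a test confirms both modes coincide exactly when `m` equals
the segment length.

### Randomness

One master seed drives everything. Every (subject, run, condition) — and
every (analysis, pairing) in the screening stage — gets its own RNG
substream keyed by stable string identifiers (CRC-32 of the key feeds a
`SeedSequence` alongside the seed), so results are independent of
iteration order and of any future parallelisation, and any scalar seed
below 2³¹ is safe.

## Feature construction

The group-by-condition analysis subtracts each subject's baseline
estimate from the semantic and pragmatic estimates edge-wise, giving
features in [−1, 1]. The idiosyncrasy analysis takes |semantic −
pragmatic| per edge on the *raw* estimates; because the baseline term
cancels inside the difference, normalised and raw inputs give identical
idiosyncrasy values (an algebraic identity that is also tested
numerically), so the choice is immaterial. Cell order is fixed —
(ASD-semantic, ASD-pragmatic, TD-semantic, TD-pragmatic) and (ASD, TD) —
so contrasts are comparable across pairings. Feature columns are never
standardised: mean-centered PLS operates on raw cell means.

## Mean-centered PLS

For one pairing, the cell-mean matrix (cells × edges) minus the
*unweighted* mean of cell means is decomposed by SVD. The unweighted
grand mean (rather than the pooled row mean) keeps the centring
interpretable at cell level when groups are unbalanced (16 vs 19). Only
LV1 — the latent variable with the highest explained variance — is
inferenced; the full spectrum is retained on the results object.

**Permutation test.** Rows are reassigned to cells uniformly with cell
sizes preserved, the centring and SVD repeated, and
p = (1 + #{s₁ᵖᵉʳᵐ ≥ s₁ᵒᵇˢ}) / (1 + n_perm) with 1000 permutations by
default (add-one avoids p = 0; a zero observed s₁ yields p = 1 by
convention). An exact mode enumerates all distinct assignments for small
designs. Free row reassignment ignores that in the four-cell design a
subject contributes one row per condition; a whole-subject scheme
(`permute_scheme="subjects"`, group labels permuted with conditions kept)
is provided. Validation on null cohorts shows the row scheme is exactly
calibrated for the one-row-per-subject idiosyncrasy design and mildly
*conservative* for the paired group-by-condition design (within-subject
row dependence inflates null p-values toward 1); the subject scheme is
exactly calibrated there. The row scheme stays the default — a
conservative test is valid — and the uniformity validation runs each
design under its exchangeable scheme.

**Bootstrap ratios.** Subjects are resampled with replacement within
group (strata are the sets of subjects sharing a cell-membership
pattern), a subject's condition rows moving together; each resample is
re-centred and re-decomposed, and its feature saliences are aligned to
the observed solution by orthogonal Procrustes rotation of the cell
saliences restricted to the non-null LVs — for a single retained LV this
reduces to the usual sign flip — preventing reflection artifacts from
inflating the bootstrap SD. The "z-score" of an edge is its observed
salience divided by the bootstrap SD (floored at 1e-12); 1000 resamples
by default. If the median z is negative, contrast, saliences and z are
negated and the flip recorded, making z distributions positively skewed
and contrasts comparable across pairings.

## Screening and FDR

One PLS per pairing; all p-values of an analysis series form a single
family corrected by Benjamini–Hochberg (via
`statsmodels.stats.multitest`), reported at 5% and 10%. The two analysis
series are corrected separately. A degenerate pairing (e.g. a single-ROI
network's empty intra edge set) is recorded with p = 1 and flagged rather
than dropped — silently shrinking the family would change every q-value.
Edges of significant pairings are reported where z strictly exceeds 2.5
and can be classified as left-intra / right-intra / inter-hemispheric.

## Synthetic cohorts

The generator emulates the target study design: two groups (16 and 19
subjects at full scale), two runs, three conditions in fixed block order
with per-condition volume counts 66/55/55 (run 1) and 54/44/44 (run 2) at
TR = 2 s. Per (subject, condition), data are multivariate normal with a
correlation matrix built from: `base_within = 0.20` inside networks and
`base_between = 0.05` across networks (typical magnitudes for task-fMRI
ROI correlations); optional mean effects (a delta added on one pairing's
edges for one group × condition); and idiosyncratic perturbations —
zero-mean Gaussian edge offsets with group-specific SD (default 0.05),
optionally elevated on chosen pairings.

Idiosyncratic perturbations are drawn once per (subject, condition) and
held fixed across runs: a stable subject trait that differs between
conditions. Both halves matter — run-stability is what the cross-run
median pooling assumes, and condition-dependence is what the
|semantic − pragmatic| statistic measures; a perturbation constant across
conditions would cancel there identically and the construct would be
vacuous. The deterministic structure (base levels plus mean effects) must
satisfy |r| < 1 or generation errors out; the random perturbation tails
are instead truncated at ±0.97, and the final matrix is repaired to
positive definiteness by iterated eigenvalue clipping (floor 1e-6) with
re-normalisation to unit diagonal.

Signals are temporally white by default. Distance correlation pairs time
points, so serial structure is unnecessary for functional validation; an
optional AR(1) coefficient exists to probe the subsampling estimator
under serial dependence. The generator does not model hemodynamics,
motion, physiological noise, spatial autocorrelation within networks, or
non-Gaussian tails — so passing validation demonstrates correctness of
the estimators and inference under the assumed covariance model, not
robustness to real fMRI artefacts.

## Validation studies and problem sizes

The standard self-checks (`connscreen.studies`) run complete
generate → estimate → screen experiments at desk scale:

- *Null p-value uniformity*: 200 independent null cohorts (2 networks ×
  3 ROIs, 5+5 subjects, 20 repetitions), KS test on the inter-pairing
  p-value, each design under its exchangeable permutation scheme.
- *FDR calibration*: 20 null cohorts at the scaled screen size
  (8 networks × 5 ROIs, 6+6 subjects, 200 permutations); mean proportion
  of 5%-FDR-significant pairings compared against 0.05 plus two
  Monte-Carlo SEs.
- *Parameter recovery*: the scaled 8-network atlas with the study's full
  group sizes (16+19). Group-by-condition plants delta = +0.3 on one
  inter pairing for ASD-semantic (50 repetitions, 200 permutations) and
  asks whether that pairing attains the family's minimum p.
  Idiosyncrasy plants a 3× perturbation SD (0.30 vs 0.10) on one pairing
  for ASD (100 repetitions, 1000 permutations — the q-value resolution
  of a 36-pairing family requires p below 0.1/36, beyond the reach of
  200 permutations) and asks for 10%-FDR significance with an ASD > TD
  contrast. Both demand ≥18/20 seeded successes.
- *Determinism*: the file-based pipeline run twice with one seed must
  produce byte-identical reports (timing fields are excluded from all
  reports for exactly this reason).

Repetition counts in these studies (20–100 instead of the full 100) and
the reduced bootstrap counts were chosen so the whole suite runs in
minutes on a single CPU; they only affect Monte-Carlo granularity, not
the logic under test.

## Known limitations

- The permutation scheme question (rows vs whole subjects) has no ground
  truth in the emulated design; both are implemented, and the default is
  the conservative one.
- Bootstrap ratios are an interpretation of loosely specified per-edge
  "z-scores"; they are the standard salience-stability statistic in
  task PLS, but other readings (e.g. standardised saliences) exist.
- Edge-level reporting (z > 2.5) is descriptive, not an error-controlled
  test; only the pairing-level FDR is inferential.
- The 0-based edge indexing follows atlas file order; results are only
  comparable across runs that used identical atlas files.
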