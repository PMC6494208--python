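# Methods

`numdecode` implements the group-analysis battery of a dyscalculia
neuroimaging study design: adults with developmental dyscalculia and
matched controls perform a number-comparison task (numerosities 2, 4, 6,
8 presented as Arabic digits or dot arrays) in a short-block fMRI
design, and group differences are probed with univariate ROI tests,
multivoxel pattern decoding, whole-cohort subject classification,
searchlight mapping, seed-based functional connectivity, and
tract-metric comparisons. Because no scan data ship with the package,
every stage is paired with a synthetic generator that reproduces the
statistical structure each analysis assumes; all empirical claims below
are the ones the test suite itself computes.

## Experimental design model

A run is modelled as 48 experimental blocks (8 conditions x 6 blocks)
and 7 fixation blocks. Boundary fixations last 8 s; the five interleaved
fixations follow every 8th experimental block. Block durations come from
{4, 5, 6} s. The generator balances durations so that each condition's
six blocks contain every duration twice (total 30 s per condition) and
chooses the interleaved-fixation multiset so the run lands exactly on
its 280-s target (24 s across the five blocks, e.g. 4+4+5+5+6); the
source text states only that durations were 4, 5 or 6 s, so the balanced
scheme is the minimal deterministic rule consistent with the printed
totals. Sampling is at TR = 3 s (93 volumes per run).

## Synthetic cohorts

`SyntheticCohortSpec` defaults encode the study conditions: 24 subjects
per group (dyscalculia / control), 10 runs each (the acquisition range
was 8-12). Three knobs carry the effects of interest:

* **separation** — per (group, format, region), the distance scale of
  condition prototypes in voxel space. Prototypes sit on a random
  orthonormal frame scaled by the separation, so each same-format pair
  of prototypes is exactly `separation * sqrt(2)` apart and pairwise
  distance is linear in the parameter (verified by regression in the
  tests). Defaults: symbolic 0.8 in both groups; non-symbolic 1.0
  (control) vs 0.5 (dyscalculia) — the qualitative effect structure the
  decoding pipeline targets (reduced non-symbolic pattern distinctness
  in dyscalculia, equal symbolic distinctness). With unit observation
  noise these values put single-subject within-format accuracies in the
  0.55-0.75 range, comparable to small-ROI decoding in practice.
* **noise_sd** — iid Gaussian noise added to each run's pattern
  (default 1.0).
* **connectivity_target** — per-group seed-by-seed correlation matrices
  for the time-course generator (Cholesky-factored Gaussian noise plus a
  shared HRF-convolved task component and random-walk motion).
  Defaults: background r = 0.2 among the 8 level-III seeds, with the
  PVC-IOC and PVC-FG edges at 0.6 in controls vs 0.3 in dyscalculia.

The generator deliberately omits several properties of real BOLD data:
spatial autocorrelation within ROIs, temporally autocorrelated (1/f)
noise, physiological confounds, inter-subject anatomical variability,
and any relation between univariate amplitude and pattern separation.
Passing calibration tests therefore demonstrate the *statistical
machinery* (no spurious effects under exchangeability, recovery of
planted effects), not performance on real scans.

## First-level model

Per run, each voxel is fit by OLS against 8 HRF-convolved condition
boxcars, one fixation regressor, six motion parameters, and an
intercept (16 columns). The HRF is the canonical double-gamma (peak 6 s,
undershoot 16 s, ratio 1/6), applied on a 0.1-s grid before TR
sampling. The decoding substrate is the per-run condition-minus-fixation
t-pattern, t = c'b / sqrt(s2 c'(X'X)^- c), df = volumes - rank(X). No
prewhitening or autoregressive noise model is applied; with white
synthetic noise OLS is exact, and on real data the t-patterns would
simply inherit the usual mild df optimism. Voxels with (relatively) zero
residual variance are flagged rather than returned as infinities.
Spatial smoothing of inputs is the caller's concern; the module is
smoothing-agnostic.

## ROI hierarchy and gated FDR

ROIs are anatomical masks intersected with supra-threshold localizer
activity (one-sided uncorrected p < 0.001 on the localizer t-map). The
tree has four levels — All Regions; 4 lobes; 11 regions; 4 IPS subparts
— and a node undefinable in at least 5 subjects is excluded outright
(the reading adopted for an ambiguous rule; with the three historically
undefinable occipito-parietal regions excluded, 8 level-III seeds
remain). Group tests descend the tree: the root is tested first
(two-sided two-sample t); within each level the *tested* nodes are
Benjamini-Hochberg corrected together, and a node is tested only when
its own parent survives at alpha. Correcting over tested nodes only
(rather than all nodes at the level) follows from the gating: closed
gates contribute no p-values. Gating is per-parent, so a significant
parent's children are testable even when a sibling parent fails.

## ROI decoding

Patterns are standardized per condition and run (subtract the mean
across voxels, divide by the *population* SD across voxels). For each
of the 28 condition pairs, runs are split 70/30 into training and test
100 times (split over runs — the unit that makes "averaged to one
response pattern per condition" well-defined; 70% is rounded to the
nearest run count keeping at least one test run). A C-SVC with C = 1
trains on the training runs' patterns; the test runs are averaged to
one pattern per condition and both are scored. The cell of the 8x8
matrix is the mean accuracy over repeats. Within-format summaries are
the plain means of the six symbolic and six non-symbolic pairs. Group
comparisons use two-sided pooled-variance t-tests fed into the gated
hierarchy; each group is also tested against chance (0.5) with a
one-sample t.

The classifier kernel deserves a note: the source description is
self-contradictory ("linear support vector machines" with "a radial
basis function kernel ... gamma set to 1" — the toolbox's defaults).
The default here is linear; `ClassifierSpec(kernel="rbf", gamma=1)`
reproduces the alternative for sensitivity analysis.

## Subject classification

Subjects are classified (dyscalculia vs control) from contrast-map
feature vectors with the same C-SVC under leave-one-pair-out CV: random
cross-group pairing, train on all but one pair, test on the pair, every
subject held out exactly once per repeat. Pairing randomness is averaged
over repeats (1000 in the full analysis; the stability tests show two
independent multi-repeat runs agree within 0.02). Significance is a
Monte-Carlo permutation test: each iteration draws one global label
permutation, applied coherently to the whole cohort (training and
scoring), and p = #{null >= observed} / N. The coherent global
relabelling is the exchangeable null; permuting training labels while
scoring against true labels was measured to be anti-conservative at
small n and is not used. The plain b/N estimator (which can return 0)
is the default for fidelity; `plus_one=True` gives the (b+1)/(N+1)
variant. Inside each permutation the LPOCV uses a configurable number
of pairings (default 20; the full 1000 x 1000 grid is not a desk-scale
computation).

## Searchlight

The stencil is every integer offset with squared norm <= r^2 (33 voxels
at the radius-2 default), defined in voxel units. At each in-mask
centre the in-mask stencil voxels form the feature set for pairwise
decoding, and the map holds the mean within-format accuracy. Maps are
smoothed with a mask-aware Gaussian (sigma = FWHM / 2.3548 per axis):
each in-mask source voxel's kernel mass is renormalised over its
in-mask support *before* convolution, which preserves the in-mask sum
(hence mean) exactly and spreads a delta into a kernel integrating to 1
within the mask. Group comparison subtracts chance, computes voxel-wise
two-sample t, and controls family-wise error by max-|t| permutation
over group relabelings (p_FWE = (1 + #{max-null >= |t|}) / (N + 1)) —
a self-contained exact-under-exchangeability substitute for parametric
random-field correction.

## Functional connectivity

Seed series preprocessing follows a fixed six-step order: (1) zero-phase
4th-order Butterworth band-pass at the nominal 0.01-0.2 Hz band;
(2) regression of motion parameters and their first derivatives;
(3) regression of white-matter/ventricle signals and derivatives
(generator-provided columns in synthetic mode); (4) regression of the
HRF-convolved task-vs-baseline regressor; (5) scrubbing of volumes with
framewise displacement > 0.5 mm (rotations converted on a 50-mm sphere;
flagged volume plus 1 back / 2 forward censored — the threshold and
adjacency rule are package defaults, configurable, not asserted as the
original study's); (6) spatial smoothing applies to volumetric mode
only and is skipped for ROI-averaged tables. One physical subtlety: at
TR = 3 s the Nyquist frequency is 0.167 Hz, so the nominal 0.2-Hz upper
edge is not realisable; the filter clips it to just below Nyquist with
a warning, making step (1) effectively a 0.01-Hz high-pass with a
gentle roll-off. Pearson matrices are Fisher r-to-z transformed
(diagonal excluded; |r| = 1 clamped at 1e-7 with a warning); per edge,
within-group one-sample t-tests (BH-FDR across edges at 0.001) and
between-group two-sample t-tests (BH-FDR at 0.05) are reported with
direction.

## Summary statistics

Cohort-matching measures are tested from printed summaries: pooled
two-sample t with df = n1 + n2 - 2, and Cohen's d with the equal-n
pooled SD sqrt((s1^2 + s2^2)/2) (numerically consistent with the
printed effect sizes). The behavioural 2x2 (group x format) ANOVA
treats the two formats of a subject as independent rows, reproducing
the printed df = (1, 92) layout for 48 subjects; this is a faithful
reproduction of the original convention, not the repeated-measures
model a fresh analysis would choose. DTI tract metrics (FA/MD/AD/RD)
are compared per tract with two-sample t-tests and BH-FDR across
tracts within each metric (an `--all-cells` style family is a one-line
change but the per-metric family is the default reading).

## Problem sizes and numerical choices

Calibration and power suites run on reduced problem sizes chosen as
this package's desk-scale study conditions: chance calibration uses a
50-subject null cohort (1 ROI, 16 voxels, 10 CV repeats); permutation
calibration uses 400 datasets of 4+4 subjects with 39 permutations and
3 LPOCV pairings each; effect recovery uses 50 cohorts of 12+12
subjects, two regions, 8 runs, 6 CV repeats, with non-symbolic
separation 1.2 vs 0.4 and symbolic 0.8 in both groups; the full
default pipeline keeps the study-scale 24+24 x 10-run cohort.
Tie-breaking in the SVC follows scikit-learn's deterministic decision
function; run splits, pairings and permutations all derive from
`numpy.random.Generator` seeded per call, so every table is
reproducible bit-for-bit from a config and a seed.

## Known limitations

* Real-data mode expects preprocessed, normalised inputs (NIfTI/TSV);
  no slice timing, realignment, normalisation, tensor estimation or
  tractography is performed.
* The generator's independence assumptions (white noise, orthonormal
  prototypes) make decoding easier per voxel than in real data; the
  separation parameters are calibrated to produce realistic accuracy
  ranges, not realistic voxel covariance.
* The permutation FWE for searchlight group maps assumes exchangeable
  subjects under the null (satisfied by the generator; approximately
  true for matched cohorts).
* The 2x2 ANOVA's independence convention and the permutation test's
  b/N estimator are reproduced as-is from the original conventions;
  both have better-behaved alternatives that are available behind
  flags or trivially derivable.
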