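# Methods

This note documents the models, defaults and numerical choices behind
`nback_ica`, and what the synthetic-data experiments do and do not show
about real data.

## Task model

The paradigm is a letter n-back with three load conditions (0-back,
1-back, 2-back), each presented in two blocks of 100 trials (600 trials
per run by default). A trial shows one consonant (18-letter set, no
Q/Y/J, random case) for 500 ms, followed by a blank inter-trial
interval drawn uniformly from 1.0–2.0 s. Targets occupy exactly half
of each block's trials: in 0-back the letter 'x', in n-back a letter
matching the one n trials earlier, case-insensitive. Non-target letters
are constrained never to satisfy the n-back rule accidentally, so the
target flags are the unique ground truth. Block order is
semi-randomized with each condition appearing once in each half of the
run. Blocks are separated by a rest/instruction period (default 20 s),
which is the implicit baseline the task regressors are contrasted
against. At TR = 2 s this yields roughly 200 scans per condition.
Events are modeled as 0.5 s boxcars at trial onsets; incorrect
responses are *not* excluded from the regressors, because the analysis
deliberately relates activation to performance.

## HRF basis and design matrix

The canonical HRF is the conventional double-gamma: gamma densities
with response delay 6 s and undershoot delay 16 s (unit dispersions),
undershoot ratio 1/6, 32 s support, peak-normalized. The temporal
derivative is the backward finite difference with respect to a 1 s
onset shift; the dispersion derivative is the finite difference with
respect to the peak dispersion parameter with increment 0.01. Both
increments are configurable; the finite-difference error is first
order (halving the increment halves the error against the analytic
gamma derivative, which the tests verify).

The design matrix holds 3 conditions × 3 bases, six motion parameters
and their first backward differences each convolved with the three
bases (46 columns with the constant). Convolving nuisance regressors
with the HRF bases is unusual; `convolve_motion=False` gives the
conventional unconvolved alternative (22 columns). All columns except
the constant are mean-centered. No high-pass filter is applied; slow
drift is left to the noise model and centering. The condition number
is reported and a warning is emitted above 1e6 — note that all-zero
motion columns make the design singular, so simulated motion should
always be non-degenerate when regression is the goal.

## Synthetic data generator

The generator is first-class, tested code; it defines the conditions
under which every downstream claim is demonstrated.

**Spatial sources.** Each network map is a signed dipole: a dominant
positive Gaussian core (σ = 1.5 voxels) and a 0.6-weight negative
satellite ~2.5σ away, unit-normalized. All lobes are packed jointly by
rejection sampling with a 3σ minimum separation, targeting pairwise
spatial correlation ≤ 0.15 (hard bound 0.3). The signed histogram
matters: purely nonnegative disjoint blobs are mis-specified for the
symmetric logistic infomax prior — on such sources the entangled
solution can have *higher* likelihood than the truth (and FastICA
fails the same way), so separation would be structurally unreliable.
Real IC z-maps are likewise signed.

**Temporal structure.** Each source carries a condition-amplitude
profile (the designated "working-memory" source increases with load:
0.5/1.0/1.5; the others cycle through flat, decreasing and mid-peak
profiles with a fixed per-source perturbation) plus per-subject
amplitude noise (SD 0.3). On top of the task modulation every source
fluctuates spontaneously: HRF-smoothed white noise with SD equal to
the mean task-regressor SD (`spontaneous_sd=1`). This ongoing,
task-independent covariation is the physiological basis of fMRI ICA,
and it is what makes networks with similar task profiles separable; at
`spontaneous_sd=0` the voxel data reduce exactly to the linear mixing
of amplitude-weighted regressors (the identity the unit tests check).

**Hemodynamics, noise, nuisance.** Each subject's HRF uses jittered
gamma delays (young SD 0.3 s, old × 2 — the motivation for the
derivative bases), clipped to [3, 9] s and [12, 20] s. Drift is three
low-order cosines with configurable amplitude (default 0.5); scan
noise is white Gaussian (default SD 1.0, which is roughly the mean
clean-signal SD in active voxels); motion is a smoothed 6-column
random walk. The default grid is 16 × 16 × 12 (3072 voxels): with
~10²-voxel supports, smaller grids leave too few effective spatial
samples for stable unmixing.

**Behavior.** Per subject and condition a mean RT and an accuracy
level are drawn from published group distributions (young/old,
0/1/2-back); trial RTs are lognormal around the subject level (within
CV 0.2), so the subject's median RT is the drawn level, and
correctness is Bernoulli. A 2% fraction of RTs is replaced by
out-of-range values (< 200 or > 1500 ms) to exercise filtering.
Old-group 2-back accuracy optionally includes
`coupling_strength × z(designated-source 2-back amplitude)`;
the generator raises if the coupling pushes accuracy out of (0, 1).
The coupling acts on 2-back only because the 0-back accuracy ceiling
(.94) leaves no additive headroom.

**Randomness.** All draws flow from one master seed through named
substreams (`substream(seed, stage, subject)`), so outputs are
bit-reproducible and independent across stages.

## Group ICA

Order can be estimated with the Wax–Kailath Gaussian MDL applied to the
eigenvalue spectrum of the temporal (scan × scan) covariance averaged
over subjects, with the scan count as the i.i.d. sample count;
zero eigenvalues are ridge-floored so exact-rank data yield the exact
rank. Reduction is two-stage PCA: per-subject temporal projection to
`k_subject` (default 1.5 × n_components, capped by the scan count and
the actual temporal rank), concatenation, group PCA to `k_group` with
whitening to unit sample variance applied only at the group stage —
whitening per subject would equalize noise and signal directions
before the group stage sees them.

Infomax is the natural-gradient Bell–Sejnowski update with logistic
nonlinearity and bias, identity initialization, initial learning rate
0.005/ln k, runica-style block size ⌈min(5 ln N, 0.3 N)⌉, annealing by
0.9 on oscillation (update angle > 60°) and a geometric decay of 0.97
per sweep after 64 full-rate sweeps. Convergence is a relative
weight-change norm below 1e-6 within 512 sweeps; non-convergence
raises, with the partial unmixing attached to the exception.

Stability follows ICASSO: n_runs (default 10) infomax runs with
distinct seeds, pooling of all component maps, average-linkage
clustering of 1 − |correlation| into n_components clusters, and per
cluster the centrotype (member with maximal summed within-cluster
similarity) plus the quality index Iq = mean within-cluster |r| −
mean between-cluster |r| (the pure within-cluster similarity is stored
separately). At least half the runs must converge.

Back-reconstruction applies the pseudo-inverse of the composed
(unmixing ∘ group reduction ∘ subject reduction) pipeline to each
subject's block; subject maps sum to the group maps, so their mean
matches the group map up to scale. Conventions: each map is flipped so
its largest-|value| voxel is positive, components are ordered by
back-projected time-course variance (descending), and stored maps and
time courses are z-scored after back-projection, at both group and
subject level. In practice two components beyond the planted source
count are estimated on noisy data so that drift and noise structure
have somewhere to go — over-extraction for artifact separation is
standard in this literature.

Component selection is template matching: each template picks the
component maximizing |spatial correlation|, below a 0.3 threshold it
is reported unmatched, and duplicate assignments raise unless an
override (or non-strict mode) resolves them. This is a programmatic
stand-in for the visual selection used with real data.

## Temporal regression and AUC

Component time courses (z-scored) are fit by OLS on the full design;
rank deficiency raises with the offending columns named. The three
per-condition betas collapse to AUC = (β₁Σh + β₂Σh' + β₃Σh_d)/Σh,
which is linear in each beta, equals β₁ exactly when the derivative
sums vanish, and is invariant to pure response-latency shifts (the
temporal derivative absorbs them). A latency *shape* change (e.g. a
longer gamma delay) changes the true response area, and the AUC
reports that faithfully — it is an area statistic, not a peak
statistic. Degenerate bases with nonpositive canonical sum are
rejected rather than sign-flipped.

## Behavior analysis

Filtering marks RTs < 200 ms or > 1500 ms (and non-responses) as
incorrect without changing trial counts; the bounds themselves are
valid. Accuracy is correct-and-in-range over all trials; the RT
summary is the median over correct in-range trials, undefined (and
flagged) when none exist. Cost indices require positive 0-back
denominators. The exclusion rule removes subjects below 50% accuracy
in the 1-back *or* the 2-back condition (strict inequality); the
conjunctive reading is available via `rule="both"`.

## Statistics

The mixed ANOVA (within: component, between: age group) is computed by
`pingouin.mixed_anova` with Greenhouse–Geisser correction reported
alongside uncorrected p-values; the tests verify it against an
independent cell-means sums-of-squares oracle to 1e-8. Two-sample
t-tests use pooled variance (the published residual dfs imply pooled),
one-sample t-tests are standard, and zero-variance cells are flagged
rather than silently propagated. Interaction regressions code age as
±1 then center (with unbalanced groups the centered codes are not
±1), z-score the predictor within group (sample SD), and fit by OLS
with the usual n − p − 1 residual df. Spearman correlations use
average ranks; the Fisher r-to-z comparison uses
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)) with a two-sided
normal p (the transform is approximate for Spearman rho, as in the
original analysis). No multiple-testing correction is applied by
default; Holm is available behind a flag. The full chain
(`analysis_report`) runs ANOVA → post-hoc t → interaction regressions
for cost outcomes → within-group per-condition regressions and
correlations → between-group correlation comparison, aborting with a
stage-labeled error on subject misalignment.

## What the synthetic experiments show — and what they do not

Monte-Carlo experiments use scaled-down problem sizes chosen for
statistical adequacy: source recovery uses 8 sources, 12 subjects and
a full-length run on the 16 × 16 × 12 grid; coupling detection uses
40 subjects per group, 100 trials per condition, 100 replicates for
power at a planted r = .5 and 500 replicates for the type-I rate.
Passing these shows that the implementation recovers what it plants
under its own generative assumptions: linear mixing, Gaussian noise,
cosine drift, spatially fixed maps, HRF variability limited to gamma
delays. Real fMRI adds spatial smoothing, physiological noise, motion
interactions, imperfect registration and non-stationary networks, none
of which are simulated; recovery numbers here are upper bounds on what
the same pipeline would achieve on real data, not predictions of it.

## Known limitations

- OLS without prewhitening: temporal autocorrelation is ignored, as in
  the analysis being replicated.
- The MDL order estimate assumes i.i.d. samples; smoothness of real
  data would require an effective-sample correction it does not have.
- GICA back-reconstruction is the pseudo-inverse (GICA1-style) path;
  dual regression is not the primary route.
- The Fisher z comparison applied to Spearman rho is approximate.
- Exact 50% targets per block is a testability choice; the original
  task randomized target placement at rate 0.5.
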