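# Methods

This note documents the models, numerical choices and synthetic-data design
behind `bwage`, and what the tests do and do not establish about real data.

## Connectome estimation

Regional time series (time × regions, sampling interval `tr` seconds) are
conditioned per scan: linear detrending; band-pass filtering with a
second-order Butterworth design applied forward–backward (`filtfilt`), so
the pass band (default 0.01–0.1 Hz) is preserved without phase lag — phase
lag would distort inter-regional correlations, which is why the zero-phase
form is used even though it squares the attenuation; optional scrubbing
(frames whose mean intensity deviates more than 3 SD from the scan mean, or
whose head position jumps more than 3 mm from the previous frame — the later
frame of the pair is flagged; the mean/SD are computed once, not
iteratively); nuisance regression by least squares on the retained frames,
with flagged frames replaced by the model interpolation (their residual is
zero, keeping residuals exactly orthogonal to the design); global signal
regression; normalization to zero mean and unit L2 norm. Scans are
concatenated and renormalized, correlated (for normalized columns the
correlation matrix is the Gram matrix), and stabilized with Oracle
Approximating Shrinkage.

OAS shrinks toward `(tr(C)/p)·I` with the closed-form intensity

    rho = [(1 − 2/p)·tr(C²) + tr²(C)] / [(n + 1 − 2/p)·(tr(C²) − tr²(C)/p)]

clipped to [0, 1], where `n` is the number of retained frames. Two
documented idiosyncrasies: shrinkage is applied to the *correlation* matrix
(the pipeline's convention, although the estimator was derived for
covariances), and the diagonal is reset to exactly 1 afterwards — the
target's diagonal is already 1 for a correlation input, so this only removes
rounding. The tests verify the "closer to the population correlations"
property in the estimator's own regime (weak structure, short scans); with
strong correlations at very small `n` the identity target over-shrinks, which
users should keep in mind when processing highly structured data.

Motion and tissue-component regressors require voxel-level data and are
accepted as caller-supplied columns; only the polynomial trend columns
(Legendre, orthogonal on the frame grid) are constructed here.

## Representations

Three interchangeable connectome representations feed the regressors:

* raw correlations;
* clipped Fisher z, `D = atanh(0.999·C)` elementwise — odd, strictly
  increasing, bounded by ±atanh(0.999) ≈ ±3.8, finite at |c| = 1;
* the Bures–Wasserstein log matrix. The general form around an SPD
  reference `B` is `E = (BC)^{1/2} + (CB)^{1/2} − 2B`, computed via the
  similarity identity `(BC)^{1/2} = B^{1/2}(B^{1/2} C B^{1/2})^{1/2} B^{−1/2}`
  so that every root is taken on a symmetric matrix, then symmetrized.
  With the identity reference the pipeline uses the convention
  `E = 2C^{1/2} − I`, which differs from the general form at `B = I` by the
  constant shift `+I` (irrelevant to regression) and has the exact inverse
  `C = ((E + I)/2)²`. Matrix square roots use symmetric eigendecomposition
  with eigenvalues floored at 1e−12; an eigenvalue below −1e−12 raises.

The BW representation is the pipeline default: the planted-signal
experiments confirm that a signal linear in BW space is recovered
substantially better from BW features than from raw correlations, whose
relation to the signal is only approximately linear.

## Compression and harmonization

Symmetric matrices are flattened to their upper triangle including the
diagonal (length `R(R+1)/2`; 70 876 at R = 376). The truncated SVD keeps the
smallest `k` leading right singular vectors whose squared singular values
reach a proportion `π` (default 0.999) of the squared Frobenius norm; ties
at the cut extend `k`; each basis vector's largest-magnitude entry is made
positive (sign convention), making the basis deterministic.

One consequence worth knowing: the energy threshold is computed on
*uncentered* rows, so the participant-mean connectome dominates the energy
budget. A predictive direction carrying less than `1 − π` of the energy can
be truncated away entirely — observable in the noise-free limit of the
synthetic generator, where the age direction holds <0.1% of the energy and
compression removes it. Real connectomes carry enough participant-level
variability that this regime is not reached, but `π` should not be lowered
carelessly.

Harmonization follows the ComBat family: per feature, a linear location
model with batch indicators and biological covariates (age, sex) is fit;
features are standardized by the pooled residual SD; per-batch location and
scale parameters are shrunk across features by parametric empirical Bayes
(normal prior on locations, moment-matched inverse-gamma prior on
variances, iterated to convergence) and removed; the covariate-explained
signal is restored. A non-EB fallback uses the raw per-batch moments (the
prior is uninformative with very few features). Degenerate features that the
design explains (near-)perfectly have their residual SD floored at 1e−8 of
the feature scale, collapsing them to the model prediction instead of
amplifying rounding noise. Fitting basis and harmonization on the full
table before the train/test split mirrors the pipeline's published order;
`HarmonizationModel.apply` supports a leakage-safe fit-on-train mode.

## Age regression and validation

Ridge regression solves `(X'X + λI)β = X'Y` on the ones-augmented design by
a linear solve; the intercept **is** penalized by default (the printed
normal-equations form), with the unpenalized variant available. At λ = 0 a
singular system falls back to the minimum-norm least-squares solution with
a warning (the λ grid includes 0). SVRs use the ε-insensitive loss
(ε = 0.1 years, fixed; the source protocol leaves it unstated) with linear
(primal solver) or RBF kernels; hyperparameters are stored as 1/C to match
the grids: λ ∈ {0, 10, 25, 50, 75, 100, 250, 500, 750, 1000, 2500, 5000},
linear-SVR 1/C ∈ {10, …, 1000}, RBF 1/C ∈ {0.001, …, 0.1}.

Validation is two-stage, run separately per sex. A seeded shuffle within
each study×sex cell sends the first `floor(0.10·n)` rows to the
parameter-setting set (this floor rule reproduces the published stratified
counts exactly: 1895/17070 men, 2144/19305 women at the full sample sizes).
Monte-Carlo CV (25 shuffled half/half splits, stratified by study — the
protocol source does not state whether its halves are stratified; stratified
is the default here, with a flag) scans the grids; the best hyperparameter
per model is the one minimizing the *mean* MAE over repeats (the summary
statistic is likewise unstated; the mean is used). Ten-fold study-stratified
CV then compares the frozen models; the RBF SVR trains on a random tenth of
each fold's training rows for tractability; every model sees identical
folds, so per-fold MAEs are paired and compared with two-sided Wilcoxon
signed-rank tests (exact null for n ≤ 25 without ties, normal approximation
otherwise, p = 1 for all-zero differences).

## Biomarker and audits

`δ = predicted − actual age` is residualized against
`δ* = β₁ + β₂·age + β₃·sex + β₄·age·sex` (OLS; sex terms dropped with a
warning for single-sex samples) and negated: `μ = −(δ − δ*)`, positive for
younger-looking brains. On the fitting sample μ is exactly uncorrelated
with age, sex and their interaction (OLS residual orthogonality) — the
age-association row of any report is a built-in null check. δ* is fitted on
the same sample whose μ is reported by default; a fit/apply split exists
for held-out scoring.

Associations are simple OLS fits `μ ~ const + x` on complete pairs (≥10),
reporting the raw coefficient α, adjusted R², the standardized coefficient
`β = α·sd(x)/sd(μ)` — equal to the Pearson correlation, which fixes which
SD ratio appears — its 95% CI (the α CI scaled by the same ratio) and the
coefficient p-value. Ordinal encodings (overall health 0–3, alcohol
frequency 0–5, processed-meat intake 0–5), the derived arterial stiffness
index (height / pulse propagation time) and abnormal-record filters
(education completed before 15, stiffness index above 3) are declarative
rules; encoding and exclusion commute.

Bias audits run per sex: Kruskal–Wallis H (with tie correction) across
group memberships — overlapping memberships contribute a participant once
per group and are flagged as non-independent; groups below a configurable
floor (default 7) are dropped with a warning — and Pearson correlations of
μ with neighborhood composition proportions, plus a majority-group
assignment (argmax, ties to the first declared group) re-fed to the H test.

## Interpretation

For linear models the weight vector (intercept excluded — it has no
connectome-space image) is projected through the SVD basis, unflattened and
mirrored into a symmetric direction `ℬ`. Around the mean BW connectome `𝒜`,
the covariance-space first-order effect of moving along `ℬ` is

    D(ℬ) = c_b·ℬ + (𝒜ℬ + ℬ𝒜)/4,

with `c_b = 1/2` by default: differentiating `C(𝒜 + δℬ) = ((𝒜 + δℬ + I)/2)²`
gives exactly `ℬ/2 + (𝒜ℬ + ℬ𝒜)/4 + O(δ)` (`(𝒜+I)/2` contributing the ℬ/2
term), and the finite-difference oracle in the tests confirms it to 1e−4.
The variant `c_b = 1` is kept selectable for comparison with reports using
that convention; the discrepancy is a factor on the ℬ term only. The
elementwise product `𝒜 ∘ D(ℬ)` separates connections reinforced by aging
(positive: positive correlations growing or anti-correlations deepening)
from weakening ones. Parcel-level matrices are block-averaged per
hemisphere into large atlas regions via a user-supplied grouping table
(22 regions for the HCP atlas; a toy grouping ships with the tests);
direction matrices are additionally normalized to unit SD of entries.

## Synthetic cohort design

The generator's defaults are the study conditions of the test suite.

* **Demographics** mirror the four-cohort sample the pipeline targets:
  per-study per-sex sizes and age moments (e.g. 211 men aged 58.54 ± 10.35
  in the smallest study; 17 787 men aged 64.38 ± 7.65 in the biobank arm;
  40 414 participants in total at scale 1, 47%/53% men/women). Ages are
  truncated-normal at zero (the exact redraw law). Scaled presets shrink
  every cell for fast tests.
* **Connectomes** are linear in BW space: `E_s = E_base + slope·(age −
  center)·direction + sex·sex_offset + site_offset`, mapped through the
  inverse BW transform, perturbed by Wishart-type noise (the sample
  covariance of `noise_df` normal draws from the target — SPD by
  construction, and exactly how real connectomes arise from finite scans),
  and renormalized to unit diagonal. Defaults: R = 20 regions, slope
  0.01/year (ages spanning ~50 years traverse ~0.5 Frobenius units, against
  sex/site offsets of 0.05), `noise_df = 200` (the effective frame count of
  a few minutes of scrubbed fMRI). The planted direction has zero diagonal
  and unit Frobenius norm, so the correlation renormalization perturbs it
  only at second order (measured distortion of the observed age-derivative
  direction: cosine 0.996 with the planted one).
* **Biomarkers**: `x = ρ·z(gap) + √(1−ρ²)·noise` plants exact population
  correlations with a known true age gap; missingness is completely at
  random.

What the generator does *not* emulate: voxel-level artifacts, motion
structure, heavy-tailed or non-stationary noise, age-dependent noise
levels, nonlinear aging trajectories, and realistic inter-feature biomarker
correlations. Passing tests therefore establish the pipeline's correctness
and its behaviour under the planted model, not performance claims about any
real cohort.

## Experiment design notes

* **Planted-signal recovery** (~4000 participants, R = 20): BW + ridge is
  compared on identical study-stratified folds against raw correlations and
  against the oracle 1-D regression on the participant's true-direction
  score. At these conditions BW + ridge lands within a few percent of the
  oracle and beats correlations on every fold. The recovered direction
  (projected ridge weights, minimum-norm OLS selected by the protocol)
  reaches cosine ≈ 0.87–0.94 with the planted direction depending on the
  seed — the residual is estimation variance from the low-variance tail of
  the compressed feature space; stronger ridge penalties raise the cosine
  but measurably worsen MAE, and the protocol selects by MAE.
* **Sample-size crossover**: a fixed design (a noisy linear channel that
  gives ridge a solid floor, a noisy squared channel exploitable only
  nonlinearly, 16 distractor dimensions) on which ridge is at least as good
  as the RBF SVR at n = 500 while the SVR wins clearly at n = 3000, with
  hyperparameters selected inside each training set by Monte-Carlo CV
  (5 repeats here, for runtime).
* **Harmonization**: planted per-site shifts of one within-site SD are
  reduced below 2% of the within-site SD, and feature-wise age slopes move
  by <1% relative to their pre-harmonization fits (the before/after
  comparison isolates what harmonization changes from shared OLS sampling
  noise).
* **Null calibration**: association p-values under independence are
  uniform (KS check over 500 replicates).

Problem sizes throughout (cohort scale 0.1, R = 20, 5–10 SVD-compressed
feature dimensions per hundred participants) are the package's chosen
desk-scale conditions; they keep the full suite within a couple of minutes
while leaving every statistical property measurable.

## Known limitations

* The OAS-on-correlations convention can over-shrink strongly structured
  connectomes at very short scan lengths (see above).
* The ε of the SVR loss and the harmonization EB priors are fixed
  conventions, not tuned per dataset.
* Interpretation operators assume a *linear* model in the chosen
  representation; RBF-SVR models are excluded by construction.
* The ethnicity-audit machinery treats overlapping group memberships as
  separate observations, matching its published usage but violating
  independence assumptions of the H test; results for heavily overlapping
  groupings are indicative only.
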