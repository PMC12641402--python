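# Methods

`dysconn` implements a normative-deviation analysis of resting-state
functional connectivity for a two-session intervention study, together with a
synthetic-data generator that makes every stage testable against known ground
truth. This note documents the models, the defaults and why they were chosen,
and what the synthetic data does and does not emulate.

## Dysconnectivity scoring (DCC / DCI)

For each hemisphere separately, region-by-region Pearson correlations of
cleaned BOLD series are Fisher-z transformed (`arctanh`, with |r| clipped at
1 − 1e−6 so every value is finite). A healthy reference cohort defines, per
connection, the normal location and scale of Fisher-z connectivity: the
across-subject mean μ and sample SD σ (SD floored at 1e−6 so the rule is
always defined). A subject's connection is *dysconnected* when its z value
deviates from μ beyond a threshold; per region, the count of incident
dysconnected connections is the DCC, and the DCC summed over a scope's
regions divided by the number of regions in the scope is the (specific) DCI.
Cross-hemisphere connections are never formed.

**Deviation threshold and calibration.** The nominal rule is a two-sided
k-SD deviation with k = 2 (configurable; always recorded in outputs). Because
μ and σ are estimated from a finite reference cohort, the naive plug-in rule
|z − μ̂| > k·σ̂ over-flags held-out healthy subjects: the predictive
distribution of (z − μ̂)/σ̂ is a scaled t, not a standard normal, so at
n = 40 reference subjects the realised false-flag rate is ≈ 0.0553 instead
of the nominal 2Φ(−2) ≈ 0.0455. The default `calibration="predictive"`
therefore flags when

    |z − μ̂| / (σ̂ · sqrt(1 + 1/n)) > t⁻¹(Φ(k); n − 1),

the standard prediction-interval treatment of reference-sample uncertainty in
normative modelling. This makes the held-out flag fraction equal to 2Φ(−k)
for Gaussian connectivity at any reference size (measured 0.0454 ± 0.0009
across seeds at n = 40) and converges to the plug-in rule as n grows.
`calibration="plugin"` retains the naive rule for comparison.

**Scopes.** Thirteen DCI outcomes are computed per subject, session and
hemisphere: whole brain; the eight canonical networks (visual, somatomotor,
limbic, frontoparietal, default-mode, dorsal-attention, salience,
subcortical), each as a within-network scope; connectivity within the
hippocampal formation; and three region-pair scopes (hippocampal formation ↔
prefrontal cortex, thalamus ↔ middle frontal gyrus, thalamus ↔ somatomotor).
For a scope with region sets A and B, the mask is restricted to connections
with one end in A and the other in B, and both the DCC and the region-count
normaliser use only the scope's own regions.

**Change maps.** Per region, DCC values are standardised across all
participants pooling both sessions, and the change score is standardised
baseline minus standardised follow-up — so a positive change means
dysconnectivity was *reduced*. The normalisation statistic (z-score, pooled
sessions) is a documented choice; the sign convention is stored in the
`ChangeMap` metadata. Note the two natural conventions (literal
"follow-up − baseline" vs "positive = reduction") conflict; this package
follows positive = reduction throughout, including the session-effect map.

## Quality control and preprocessing

tSNR per region is the temporal mean over the temporal SD (sample SD); a
zero-SD region is reported as +∞ and logged. Framewise displacement uses
backward differences of the six rigid-body parameters with rotations scaled
to millimetres on a 50 mm sphere. The default gates are mean tSNR > 100 and
mean FD < 0.3 mm. Cleaning order is: drop the first five frames → per-region
linear detrend → zero-phase (forward–backward) second-order Butterworth
band-pass, 0.01–0.08 Hz → per-region z-scoring. Zero-phase filtering is used
so correlations suffer no phase distortion; standardisation last guarantees
exactly unit-variance inputs to the correlation step (a no-op for Pearson r,
but convenient for downstream checks). No nuisance regression against tissue
signals is performed; the pipeline starts from cleaned region-by-time series.

## Longitudinal inference

Each DCI outcome is modelled with a linear mixed model fitted by REML
(statsmodels `MixedLM`):

    DCI_ijk = β0 + β1·Session_j + β2·Age_i + β3·Sex_i + β4·CPZ_i
              + β5·Trainings_i + β6·Group_i + β7·Hemisphere_k + γ_i + ε_ijk

with a random intercept γ_i per participant. Continuous covariates are
z-scored inside the fit for numerical conditioning (this changes their own
coefficients to per-SD units but leaves the session effect, its SE and
p-value untouched). Optimisation falls back bfgs → powell → nm because
boundary fits (γ variance → 0) can break a single optimizer's linear
algebra. A response with (near-)zero variance yields a degenerate zero fit
flagged `singular`. Session p-values are Wald-based.

Session p-values are corrected across the 13 outcomes by Benjamini–Hochberg
FDR (implemented directly as the step-up with enforced monotonicity).
Outcomes with q < 0.05 receive the post hoc session contrast — with two
sessions the Tukey family collapses to this single comparison — expressed as
Cohen's d = (session coefficient) / sqrt(random-intercept variance +
residual variance), i.e. standardised by the model-based total SD. The 95%
CI for d is a delta-method interval whose variance adds the classical
d²/(2(n−1)) standardiser term to the contrast's squared relative SE; a plain
rescaling of the contrast's t interval ignores the standardiser's sampling
error and measurably undercovers (≈ 87% vs the delta interval's ≈ 98% at
n = 12 in simulation).

Region-resolved analyses: the session-effect map fits, per region, the same
repeated-measures model on the DCC (session, age, sex, CPZ, trainings,
group; random intercept) and reports the negated session t-statistic so that
positive = reduction. Clinical-change regressions fit, per region and per
outcome (GAF, PANSS, cognition — all coded so positive change =
improvement), ordinary least squares of the clinical change on the region's
standardised DCC change controlling for age, sex and CPZ; β maps are
thresholded descriptively at unadjusted p < 0.05 (an FDR mode is available
through `fdr_bh` but is not the default, matching the descriptive intent of
such maps).

## Imaging transcriptomics

Statistical maps are parcellated by averaging member-region values and
centroids. Spatial specificity of map–gene associations is assessed against
variogram-matched surrogates: each surrogate permutes the parcel values,
smooths them with Gaussian distance kernels over a geometric grid of ten
candidate length scales (plus "no smoothing"), keeps the scale whose
variance-rescaled empirical variogram best matches the original's in least
squares, and rank-remaps the result to the original value multiset — so the
value distribution is preserved exactly. The variogram is evaluated over 25
equal-width bins covering only the closest 25% of parcel pairs: short
distances carry the autocorrelation signature, while the long-distance sill
is reproduced by any permutation and would otherwise dominate the fit
(calibration measured on independent smooth-field pairs: ≈ 4% rejections at
nominal 5%, versus ≈ 35% for the naive parametric p). Euclidean distance
between centroids stands in for geodesic distance — a documented limitation.
The per-gene statistic is the Spearman correlation between map and
expression; its two-sided spatial p is (1 + #{|ρ_surr| ≥ |ρ|}) / (n + 1),
never zero.

Cell-type enrichment is pre-ranked GSEA on the per-gene correlation vector:
genes ranked by ρ descending, weighted Kolmogorov–Smirnov running sum with
weight exponent 1, null ES from gene-label permutations (default 1000,
seeded, vectorised; the scalar running-sum implementation cross-checks it
and the ES agrees with gseapy's to machine precision). NES divides ES by the
mean |null ES| of matching sign; q-values follow the signed-NES pooled-null
convention of pre-ranked enrichment with monotonicity enforced within each
sign (Benjamini–Hochberg on nominal p is available via `fdr_method="bh"`).
A positive NES means the set's genes are more expressed where
dysconnectivity *fell* more. The leading-edge `hit_proportion` is the
fraction of set genes at or before (after, for negative ES) the running-sum
extremum.

## Synthetic data: what it emulates and what it does not

The generator draws BOLD-like series as stationary Gaussian frames with a
prescribed region-by-region correlation matrix (i.i.d. frames by default so
the connectivity oracle is closed-form; an AR(1) option gives the band-pass
filter something to remove). Defaults — 40 reference subjects, 12 patients
at two sessions, 60 regions per hemisphere, 300 frames at TR = 2 s — keep
every test minutes-scale while preserving hemisphere-wise structure.

Regions are allocated to the eight networks with unequal, literature-like
shares (default-mode largest at ~21%, limbic smallest; see
`NETWORK_PROPORTIONS`), mirroring the strongly unequal surface fractions of
standard 7-network cortical atlases, plus four small anatomical groups
(hippocampal formation, prefrontal, thalamus, middle frontal; at least two
regions each so every within-set scope has a connection). Coordinates place
each network as a compact cluster, mirrored across hemispheres, so
network-structured maps are spatially autocorrelated. The base covariance is
block-structured (within-network r = 0.3, between 0.05).

Each subject receives an individual population correlation matrix: the
correlation of a Wishart draw from the base covariance with
`subject_dof = 100` degrees of freedom, giving a per-connection Fisher-z
spread of ≈ 1/sqrt(dof − 3) ≈ 0.10 that is stable across the subject's
sessions (a trait, as real connectomes are). This between-subject
heterogeneity is essential: without it the reference SD is pure estimation
noise and *any* planted shift larger than a few hundredths of a z-unit stays
flagged forever, making attenuation undetectable. The value 100 was set from
threshold geometry — a 60%-attenuated 0.5-z shift must be able to re-enter
the 2σ normal range — and is a realism parameter, not a fitted one.

Planted effects shift the Fisher-z of target connections (a network's
within-network pairs, or explicit pairs) by `baseline_shift` at baseline and
by `(1 − attenuation)·baseline_shift` at follow-up, scaled per patient by a
susceptibility factor drawn from `subject_scale_range` (default 0.5–1.5),
then map back through `tanh` — so correlations stay in (−1, 1) by
construction; if entry-wise shifting breaks positive definiteness, the
matrix is repaired by eigenvalue clipping at 1e−8 (logged) and rescaled to
unit diagonal. Ground truth (`true_region_change`) records each region's
planted deviation reduction, and clinical change scores are generated as
strength-weighted sums of true network-level reductions plus noise, positive
= improvement. Gene expression plants one cell-type set as
`coupling·standardised(map) + noise`, all other genes pure noise.

Not emulated: haemodynamics, head motion (beyond an externally supplied
table), scanner artefacts, nuisance structure, geodesic cortical geometry,
donor-level transcriptomic aggregation, and any between-subject covariate
effects on connectivity (age, sex, CPZ, trainings and group are generated
independent of the planted effects, so they act as pure noise covariates).
Passing tests therefore demonstrate the *statistical machinery* —
calibration, recovery, sign conventions, null behaviour — not robustness to
the artefact structure of real MRI data.

## Known limitations and degenerate behaviour

- At desk scale, small scopes (e.g. a 4-region limbic network, 6
  within-network connections at a 4.5% flag rate) produce DCIs with only a
  handful of distinct values. Null session p-values for such scopes are
  conservative and lattice-valued (including exact-zero session contrasts,
  hence p = 1 atoms) rather than strictly uniform; with a continuous
  response the identical battery machinery is uniform. This is a
  consequence of scale, not of the inference code.
- Fixed effects use Wald inference (no Satterthwaite df in statsmodels);
  at 12 subjects this is mildly liberal for continuous responses.
- The surrogate engine targets the preservation property (value multiset
  exact, short-range variogram matched), not bit-compatibility with any
  published toolbox.
- A constant-response scope has undefined Cohen's d; `posthoc_session`
  raises rather than reporting 0/0.
- `generate_expression` with `noise_sd = 0` makes non-planted genes exactly
  constant; their correlations are reported as missing.
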