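# Methods

This note documents the models behind `facesd`: what each stage computes,
the assumptions it makes, what the synthetic-data generator does and does
not emulate, and the numerical and design choices that were genuinely open.

## Circular geometry

All stimulus arithmetic lives on a wheel of `n_points = 141` morphs (three
anchor identities 47 steps apart, 46 interpolated morphs per segment). The
signed circular distance from index *b* to index *a* is
`((a − b + n//2) mod n) − n//2`, the minimal displacement with clockwise =
increasing index. Odd `n` guarantees a unique shorter arc; even wheel sizes
are rejected rather than tie-broken because an antipodal pair has no signed
direction. Distance-range bins are close ±1–23, middle ±24–46, far ±47–69
(23 absolute distances each); |Δ| = 0 carries no direction and |Δ| ≥ 70 is
trimmed so the bins are even — both are excluded rather than assigned.

The wheel has no intrinsic orientation: mirroring it negates both Δ and the
adjustment error, which leaves the bias statistic unchanged. "Attractive"
is therefore well defined without fixing which direction is clockwise.

## Bias statistic and its sign

`m = median(error | Δ>0) − median(error | Δ<0)` per participant ×
visibility × bin. A pure attraction toward the inducer produces positive
errors on clockwise-inducer trials and negative on counterclockwise ones,
so this orientation makes attraction positive and repulsion negative. The
verbal description of the subtraction could be read in either order; the
package fixes the order by the attraction-positive contract and exposes
`bias_sign_convention="ccw_minus_cw"` for the mirrored reading (which flips
every sign and nothing else). Cells missing one direction have undefined
bias; they are dropped, and because the within-subject F test needs a
complete design, a participant missing any cell is excluded from the ANOVA
(never imputed).

## Exclusions

Reaction times above 15 s (strict) and absolute errors above 60 morph steps
(strict) mark off-task trials; together with the |Δ| trims they are flagged,
never deleted, and reported per reason. Under the default generator the
performance-based exclusions run at ≈3% of trials (2.5% slow-tail RT
contamination plus gross errors from lapses).

## Aligned rank transform (ART) ANOVA

For each effect, responses are aligned — residuals from the full-factorial
cell means plus that effect's own inclusion–exclusion estimate — then
ranked across the whole table (average ranks on ties), and the classical
fully-within-subjects F test for that effect is run on the ranks: each
effect is tested against its own effect-by-subject interaction, giving
F(df_eff, df_eff·(n−1)) (e.g. F(2, 54) for the distance-range effect at
n = 28). One aligned-rank pass per effect; any number of within factors is
supported (the topographic ANOVA uses three). A design with constant
responses is degenerate and rejected. Simulation shows the test is
calibrated: type-I error per effect within [0.04, 0.05] at α = .05 over 500
null-generator replications (and matches `pingouin.rm_anova` exactly on
Gaussian data).

Bayes factors per effect use the BIC approximation
`BF10 = exp((BIC_null − BIC_full)/2)` on least-squares fits with fixed
participant intercepts; the null is the matched model without the effect
(interactions keep their main effects). Closed-form and deterministic; a
random-intercept mixed model was rejected because its variance estimate
sits on the zero boundary for a sizable fraction of simulated datasets,
making the fit fragile. Bayes factors are computed on the raw (not
rank-transformed) responses.

Group confidence intervals are percentile bootstrap over participants
(5,000 resamples, 95%). At n = 28 the percentile interval's true coverage
is ≈93.6% — the familiar small-sample narrowness of percentile intervals —
which the calibration sweep makes visible rather than hiding.

## Synthetic data generator

**Design.** 28 participants × 8 blocks × 24 trials (5,376 trials), exactly
half of each block at low visibility, both faces uniform independent draws
from the wheel (uniform sampling is an assumption; the design's random
selection is not otherwise specified).

**Responses.** error = `pull(Δ) · scale_p` + Gaussian noise (σ = 8 steps),
rounded and wrapped; 2% lapses respond uniformly; RTs are log-normal
(median 2.5 s, σ = 0.5) with a 2.5% slow-tail contamination uniform on
16–60 s so the 15 s filter has work to do. `pull` is odd in Δ: per-bin
constants by default, with a derivative-of-Gaussian curve available. The
bias statistic recovers ≈ 2 × pull, so the default pulls
{close −1.5, middle +0.5, far +1.25} target group biases of roughly
−3 / +1 / +2.5 morph steps — a close-repulsive / far-attractive pattern of
realistic magnitude. `scale_p ~ N(1, 0.5)` is a per-participant
multiplicative random effect. Noise is unwrapped Gaussian; at σ ≤ 15 wrap
events are negligible and the median-based statistic is robust to them.

**EEG.** Epochs on the 31-channel extended 10-20 set plus two mastoids
(−200…1200 ms at 512 Hz, linked-mastoid reference, µV). Each trial is a sum
of Gaussian-windowed component templates — N170-like (170 ms, −4 µV,
bilateral parieto-occipital), N250-like (280 ms, −3 µV, same topography),
LPP-like (500 ms, +5 µV, centroparietal) — with topography weights falling
off as a Gaussian of scalp distance on an idealized spherical montage
(exact left/right symmetry; azimuthal equidistant projection, ear-ring
radius 1, Cz at the origin; mastoids at the TP9/TP10 sites). The LPP
amplitude receives an additive per-bin delta, {−1, 0, +1} µV for
close/middle/far by default: attenuation after a similar inducer,
amplification after a dissimilar one. Noise is white Gaussian (σ = 10 µV
per channel) mixed across neighboring channels by a row-normalized Gaussian
kernel; 1/f temporal coloring is available but off by default (the
permutation machinery's calibration is distribution-free, so white noise is
the simpler reference).

**Brain–behavior coupling.** With `coupling > 0`, one standard-normal
latent z per participant scales both modalities, with separate gains: the
bias pulls by `1 + coupling·z` (default gain 2) and the LPP deltas by
`1 + coupling_erp·z` (default gain 1). The two gains are deliberately
unequal: the group-level ERP effect size is `d ≈ μ/σ ≈ 1/coupling_erp`, so
a gain near 1 yields cluster effect sizes around 0.9–1, while the larger
behavioral gain carries enough shared variance for a latent-driven
correlation of ≈0.6 between the far−middle difference scores (regression
R² in the 0.3–0.4 range). A single shared gain cannot produce both: gain 2
on the ERP side halves the cluster d, gain 1 on the behavioral side starves
the regression. The behavioral gain of 2 also reproduces a realistic
between-participant spread of the per-bin bias (95% CIs several morph steps
wide at n = 28); a side effect is that the distance-range ANOVA, which
tests against the effect-by-subject stratum this heterogeneity inflates,
has only moderate power under the coupled generator. Without coupling the
two modalities draw independent random effects.

**What the generator does not emulate:** biophysical sources (no dipole
forward model), ocular/muscle artifacts (the pipeline ingests clean
epochs), 1/f background by default, stimulus-image content (faces are wheel
indices), and any dependence of behavior on the EEG beyond the shared
latent. Passing tests therefore demonstrate that the *statistics* behave
as specified under the design's sampling structure, not that the generator
reproduces real EEG.

## Cluster-based permutation tests

Per (channel, sample), a paired t across participants; samples beyond the
two-tailed critical value at α = .05 (df = n−1) are clustered by temporal
adjacency within channels and spatial adjacency across channels at the same
sample; cluster statistic = summed t. The null records the maximum absolute
cluster sum over 10,000 random within-participant sign flips of the
condition difference; Monte Carlo p = (1 + #{null ≥ |observed|}) / (n_perm
+ 1), with ties counted as exceedances under a 10⁻⁸ relative tolerance
(exact ties occur for the identity and global-flip permutations and float
round-off would otherwise silently drop them — visible at small n against
an exhaustive-enumeration oracle). Positive and negative clusters are
evaluated separately against the same max-|statistic| null (two-tailed).
Zero-variance samples are excluded from clustering with a warning.

Spatial adjacency links channels closer than 0.55 of the head radius on the
2D montage (~5 neighbors per channel, comparable to a toolbox neighbor
template); the graph is validated connected. ROI tests treat the four ROI
channels as fully adjacent and cluster per channel over time
(`roi_mode="average"` clusters the ROI-averaged signal instead). Cohen's d
for a cluster is mean/SD over participants of the difference averaged over
the cluster's members; the per-cluster Bayes factor is the JZS paired BF of
the same quantities.

Calibration: the any-cluster false-positive rate of the ROI test under the
null generator is ≈0.05 (measured 0.052 over 500 replications at 1,000
permutations), and at n = 5 the Monte Carlo p matches exhaustive 2⁵
sign-flip enumeration within binomial error.

## Topography

Window-mean LPP difference amplitudes (far−middle, close−middle) on 18
representative channels are vector-scaled jointly over all analyzed
channels (per-region scaling is a config switch), then averaged into
region × hemisphere cells (averaging keeps the design balanced despite
unequal set sizes — the centroparietal set deliberately lists CP5 without
CP6, and the resulting left-heavy cell is kept as specified) and submitted
to a contrast × region × hemisphere ART ANOVA. Scaling makes the analysis
invariant to any positive per-participant, per-contrast gain, so a
contrast × region interaction indicates different topographic *shapes*,
not different strengths.

## Robust regression and Bayes factors

IRLS with Huber loss, c = 1.345 (95% Gaussian efficiency; Tukey bisquare
available), via iterative reweighting to convergence. The slope is tested
with F = (b/se)² on (1, n−2) df — reported in the standard order (regressor
df first). R² is computed from the robust weights (the plain version is
also reported); as c → ∞ the fit reproduces OLS exactly. The JZS paired
Bayes factor integrates the noncentral-t likelihood over a Cauchy(0, √2/2)
effect-size prior by adaptive quadrature; it is symmetric in t, below 1 at
t = 0, strictly increasing in |t|, and agrees with dense-grid integration
to four significant digits.

## Problem sizes in the validation sweeps

The calibration and recovery studies in `facesd.validation` run the public
pipeline at reduced sizes chosen to keep a full sweep in the minutes range:
ART calibration at 96 trials/participant (500 replications); cluster-test
calibration at 12 participants × 48 trials on an 8-channel, 128 Hz model
(500 replications, 1,000 permutations); LPP power at 28 × 96 trials on the
same reduced ERP model; regression power at the full 192 trials/participant
(the behavioral difference score is trial-limited, so cutting trials would
understate the design's power) with the reduced ERP model. The acceptance
script runs the headline replication at the full design size (28 × 192,
33 channels, 512 Hz, 10,000 permutations for ROI tests; the all-channel
exploratory scan uses 2,000 permutations).

## Known limitations

* The percentile bootstrap undercovers slightly at n = 28 (≈93.6% for a
  nominal 95%); BCa or t intervals would close the gap but are not what the
  analysis specifies.
* The BIC Bayes factors condition on fixed participant intercepts; they
  approximate, not implement, full JZS ANOVA priors.
* The ART ANOVA tests each effect against its own subject-interaction
  stratum; analyses that pool the residual instead will print much larger
  denominator dfs for the same data.
* The generator's coupling latent scales *all* bias pulls jointly, so under
  coupling both the far and the close contrast correlate with the LPP; it
  does not emulate a selective attraction-only linkage.
* Upstream continuous-EEG preprocessing (0.1 Hz high-pass, downsampling,
  ICA, artifact rejection, channel interpolation) is an input contract, not
  part of the package.
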