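# Methods

This note documents the models implemented in `voxtune`, the defaults they
ship with, the numerical choices behind the sampler, what the synthetic
generators do and do not emulate, and the package's known limitations.

## Encoding model

Orientation lives on a circle of period 180°; all circular computation uses
the doubled-angle convention (orientations doubled, radians on [0, 2π)).
User-facing interfaces take degrees on [0, 180); values outside are reduced
modulo 180 with a warning.

The circular Normal density f(r | φ, κ) = exp(κ cos(r − φ)) / (2π I₀(κ))
is used twice: as the shape of single-neuron tuning curves (location 0,
concentration κ₂, embedded affinely as NTF(r) = α + γ f), and as the
*weight distribution* describing the relative contribution of neurons with
each preferred orientation to a voxel's signal (location φ, concentration
κ₁). Averaging neural curves under the weight distribution yields the
voxel tuning function VTF(r) = α_v + γ_v f(r | φ_v, κ_v). The voxel
concentration κ_v blends κ₁ and κ₂ and is deliberately kept a *free*
parameter: the data cannot and need not disentangle whether sharp voxel
tuning comes from sharp neurons or a sharp weight distribution.

Numerical notes:

* densities are computed with the exponentially scaled Bessel function
  (`scipy.special.i0e`), stable for large κ;
* κ = 0 is handled analytically (uniform density 1/(2π));
* `NeuralPopulation` realizes the conceptual neuron-to-voxel convolution as
  a discrete quadrature over a configurable preference grid (default 180
  points). It accepts either shared parametric tuning or an arbitrary
  tuning-curve callable, which is how the slope test's generality
  (any shape, any weight vector) is exercised numerically.

Two exact identities follow from linearity of the aggregation and are
enforced by property tests: a neural additive shift Δ shifts the voxel
curve by exactly Δ, and a neural gain g maps the voxel curve to
α + g·(curve − α), for arbitrary (including bimodal) weight vectors.

## Synthetic data

`ExperimentDesign` defaults mirror the emulated study structure: 18 runs,
8 equally spaced orientations, two contrast conditions (baseline listed
first), two presentations per (orientation × contrast) per run. Responses
emulate GLM beta weights in percent-signal-change units; raw BOLD time
series and HRF convolution are deliberately out of scope.

Noise is Normal per observation with voxel-specific σ_v, because
run-to-run variability differs across voxels. Voxel parameters are drawn
hierarchically: for each of α_v, log γ_v, log κ_v, log σ_v and log g_v
(or a_v), a population mean μ ~ Normal(loc, scale) and spread
τ ~ Half-Normal(tau_scale), then θ_v ~ Normal(μ, τ); φ_v is uniform on the
circle and unpooled. Positive parameters are log-normal across voxels —
one consistent normal-hierarchy form that the sampler also exploits.

Two prior regimes are shipped:

| hyperprior (loc, scale, tau_scale) | `default()` | `recovery_default()` |
|---|---|---|
| α (psc) | (0.5, 0.5, 0.3) | (1.0, 0.3, 0.25) |
| log γ | (log 0.5, 0.5, 0.4) | (0, 0.3, 0.25) |
| log κ | (log 0.5, 0.7, 0.5) | (log 2, 0.3, 0.3) |
| log σ | (log 0.4, 0.3, 0.25) | (log 0.3, 0.2, 0.2) |
| log g | (0, 0.3, 0.2) | (log 1.5, 0.2, 0.15) |
| a (psc) | (0, 0.3, 0.2) | (0.35, 0.15, 0.1) |

`default()` emulates the study regime: mostly weakly tuned voxels (median
κ_v = 0.5), moderate noise. `recovery_default()` is the regime used for
data-uninformed model recovery: clearly tuned voxels with modulation well
away from the null, reflecting that weakly informative priors produce
distinctly "signed" datasets for each generating family. Units: α, γ, σ,
a in percent signal change; κ and g dimensionless.

`mixed_population_params` builds the flat-dominated population used to
reproduce the failure mode of across-voxel averaging: 90% exactly untuned
voxels, a tuned minority with broad tuning (κ_v = 1), shared γ_v = 1,
gain 1.5 (or shift 0.25), σ_v = 0.3 — a caricature of real data in which
most voxels respond almost equally to all orientations.

What the generators do **not** emulate: temporal autocorrelation, run- or
session-level shared noise, heteroscedasticity across conditions, partial
voluming, vascular artifacts, or nonlinear neurovascular coupling. Passing
tests therefore show that the *methods* behave as designed under the
assumed observation model, not that real fMRI data satisfy that model.

## Hierarchical Bayesian estimation

Both model families share the likelihood y ~ Normal(VTF(r), σ_v), one row
per GLM beta. Voxel-level parameters (α_v, log γ_v, log κ_v, φ_v,
log g_v or a_v, log σ_v) are pooled through the Normal hierarchies above;
the hierarchy is population → voxel, with participants sharing the
population level.

Posteriors are approximated by an adaptive Metropolis-within-Gibbs sampler
written for this model's structure (no general-purpose gradient-based PPL
is used):

1. **Voxel blocks.** Given hyperparameters, voxels are conditionally
   independent, so all voxels are updated simultaneously with vectorized
   accept/reject. Each iteration makes one random-walk proposal per
   coordinate (scales adapted per voxel toward 0.44 acceptance during
   warmup, frozen afterwards) plus one joint 6-dimensional proposal along
   the per-voxel empirical covariance accumulated over the later part of
   warmup (Haario-style, global scale adapted toward 0.28). The joint step
   is what handles the strong α–γ and γ–g posterior correlations of weakly
   tuned voxels. φ_v proposals are wrapped on the circle (symmetric, hence
   valid MH).
2. **Hyperparameters.** Population means are conjugate Gibbs draws; scales
   τ get scalar MH steps on log τ. Two interweaving moves per pooled
   coordinate complete the scheme: a joint (μ, log τ) proposal holding the
   standardized effects η_v = (θ_v − μ)/τ fixed, and a τ-only variant with
   larger multiplicative jumps. These non-centered moves are what defeat
   the funnel that otherwise traps chains at small τ when a coordinate is
   weakly identified at the voxel level.
3. **Sufficient statistics.** The Gaussian likelihood is evaluated through
   per-cell (orientation × condition) counts, means and within-cell sums
   of squares, making each proposal O(voxels × cells) regardless of trial
   count. Pointwise per-observation log-likelihoods are evaluated only for
   stored draws.

Chains are independent with seeds spawned from the user seed; initial
states are drawn from the prior (overdispersed). Defaults mirror the
emulated study's sampler settings — 4 chains, 1000 adaptation iterations,
2000 stored draws per chain — and are reduced for tests and the
acceptance script via `draws` and `thin` (the sampler runs `draws × thin`
post-warmup iterations and keeps every `thin`-th).

Convergence is assessed with rank-normalized split R-hat (arviz) for every
parameter, with φ_v monitored through sin φ and cos φ: a posterior
concentrated near the 0/2π seam is unimodal in those components but
spuriously bimodal in the raw angle. Parameters with zero variance across
all chains yield NaN R-hat, reported with a warning and a failing verdict.
Because the sampler is random-walk based, Hamiltonian divergences cannot
occur; the report's divergence count instead records draws whose log
posterior is non-finite (zero in normal operation) and the verdict keeps
the conventional rule: pass iff max R-hat < 1.1 and no divergent draws.

Design choices made where the design was genuinely open:

* *Centered base parameterization with interweaved non-centered moves*
  rather than a purely non-centered model: the centered form admits
  conjugate mean updates and conditionally independent voxel blocks, and
  the interweaving moves supply the funnel-crossing behavior non-centering
  would otherwise provide.
* *φ_v sampled directly on the circle* (wrapped random walk) rather than
  through an embedded unit vector; simpler, and valid because the proposal
  is symmetric.
* *Baseline-condition mapping*: contrast labels are ordered by a helper
  preferring conventional baseline names ("low", "baseline", ...), always
  overridable. Which condition is baseline is an arbitrary labeling choice,
  but it must be consistent between generation and fitting for parameter
  comparisons to be meaningful.

## Model comparison and recovery

PSIS-LOO elpd and Pareto-k diagnostics come from `arviz.loo` applied to
the stored pointwise log-likelihood matrix. Two models fitted to the same
observations are compared through the *paired* pointwise elpd differences;
the difference's SE is √(n · var(dᵢ)) and a model is "favored" when
|Δelpd| ≥ 1.65 SE (configurable). The per-dataset "selected" model is
simply the one with higher elpd.

Model recovery fits both families to datasets generated from each family
and tallies how often comparison selects the generator. Data-uninformed
mode draws generating parameters from `recovery_default()` priors;
data-informed mode resamples joint posterior draws from fitted models.
Non-converged fits flag their dataset, which is excluded from the accuracy
tally with a logged warning (excluded counts are reported). Desk-scale
defaults are 5 datasets per family, 20 voxels, 6 runs, with re-fits at
2 chains / 1000 warmup / 400 draws thinned by 8; the emulated study's
scale (100 datasets per family, 100–200 voxels, 18 runs) is reachable
through the same interfaces.

## Orthogonal-regression slope check

Per voxel, responses are averaged within (run, orientation, contrast)
cells, then matched across contrast conditions on (run, orientation);
unmatched cells are dropped with a count (this is how sessions measured on
a different orientation grid fall out naturally). The TLS slope is the
closed form g = [−(S_xx − S_yy) + √((S_xx − S_yy)² + 4 S_xy²)] / (2 S_xy).
Tie-breaks at S_xy = 0 follow the principal covariance axis: slope 0 if
S_xx > S_yy, vertical (angle 90°) if S_yy > S_xx, and a degenerate flag
for isotropic or zero-variance clouds — an isotropic cloud genuinely
carries no slope information. Angles live on [0, 180) with 45° = identity
line; negative slopes map to (90°, 180°). The population summary is the
median angle across non-degenerate voxels with a 10,000-replicate
percentile bootstrap CI; degenerate voxels are excluded with a count.

## Binning estimator

The conventional average-voxel-tuning display: z-score each voxel across
all its rows; for each held-out run estimate the voxel's preferred
orientation as the argmax of mean response over the remaining runs
(averaged over contrasts, ties to the lowest orientation); re-index the
held-out run's responses by signed circular distance from that preference
(range (−90°, +90°]); repeat for every run; average per-voxel cell means
across voxels. Confidence intervals are repeated-measures: within-voxel
centering plus the √(M/(M−1)) small-sample correction for M cells
(the Morey-corrected variant of the Cousineau procedure), treating
contrast and distance as within-voxel factors and ignoring participants.
Voxels lacking a contrast condition or measured on a non-modal orientation
set are excluded with a count.

The package intentionally reproduces this estimator's failure mode: on a
multiplicative population dominated by untuned voxels the aligned
high−low difference curve is nearly constant — indistinguishable from an
additive shift — while the per-voxel slope test on the same data still
shows median angles above 45°.

## Kohonen orientation maps

A 67 × 67 grid of model neurons with uniform-random initial preferences is
trained for 20,000 iterations. Each iteration presents a uniform-random
orientation; the neuron with the circularly nearest preference wins (ties
to the lowest index); every neuron moves toward the stimulus by
[ψ(d_j, σ_i)/ψ(0, σ_i)] · δ_i, where ψ is the Normal(0, σ) density, d_j
the Euclidean grid distance to the winner (adjacent spacing 0.03), δ_i the
signed circular orientation difference (period 180°, range (−90°, 90°]),
and σ_i = 0.06 · ((20000 − i + 1)/20000). Preferences are wrapped to
[0, 180°) after every update.

Per-voxel weight distributions are summarized by equal-width circular
histograms, a von Mises MLE on doubled angles (closed-form mean direction;
concentration by root-finding on I₁/I₀, capped at 500 and flagged for
degenerate samples), and a 99% flat-distribution reference band obtained
by Monte-Carlo multinomial simulation (per-bin count quantiles under a
uniform preference distribution). Map smoothness is quantified by mean
local circular dispersion over adjacent neuron pairs; pinwheel counting is
not implemented. The simulation is a proof of concept: it ignores
vasculature, cortical folding, pinwheel-density variability and partial
voluming.

## pRF retention

A voxel's population receptive field is an isotropic Gaussian with center
(x, y) and SD σ in degrees of visual angle. With an annular stimulus
(defaults 1.2° inner, 7° outer radius), a voxel is retained iff in *every*
session the circle of radius 2σ around its pRF center is contained in the
annulus: e − 2σ ≥ inner and e + 2σ ≤ outer, with e = √(x² + y²).
Containment is closed (exact tangency retains). pRF model *fitting* and
the variance-explained gating that precedes it are upstream of this
package's scope; the module consumes final parameters only.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run everything at desk scale,
as the package's own default study sizes for self-checks: slope
signatures and the TLS oracle in seconds; model recovery with 5 datasets
per family × 20 voxels × 6 runs; sampler convergence on one 20-voxel
dataset with 4 chains, 1500 warmup and 500 stored draws (thinned by 12);
gain-recovery coverage on 20 low-noise voxels; the binning failure mode on
400 voxels × 18 runs. The emulated study's full scale is reachable through
the same configuration objects.

## Known limitations

* The observation model is iid Normal noise around the tuning curve;
  deviations common in real fMRI (see above) are not modeled.
* Only the gain and shift modulation families are implemented; bandwidth
  changes and preference shifts are natural extension points of
  `HierarchicalModelSpec` but are not part of the candidate set here.
* The sampler is random-walk based: robust and dependency-free, but slower
  per effective sample than gradient-based HMC; paper-scale hierarchies
  (200 voxels × 6 participants) are feasible but take correspondingly
  longer.
* A hierarchical Bayesian model *of the slopes* (as opposed to the
  bootstrap summary) is not implemented; the bootstrap median is the
  shipped summary.
* The Kohonen module makes no claim of biological realism beyond producing
  smooth maps with mostly flat, occasionally unimodal voxel-level weight
  distributions.
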