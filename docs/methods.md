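# Methods

## Detection histories

A station's captures are pooled into occasions of `occasion_days`
(default 6) trap-days. Windows are anchored to each station's own
deployment start by default — the field design deploys stations on
different dates, and per-station anchoring keeps every occasion an exact
block of that station's effort; a common `calendar_anchor` date is
available when stations should share columns. Occasion o covers
deployment days `o·d+1 … (o+1)·d`; an entry is 1 if the species was
captured at least once in the window (multiple captures collapse to one
detection), 0 if the station was active without a capture, and NA if the
station had no active day in the window. Trailing partial windows with at
least one active day are kept as valid occasions: dropping them would
discard detections, and per-site effort differences are exactly what the
NA coding exists to express. When two species' matrices are aligned into
a pair, the missing pattern is unified (missing in either → missing in
both) so both likelihood contributions always range over the same
occasions. Clock times are used as-is (no solar-time correction; nothing
in the sampling design anchors activity to sun events), mapped to
radians as 2π·(seconds since midnight)/86400.

## Two-species occupancy

The conditional parameterization (dominant A, subordinate B) puts all
interaction at the occupancy level: ψA, ψBA, ψBa plus per-occasion
detection pA, pB. Detection is species-independent by default because the
interaction of interest is spatial; a conditional-detection variant
(rA, rBA, rBa at sites where both species are present, with B's
probability split by whether A was detected on the same occasion) is a
flag for users who suspect behavioural interference at the camera itself.
The SIF is computed per posterior draw as ψBA/ψB and summarized like any
other parameter, rather than given its own prior — it is a deterministic
function of the occupancy parameters, and deriving it keeps the prior
exactly Uniform(0,1)⁵.

Fitting uses data augmentation: given the latent z field every parameter
has a Beta full conditional under the uniform prior, and given the
parameters each site's (zA, zB) has a closed-form conditional (sites with
a detection are pinned to z = 1). This makes the sampler exact,
tuning-free and fast (all site updates vectorized). Defaults are 3 chains
× 1,000 kept iterations after 10,000 burn-in, one master seed spawning a
deterministic substream per chain. Convergence is summarized by the
classic split-chain Gelman–Rubin statistic with a 1.1 alarm threshold —
the rank-normalized variant would also be defensible, but the classic
form is transparent and directly testable against its definition.
Uncertainty is reported as the 95% highest-density interval (shortest
interval containing ⌈0.95·n⌉ sorted draws); with 3,000 kept draws its
endpoints carry Monte-Carlo noise of a few hundredths, which is why the
SIF verdict is phrased as "HDI excludes 1" rather than a p-value.

Degenerate inputs: an all-missing pair is an error; a species never
detected anywhere triggers a warning (its ψ, p posteriors are
prior-driven). The maximum-likelihood cross-check optimizes the
marginal log-likelihood on the logit scale (L-BFGS-B) and flags
boundary-drifting solutions (|logit| > 8) as non-converged instead of
clipping silently. Habitat covariates are deliberately out of scope: the
model is the interaction-only parameterization.

## Activity overlap

Each species' diel density is a von Mises kernel mixture over its capture
angles. The kernel concentration uses the circular plug-in rule: the ML
concentration κ̂ from the mean resultant length, converted to the
asymptotically optimal smoothing concentration
ν = (3n κ̂² I₂(2κ̂) / (4√π I₀(κ̂)²))^{2/5}, then multiplied by `adjust`
(default 0.8 for Δ1, the small-sample convention of the activity-overlap
literature; here larger `adjust` means a more concentrated kernel).
Densities are evaluated on a 128-point uniform grid (the periodic
rectangle rule is spectrally accurate; refining to 512 points moves Δ1 by
< 0.005 in tests) and renormalized to integrate to exactly 1. Δ1 is the
grid integral of the pointwise minimum. A κ floor of 0.05·adjust keeps
the kernel proper for flat samples.

Known limitation: the resultant-length plug-in under-smooths nothing but
*over*-smooths strongly bimodal patterns (two antipodal activity peaks
nearly cancel in the resultant, driving κ̂ toward the floor), so sharply
crepuscular species get flatter estimated densities than a
mixture-of-peaks fit would give. Overlap values remain well-behaved
because both densities integrate to 1. Records are not thinned for
temporal independence by default — individuals are unmarked, so any
interval rule is a guess — but `thin_by_interval` provides an optional
minutes-apart filter.

## Diet

FO is 100·n/N per prey with multi-prey scats counting toward every prey
they contain (so FO columns may sum past 100%). Bootstrap CIs resample
whole scats with replacement at the original N, 10,000 times, and apply
the bias-corrected (BC, not BCa — no acceleration term) percentile
method: z₀ = Φ⁻¹(fraction of bootstrap values below the point estimate),
interval endpoints at the Φ(2z₀ ± z_{0.025}) bootstrap quantiles. Prey in
every scat or no scat get a degenerate interval at the estimate. Relative
biomass re-weights FO by the predator-specific biomass-per-scat
regression (snow leopard Y = 1.980 + 0.035X; wolf Y = 0.439 + 0.008X;
common leopard Y = 2.171 − 1.671·e^{−0.056X}) and normalizes to 100%.
Prey mean body masses are user configuration; the shipped
`prey_masses_example.yaml` is illustrative/synthetic, so relative-biomass
outputs from it are demonstrations, not reproductions. Pianka's index is
computed on FO-based proportions by default (evaluating it on the bundled
greater-Himalaya FO columns reproduces the published felid overlap,
0.754 → 0.75); a biomass-based variant is a matter of passing the biomass
column instead. For the trans-Himalayan pair the same FO-based
evaluation gives 0.886 against a published 0.8 — neither FO- nor
biomass-based evaluation reproduces that figure, and the table is loaded
as printed rather than adjusted. Seasonal diet splits are not computed
(scat sample sizes do not support them); all scats are pooled per
predator.

## Synthetic data

The generators are the models' generative twins: occupancy data follow
the exact conditional two-species process (with missing station-occasions
placed jointly in both matrices, matching the unified-missing invariant);
activity times come from von Mises mixtures (κ = 0 components are
uniform); scats draw one primary prey from a multinomial profile plus,
with probability `multi_prob`, a second distinct prey by renormalized
draw. Defaults describe a realistic single-season survey: 50 stations
(the study's seasons ranged 43–66), K = 10 six-day occasions, ψA = 0.5,
ψBA = 0.3 / ψBa = 0.6 (an avoiding subordinate, SIF ≈ 0.67), detection
0.4, 10% missingness, 32 scats per predator, crepuscular two-peak
activity. What they deliberately do not emulate: spatial autocorrelation
between neighbouring stations, detection heterogeneity across stations,
individual movement, and seasonal drift within a deployment — so passing
recovery tests demonstrates correctness of the estimators under the
models' own assumptions, not robustness to their violation. One master
seed spawns named substreams per block (occupancy/activity/diet), so any
block regenerates independently and identical specs are bit-identical.

## Problem sizes in the test suite

Recovery and coverage checks use sizes chosen to make their tolerances
meaningful at interactive runtimes: SIF recovery uses 20 replicate
200-station surveys at the full 3 × (10,000 + 1,000) schedule;
Gibbs-vs-quadrature agreement uses a 2-site, K = 2 fixture with 4 × 25,000
kept draws against a 24-node Gauss–Legendre integration of the
five-parameter posterior; bootstrap coverage uses 500 replicate 32-scat
datasets with 2,000 resamples each. The consistency check for the ML fit
uses 1,000 sites.
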