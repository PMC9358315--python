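# Methods

`facetempo` quantifies how graded facial signals vary with social
context in a group-living primate. Its inputs are three observational
streams: FACS-coded communicative bouts (timed action-unit activation
intervals with low/high grades and gaze annotation), decided dominance
interactions, and affiliation/proximity/effort records. Its outputs are
per-bout intensity and variability scores, dyadic social covariates
(dominance-rating difference, composite sociality index), and a
mixed-model analysis of how the scores depend on the covariates.

## Bout-level metrics

**Gaze inclusion rule.** Only movement produced while the signaller is
looking at the receiver — or is in body contact with the receiver and
not looking at a second individual — is analysed. Events are clipped to
the union of qualifying gaze segments; unannotated time is conservatively
non-qualifying. Bouts with no qualifying graded-AU time are flagged
`excluded` and carried through so run reports can account for them.

**Intensity.** Four AUs are graded low/high (AU10 upper lip raiser,
AU12 lip corner puller, AU26 jaw drop, EAU3 ear flattener); AU27 (jaw
stretch) is an ungraded exaggerated AU26 and is counted as high-grade
jaw-drop time:

    intensity = (H10 + H12 + H26 + H_EAU3 + T27) / (T10 + T12 + T26 + T_EAU3 + T27)

with `Hn` the high-grade time and `Tn` the total active time of AU *n*,
summed over repeated activations. The ratio is dimensionless in [0, 1]
and is defined for every valid bout (each bout must contain at least one
of these AUs).

**Unpredictable variability** is the number of changes in AU
combination plus the number of changes in grade of the four graded AUs,
divided by clip length in seconds. The implementation first partitions
movement time into maximal constant-configuration *face states*
(active non-RDAD AUs plus their grades); transitions between temporally
contiguous states are counted — a transition differing in combination
counts once as a combination change even if grades also changed, and
entries into/exits from neutral are not counted (both choices are
configurable; the definition concerns changes *between* coded
configurations). Oscillatory displays (RDADs: AD181 lipsmack, AD182
teeth chatter, AD183 tongue chatter, AD184 jaw wobble) do not define
face states; otherwise a 2 Hz lipsmack would masquerade as dozens of
combination changes per second and the two variability components would
be conflated by construction.

**Predictable variability** is the fraction of movement frames (any
facial movement active, at the clip frame rate, default 25 fps) during
which at least one RDAD is active, times 2 to approximate the ~2 Hz
cycle rate of these displays; overlapping RDADs are unioned. The
denominator asymmetry between the two components — clip seconds versus
movement frames — is part of the metric definitions and is deliberately
kept, not "fixed". Total variability is the sum of the two components.

## Social covariates

**Elo ratings.** Sequential updates through the dominance record in
date order (same-date records keep file order): the winner gains
`k·(1 − p_win)` and the loser loses the same, with the standard logistic
expectation `p_win = 1/(1 + 10^((E_loser − E_winner)/400))` (a
normal-CDF variant is available via config). Defaults: initial rating
1000, k = 50, same-sex interactions only — inter-sexual conflicts are
won by males without exception in this species, so they carry no rank
information within the update scheme. Raw updates are exactly zero-sum
within each same-sex pool. Female ratings are then recalibrated per
group by `E_new = E_old·(M_min − 1)/F_max`, placing the top female one
point below the lowest-ranked male while preserving female order. The
signed covariate is `Elo_signaller − Elo_receiver` on the recalibrated
scale, computed once over the whole observation window (a single stable
hierarchy is assumed; no per-date rating series is kept).

**Composite sociality index.** Four dyadic affiliation measures —
grooming frequency, grooming duration, within-1 m proximity, and
affiliative-contact frequency — are each divided by the dyad's combined
focal hours (sampling-effort correction; proximity can alternatively be
corrected by scan count) and then by the group-wide mean of the
corrected measure over all dyads. The CSI is the mean of the four
ratios, so 1 is an averagely bonded dyad and the group mean CSI is
exactly 1 whenever all four components are informative; a component with
a zero group mean is dropped for all dyads with a warning.

## Mixed-model stage

One row per analysable bout: dependent variables `log_intensity`
(natural log of intensity + ε, because intensity can be exactly 0;
ε defaults to half the smallest positive intensity observed and is
configurable) and `variability` (untransformed). Fixed effects: outcome
(affiliation/aggression/copulation/submission/unknown), signaller-first
sex combination (FF/FM/MF/MM), CSI, and the Elo difference entered
linearly and as a raw squared column (the quadratic term lets intensity
peak between closely matched opponents). Elo differences are divided by
1000 before entering the model so the quadratic coefficient is O(1).
Random intercept per signaller; maximum likelihood throughout, since
AICc comparisons span fixed-effect structures.

The default candidate set is the null model plus the main-effects model
crossed with every subset of the five admissible two-way interactions
(outcome×CSI, outcome×Elo, sex×CSI, sex×Elo, CSI×Elo) — 33 models. The
outcome×sex interaction is structurally forbidden (crossing a 5-level
and a 4-level factor over a few hundred bouts produces degenerate
cells). Any externally defined candidate list can be supplied as YAML
and is used verbatim. Selection minimises AICc
(`−2ℓ + 2k + 2k(k+1)/(n−k−1)`, k counting fixed effects plus the two
variance parameters); ties break toward fewer parameters then formula
order. The selected model is compared to the null by a likelihood-ratio
test.

Fitting is delegated to `statsmodels.MixedLM`. Satterthwaite degrees of
freedom and estimated marginal means are computed by the package itself:
for a single random intercept the marginal covariance is
`σ²I + τ²ZZ'`, and for a contrast `l` the df are
`2(l'C(θ)l)² / (g'Ag)` where `C(θ)` is the GLS fixed-effects covariance,
`g` its finite-difference gradient in `θ = (σ², τ²)`, and `A` the
inverse observed information of the profiled ML likelihood (also by
finite differences; step 10⁻⁴ relative, variances floored at 10⁻¹²).
When the information matrix is degenerate — typically when τ̂² sits on
its zero boundary — the residual df `n − p` are used instead. Pairwise
contrasts are differences of estimated marginal means over a balanced
factor grid with covariates at their observed means, with Tukey
adjustment via the studentized range on `|t|·√2`. The whole chain
(estimates, SEs, dfs, Tukey p-values, ML log-likelihood) is tested
against R's lme4/lmerTest/emmeans on a fixture.

Non-converging candidates are flagged and excluded from selection with
a warning; with rich interaction structures on modest simulated data a
few such fits are expected and harmless.

## Synthetic data

The generator emulates two multi-male multi-female groups (defaults:
5 males + 10 females each, 30 individuals, 400 bouts) with:

* latent dominance scores strictly ordered within sex and all males
  above all females; decided interactions follow a logistic
  win-probability in the score difference (steepness 4 at 0.5 score
  spacing ⇒ ~0.88 for adjacent ranks), ~12 per same-sex dyad over a
  one-year window; cross-sex interactions always won by the male;
* gamma-distributed dyadic bond strengths driving Poisson counts of
  grooms (lognormal durations), contacts and within-1 m scans,
  proportional to combined focal hours; effort hours heterogeneous
  (uniform 20–80 h) so the effort correction is exercised;
* per-bout latent intensity
  `exp(log(context mean) + β_q z² + u_signaller + noise)` clamped to
  [0.02, 0.98], with z the standardized dominance difference,
  `β_q = −1.4`, signaller SD 0.15 and noise SD 0.10 on the log scale;
  context means 0.25 (affiliation), 0.50/0.45/0.55
  (aggression/copulation/submission), 0.35 (unknown);
* unpredictable variability as a context rate (0.65 changes/s for
  affiliation — elevated by +0.2 — and 0.45 elsewhere, noise SD 0.15)
  and predictable variability as context-dependent RDAD episodes
  (probability 0.5/0.4/0.3 in affiliation/submission/copulation, 0.2
  unknown, 0.05 aggression; covered fraction Beta(2,2)).

Realisation inverts the metric definitions exactly on the frame grid:
the graded-AU high fraction equals the latent intensity (adjusted when
an AU27 span is injected), level/configuration switches are laid down
so the change count matches the latent rate, and the RDAD span covers
the implied frame fraction. A face with zero changes cannot carry a
fractional intensity (grades would be constant), so a planted change
count of zero is bumped to one in that case. Realised post-rounding
values are emitted as ground truth; with noise off the pipeline
recovers them exactly, and latent targets to ~1/fps. Occasional
non-qualifying gaze pads containing a decoy movement exercise the gaze
filter without disturbing the planted values. Everything is
deterministic given the master seed (sub-seeds via `SeedSequence`).

What the generator does **not** emulate: sequential display grammar,
receiver responses, repeated bouts within dyads with temporal
autocorrelation, observation-quality loss (the 1545→506→364-style
attrition of field video), or coder disagreement. Passing recovery
tests therefore demonstrates correctness of the estimators under the
assumed generative structure, not robustness to field-data pathologies.

## Problem sizes used in checks

The seeded recovery study uses 100 datasets at the default conditions
(400 bouts, 30 signallers) with a reduced candidate set (null + main
effects + two interaction subsets, 5 models) — selection behaviour is
exercised while keeping the study a quick desk-scale computation; the
type-I-error study uses 1000 replicates of a null-vs-one-factor pair
(n = 120, 30 signallers). The rasterisation cross-check runs 1000
random bouts against a per-tick brute-force oracle. Reproduction of the
published field-data analysis requires the deposited 364-interaction
table at `data/supplementary/analysis_table.csv`; the corresponding
checks report how to supply it when it is absent.

## Known limitations

* Satterthwaite df are implemented for the single-random-intercept
  structure the analysis uses; nested or crossed random effects are out
  of scope (the field analysis found them unsupportable anyway).
* AICc counts variance parameters in k; software differs on this
  convention, which shifts all candidates equally and cannot change the
  selected model, but absolute AICc values may differ from other tools.
* The CSI's group denominators are grand means over all dyads of the
  group roster; rosters with many never-observed dyads shrink the
  denominators and inflate ratios for observed dyads.
* `elo_difference_squared` is a raw squared column, not an orthogonal
  polynomial; with centering off (default) the linear and quadratic
  terms are correlated, as in the published analysis.
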