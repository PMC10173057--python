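# Methods

This note documents the statistical models implemented in `guildniche`,
the defaults chosen where the methodology literature leaves a choice open,
and what the synthetic-data tests do and do not demonstrate.

## Detection histories

Raw camera records are thinned to *independent detections* with a sliding
half-hour rule: within each (station, species) stream a record is kept iff
at least 30 minutes (configurable) passed since the last *kept* record. The
window is anchored to the last retained record rather than to fixed clock
half-hours; this is standard camera-trap practice and makes the filter
idempotent. The same filtered records feed the detection histories, RAI and
activity samples, so all axes of the analysis share one notion of an
independent capture.

Weekly histories are deployment-relative: occasion k covers deployment days
[7(k−1), 7k). A trailing partial occasion with ≥1 active day counts as
sampled — discarding it would waste up to six days of effort per station,
and the default detection model is occasion-length-free anyway. Occasions
beyond a station's deployment are missing (NaN), and the matrix width is the
maximum occasion count over stations. Timestamps are naive local clock time;
no solar-time correction is applied.

## Multispecies occupancy

The latent state z ∈ {0,1}^S is multivariate Bernoulli with log-linear
potentials ν(z) = Σ z_s f_s + Σ z_s z_t f_st and ν(0) = 0; ψ(z) is the
softmax of ν over the 2^S states, computed with max-subtraction. This
anchored log-linear normalization is the standard identifiable choice for
the pairwise-interaction occupancy framework. Third- and higher-order terms
are fixed at zero.

The observed-data likelihood marginalizes all 2^S states per site:
states with z_s = 0 contribute only when species s was never detected there
(implemented as a −10¹⁰ log-penalty, numerically exact zero weight while
keeping the linear algebra finite). Sites with entirely missing histories
for a species contribute a unit detection product (empty index set) and
still inform the other species.

Estimation: multi-start L-BFGS-B on the negative log-likelihood (first
start at 0, then N(0, 0.5) jitter; default 10 starts, objective tolerance
1e-10) with numerically estimated gradients. The 2^S-state likelihood can
be multimodal at small n, hence the jittered restarts. Standard errors come
from the inverse of a central-finite-difference Hessian; when it is not
positive definite the fit is returned with SEs flagged unavailable rather
than failing. Printed summaries star slope coefficients at the 10% (\*) and
5% (\*\*) levels.

Covariate preparation standardizes to z-scores with the sample (n−1)
standard deviation and greedily drops covariates correlated |r| > 0.4 with
an earlier-retained one (input order decides survivors). Each natural
parameter takes an intercept plus at most two covariates. Detection is
constant per species by default; an optional site-level covariate (e.g.
trap-nights) on logit(p) is supported.

Model comparison uses AICc = −2ℓ + 2K + 2K(K+1)/(n−K−1) with n = sites, and
Akaike weights; candidates within 2 AICc of the best (inclusive) are flagged
supported. The CLI implements a two-step workflow: per-species
single-covariate selection first, then multispecies candidates restricted to
the step-1 winners, always including the all-intercept null. The candidate
builder is configurable rather than hard-coded to any fixed enumeration.

Conditional occupancy P(z_a = 1 | z_b) marginalizes all remaining species
from ψ. Interval estimates are a parametric bootstrap — coefficients drawn
from N(θ̂, V̂) and the conditional probability recomputed per draw — and are
labelled confidence intervals.

**Caveat at survey scale.** With ~97 stations, 5 occasions and detection
probabilities of 0.1–0.2, the full four-species model is weakly identified:
rare species (a handful of occupied sites) push natural parameters toward
the boundary and the Hessian degenerates. This mirrors the wide interval
estimates typical of field studies at this scale. Parameter-recovery claims
are therefore made at a "large" design (500 sites, 8 occasions, p = 0.5),
where the suite verifies that generating parameters fall within ±3 SE of
estimates in ≥95% of 100 replicates and that the median absolute intercept
bias stays below 0.15.

## Temporal overlap

Clock times map to radians (midnight → 0). Densities are von Mises kernel
mixtures with the Taylor-type rule-of-thumb plug-in concentration
κ_RT = [3 n κ̂² I₂(2κ̂) / (4√π I₁(κ̂)²)]^{2/5}, κ̂ the ML von Mises
concentration of the sample; the ratio of Bessel functions is evaluated with
exponentially scaled forms so tight activity clusters do not overflow. The
kernel concentration is multiplied by 0.8 for Δ̂₁ and 1.0 for Δ̂₄, following
the recommendations of the estimator literature; both are configurable.

Δ̂₁ integrates min(f̂, ĝ) by the trapezoid rule on a 128-interval grid
(integration error far below the 1-decimal reporting precision); Δ̂₄ is the
density-ratio estimator ½[mean min(1, ĝ/f̂) at x + mean min(1, f̂/ĝ) at y].
`estimator="auto"` uses Δ̂₁ when the smaller sample has < 50 records, Δ̂₄
otherwise. Confidence intervals are smoothed-bootstrap percentiles
(resampling from the fitted kernel density, 999 replicates, 2.5/97.5
percentiles), deterministic given a seed. Species with fewer than 10
independent records in a site group are gated out and rendered "−". Overlap
is computed per site group by default, not pooled.

## Spatial and dietary overlap

Pianka's index is implemented in its standard form
O_jk = Σ p_ij p_ik / √(Σ p_ij² Σ p_ik²); it is symmetric, scale-invariant
and bounded in [0,1] by Cauchy–Schwarz (all three property-tested).

Spatial overlap treats each camera station as an independent resource
category with per-station RAI as the use measure. The ≥10-captures gate
applies per species per site group. CIs resample stations with replacement
(percentile method, 999 replicates); replicates that drop one species
entirely are discarded.

Dietary overlap uses relative frequency of occurrence,
RF_i = 100 · c_i / Σc with an item-occurrence denominator (a scat holding
several items contributes several occurrences). The resource basis is the
16 itemized food categories — including plant material, plastic/paper and
unidentified — never the wild/domestic/others aggregate rows, which exist
only to validate the packaged table (each itemized group must sum to its
printed aggregate within ±0.3, a rounding allowance). This itemized
convention reproduces six of the seven published pairwise overlaps at
1-decimal rounding. The seventh (Kibber snow leopard–red fox) computes to
≈0.47 → 0.5 from the printed table under every category convention we
tested, against a published 0.4; it is documented here as non-reproducing
and excluded from the regression set. Dog diet is absent from the packaged
table (dropped in the source study for limited samples).

## Synthetic-data generator

The default scenario mirrors the target study design: 97 stations in three
groups (15 Chandratal / 39 Kibber / 43 Pin), 35/35/32-day deployments,
four predators with weekly detection probabilities {dog 0.1, red fox 0.5,
snow leopard 0.2, wolf 0.2}, first-order intercepts giving marginal
occupancies near the reported naïve values, interaction signs as reported
(fox–snow leopard positive, all other pairs negative), covariate effects on
the reported best predictors (fox/snow leopard ~ distance-to-road, wolf ~
elevation, dog ~ prey rate), diurnal dog / nocturnal fox / crepuscular apex
activity densities, and scat compositions resembling the published
Chandratal columns. Covariates are drawn standard-normal with a
configurable correlation matrix (identity by default).

Detection occasions are Bernoulli(p) per occupied site-week; each detected
occasion emits exactly one timestamped record on a uniformly chosen active
day with a within-day time from the species' von Mises mixture. Detection
timing is independent of occupancy covariates (no joint model is assumed).
This design makes simulate → filter → re-bin an exact identity, which the
suite asserts; it also means the generator does **not** emulate bursts of
near-duplicate photographs, within-occasion multiple visits, camera
failures mid-deployment, or spatial autocorrelation between stations.
Passing tests therefore validate the estimators under the stated model, not
robustness to those real-data features.

All generators are bit-reproducible given (seed, parameters); the composite
`simulate_study` derives per-stage seeds from one master seed.

## Problem sizes used in the test suite

Likelihood correctness is verified exactly (1e-10) against brute-force
latent-state enumeration at S ∈ {2,3} on 8–10 sites. Parameter recovery
runs 100 replicates at 500 sites × 8 occasions (3 optimizer starts per fit
— the intercept-only 5-parameter surface is unimodal in practice at that
n). Temporal-overlap accuracy is checked at n = 2000 (tolerance 0.05
against exact numeric integration) and n = 5000 (0.03); bootstrap checks
use 99–999 replicates. These sizes were chosen as the smallest designs
where the corresponding statistical claims are stable across seeds.

## Known limitations

- Likelihood evaluation enumerates all 2^S states; practical for guilds
  (S ≤ ~6), not for large communities.
- No Bayesian fitting, no spatial autocorrelation corrections, no
  third-order interactions, no multi-season dynamics.
- Occupancy at the ~1-km² station spacing of the motivating design should
  be read as "space use", not abundance or range, for wide-ranging species.
- The temporal axis uses clock time; no sunrise/sunset anchoring.
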