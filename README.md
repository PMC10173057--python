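# guildniche

Tools for analysing intra-guild carnivore interactions from camera-trap and
scat data: multispecies occupancy modelling with pairwise species
interactions, temporal activity overlap from circular kernel densities, and
spatial/dietary niche overlap via Pianka's index. Built for studies of small
predator guilds (e.g. snow leopard, Himalayan wolf, red fox and free-ranging
dog in trans-Himalayan cold-desert landscapes), where all four species are
detected imperfectly and at low rates.

## The models

**Multispecies occupancy.** The latent presence/absence state of S species at
site *i* is a vector z ∈ {0,1}^S with a multivariate Bernoulli distribution
parameterised by log-linear potentials ("natural parameters"):

    ν(z) = Σ_s z_s f_s + Σ_{s<t} z_s z_t f_st,   ψ(z) = e^{ν(z)} / Σ_{z'} e^{ν(z')}

First-order f_s are single-species log odds; second-order f_st are pairwise
co-occurrence log odds (third and higher orders are fixed at 0). Every f can
be a linear function of standardized site covariates. Detection is imperfect:
given occupancy, species s is recorded in a weekly occasion with probability
p_s (logit link), and the likelihood marginalizes the 2^S latent states per
site. Fitting is multi-start maximum likelihood; model selection uses AICc
and Akaike weights, with a two-step workflow (single-species covariate
selection, then multispecies candidates).

**Temporal overlap.** Detection clock times are mapped to the circle and
smoothed with a von Mises kernel (rule-of-thumb concentration). The overlap
coefficient Δ = ∫ min(f̂, ĝ) ranges from 0 (no shared activity) to 1
(identical activity); estimators Δ̂₁ (grid integration, small samples) and
Δ̂₄ (density-ratio, large samples) carry smoothed-bootstrap percentile CIs
(999 replicates by default). Species with fewer than 10 independent records
are gated out.

**Spatial and dietary overlap.** Pianka's index
O_jk = Σ_i p_ij p_ik / √(Σ p_ij² Σ p_ik²) is computed over camera stations
(using per-station trap success, RAI = detections per 100 camera-days) for
spatial overlap, and over itemized scat food categories (relative frequency
of occurrence, RF%) for dietary overlap. A published three-site scat RF
table for the focal guild ships as a checksum-verified fixture.

A forward simulator (`guildniche.synthetic_data`) generates complete studies
— covariates, correlated latent states, weekly histories, timestamped
records with species-specific diel activity, multinomial scat compositions —
with known truth, so every stage is testable end to end.

## Worked example

Dietary overlap from the packaged scat table:

```python
from guildniche import load_table4_fixture
from guildniche.diet import profiles_from_table, diet_overlap

profiles = profiles_from_table(load_table4_fixture())
res = diet_overlap(profiles[("chandratal", "snow_leopard")],
                   profiles[("chandratal", "wolf")])
print(f"snow leopard vs wolf (Chandratal): O = {res.value:.3f}")
# snow leopard vs wolf (Chandratal): O = 0.894
```

The two apex predators overlap strongly in diet (O ≈ 0.9, driven by shared
livestock use: yak/cattle and goat are top items for both).

A pairwise occupancy fit on a simulated 97-station study:

```python
from guildniche.synthetic_data import simulate_study
from guildniche import occupancy

truth, cov, states, hists, recs, scats = simulate_study(seed=1)
pair = ("red_fox", "snow_leopard")
spec = occupancy.NaturalParameterSpec.intercept_only(pair)
res = occupancy.fit({s: hists[s] for s in pair}, None, spec, n_starts=5, seed=0)
print(res.summary().round(2))
psi = res.psi_at(None)
print(round(psi.conditional("red_fox", "snow_leopard", 1), 2),
      round(psi.conditional("red_fox", "snow_leopard", 0), 2))
```

prints

```
                                     Estimate    SE     z     p sig
f[red_fox]:(Intercept)                   0.70  0.42  1.65  0.10   *
f[snow_leopard]:(Intercept)             -1.19  0.80 -1.49  0.14
f[red_fox:snow_leopard]:(Intercept)      1.72  0.90  1.92  0.06   *
p[red_fox]:(Intercept)                   0.03  0.11  0.32  0.75
p[snow_leopard]:(Intercept)             -1.33  0.24 -5.66  0.00  **
0.92 0.67
```

The positive interaction term (f = 1.72) means the fox is more likely to use
a site where the snow leopard is present — conditional occupancy 0.92 versus
0.67 given absence. The wide SEs are typical at this survey scale.

The same workflow is available from the shell:

```
guildniche simulate --seed 1 --out run/
guildniche build-history --records run/records.csv --deployments run/deployments.csv --out run/
guildniche fit --records run/records.csv --deployments run/deployments.csv \
    --covariates run/covariates.csv --out run/ --seed 1
guildniche overlap-temporal --records run/records.csv --deployments run/deployments.csv --out run/
guildniche overlap-spatial  --records run/records.csv --deployments run/deployments.csv --out run/
guildniche diet --out run/
guildniche report --indir run/ --out run/summary.csv
```

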