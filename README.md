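# sympatric

Toolkit for quantifying how two sympatric predators partition — or fail to
partition — **space**, **time** and **food**, from the two field data streams
high-altitude carnivore studies actually produce: camera-trap capture records
and genetically assigned scats. It was built around the snow leopard /
common leopard and snow leopard / woolly wolf pairs of the Upper Bhagirathi
basin (Western Himalaya), but every component is generic to any
dominant/subordinate predator pair.

Three analysis axes, one module each:

**Spatial (`sympatric.cooccupancy`).** A single-season conditional
two-species occupancy model. With zA, zB the latent site-occupancy states of
the dominant (A) and subordinate (B) species,

    zA ~ Bernoulli(ψA),   zB | zA=1 ~ Bernoulli(ψBA),   zB | zA=0 ~ Bernoulli(ψBa),

and Bernoulli detection per pooled occasion (pA, pB) given presence, so
non-detection never proves absence. The headline quantity is the species
interaction factor

    SIF = ψA·ψBA / (ψA·ψB),   ψB = ψA·ψBA + (1−ψA)·ψBa,

the ratio of joint occupancy to what independent occupancy would give:
SIF = 1 independence, < 1 avoidance, > 1 aggregation. Fitting is by a
data-augmented Gibbs sampler under Uniform(0,1) priors (all full
conditionals are Beta), default schedule 3 chains × 1,000 kept draws after
10,000 burn-in, summarized by posterior mean, sd, 95% highest-density
interval and split-chain Gelman–Rubin R̂; "significant" interaction means
the SIF HDI excludes 1. A marginal maximum-likelihood fit (`ml_fit`) serves
as a frequentist cross-check.

**Temporal (`sympatric.activity`).** Capture clock times become angles on
[0, 2π); each species' diel activity density is a von Mises kernel density
estimate whose concentration comes from the circular plug-in bandwidth rule,
and the overlap between two species is the small-sample coefficient

    Δ1 = ∫ min(f̂A(θ), f̂B(θ)) dθ ∈ [0, 1].

**Dietary (`sympatric.diet`).** Per-prey frequency of occurrence
F = 100·n/N across N scats with bias-corrected bootstrap 95% CIs (10,000
resamples), conversion to relative biomass via predator-specific
biomass-per-scat regressions Y(X) (X = prey mean body mass, kg), and
Pianka's niche-overlap index O_jk = Σ p_ij·p_ik / √(Σ p_ij² Σ p_ik²) — the
cosine similarity of two predators' prey-use vectors.

`sympatric.detection` turns raw capture records plus station deployment
windows into 1/0/NA detection matrices with 6-day pooled occasions, and
`sympatric.simulate` provides seeded generators with the exact statistical
structure each stage assumes, so the full pipeline is testable with no
field data.

## Worked example

`examples/occupancy_interaction.py` simulates a 200-station, 10-occasion
survey where the subordinate avoids the dominant (ψBA = 0.3 vs ψBa = 0.6,
true SIF = 0.67) and refits it:

```
survey: 200 stations x 10 pooled occasions (6 trap-days each), dominant present at 97 sites
         mean      sd  hdi_low  hdi_high    rhat
psiA   0.4852  0.0356   0.4175    0.5577  0.9994
psiBA  0.2787  0.0460   0.1910    0.3682  1.0000
psiBa  0.5353  0.0501   0.4367    0.6322  1.0004
pA     0.4024  0.0171   0.3708    0.4371  1.0004
pB     0.4188  0.0190   0.3804    0.4539  1.0000
SIF    0.6774  0.0879   0.5003    0.8434  0.9995
SIF 95% HDI excludes 1: yes
```

Every generating parameter sits inside its 95% HDI, all R̂ ≈ 1, and the
SIF posterior (mean 0.68, HDI excluding 1) correctly flags the built-in
spatial avoidance. The other examples cover activity overlap
(`activity_overlap.py`), dietary overlap from the bundled reported FO
tables (`diet_overlap.py` — prints Pianka 0.754 for the felid pair), and
bootstrap CIs on a small scat sample (`diet_bootstrap.py`).

A thin CLI mirrors the workflow:

```sh
sympatric simulate  --spec spec.yaml --out sim/
sympatric occupancy --matrix-a sim/matrix_A.csv --matrix-b sim/matrix_B.csv \
                    --chains 3 --burn-in 10000 --iterations 1000 --seed 1 --out occ/
sympatric activity  --records sim/captures.csv --species-a snow_leopard \
                    --species-b woolly_wolf --adjust 0.8 --out act/
sympatric diet      --scats sim/scats.csv --masses masses.yaml \
                    --predators snow_leopard,woolly_wolf --seed 1 --out diet/
```

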