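# fluorisk

Probabilistic health-risk assessment of fluoride ingested with brewed tea.

Tea (*Camellia sinensis*) accumulates fluoride in its leaves and releases it
into the infusion during brewing. Habitual tea drinkers — especially
children, with their small body weight — can therefore approach or exceed
the chronic daily fluoride dose associated with dental fluorosis. `fluorisk`
is a library and command-line tool for quantifying that risk the way
environmental-health assessments do: it propagates uncertain exposure
inputs through the chronic-daily-intake model with a seeded Monte Carlo
simulation and reports percentile and exceedance summaries plus a
sensitivity decomposition. It is aimed at exposure-assessment and
environmental-epidemiology work where measured concentrations are sparse
(a handful of brands per product type) and inputs are described by simple
parametric distributions.

## The model

Chronic daily intake of fluoride from tea and the corresponding hazard
quotient are

```
CDI = C · DI · EF · ED / (BW · AT)        [mg/kg/day]
HQ  = CDI / RfD                           [–]
```

with C the fluoride concentration in the infusion (mg/L), DI the daily tea
intake (L/day), EF the exposure frequency (days/year), ED the exposure
duration (years), BW body weight (kg) and AT the averaging time (days,
default ED·365 for this non-carcinogenic endpoint — under which ED cancels).
RfD is the reference dose: 0.06 mg/kg/day (dental fluorosis; applied to
children 0–10 y and teenagers 11–20 y) or 0.12 mg/kg/day (skeletal
fluorosis; adults 21–70 y). HQ > 1 flags a potential non-carcinogenic
health risk.

Each stochastic input is a `DistributionSpec` (point, uniform, triangular,
normal or lognormal, optionally truncated; truncation by inverse-CDF
restriction so draw counts and seeds are stable). Sparse concentration
samples are fitted with a deterministic moment method: a triangular
distribution with endpoints at the sample extremes and mode
`c = 3·mean − min − max` (clamped). The Monte Carlo engine (default 10,000
iterations) draws every input from its own named substream of one root
seed, making runs bit-reproducible and extensible. Sensitivity is
quantified as contribution to variance: the signed, normalized squared
Spearman correlation between each input's draws and the output, the
statistic behind standard tornado charts.

The package also bundles the brewing study it models — type-level fluoride
summaries for 16 commercial products (five types, brewed 5/10/20 min in
triplicate) and the chemistry of six brewing waters — together with the
study's statistical toolbox: size-weighted overall means, pooled SDs
reconstructed from group digests, Shapiro–Wilk normality gating, exact
Mann–Whitney comparisons for small brand groups, and Spearman correlation
with detection-limit-censored values under explicit substitution policies.

## Worked example

```python
import fluorisk as fl

summaries = fl.reference_group_summaries()
print(round(fl.weighted_overall_mean(summaries, 5.0), 2))   # 1.28 mg/L
print(round(fl.pooled_sd(summaries, 5.0), 2))               # 1.11 mg/L

# fit black tea concentration from its printed min / mean / max
spec = fl.fit_triangular([1.12, 2.54, 3.87])                # triangular(1.12, 2.54, 3.87)

scenario = fl.ExposureScenario(
    age_group="children", product_type="black",
    C=spec, DI=fl.triangular(0.15, 0.25, 0.4), EF=fl.triangular(180, 365, 365),
    ED=fl.uniform(1, 10), BW=fl.triangular(14, 18, 25), rfd=0.06,
)
summary = fl.summarize(fl.run_monte_carlo(scenario, 10_000, seed=1))
```

This prints (seed 1):

```
CDI p5/mean/p95    : 0.0147 / 0.0298 / 0.0498 mg/kg/day
HQ  p5/mean/p95    : 0.246 / 0.497 / 0.830
P(HQ > 1)          : 0.0093
```

so for this exposure scenario the 95th-percentile hazard quotient stays
below 1 and fewer than 1% of simulated children exceed the dental-fluorosis
reference dose. The accompanying sensitivity report,

```
C   rho=+0.641  contribution=+42.7%
DI  rho=+0.531  contribution=+29.3%
EF  rho=+0.401  contribution=+16.7%
BW  rho=-0.329  contribution=-11.3%
ED  rho=-0.002  contribution=-0.0%
```

shows the infusion concentration driving the largest share of output
variance, body weight acting (as it must) in the negative direction, and
ED inert because it cancels from CDI under the default averaging-time rule.

The same pipeline is available from the shell:

```
fluorisk synth --seed 1 --out study.csv
fluorisk fit --input study.csv
fluorisk report --seed 1 --out-dir out/
```

`report` writes group summaries, pairwise comparisons, fitted concentration
specs, per-scenario iteration CSVs and summary JSONs, sensitivity tables,
and one combined risk table (rows = product type, columns = age group ×
CDI/HQ digests), each stamped with seed, version and config hash.

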