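# Methods

This note records the scientific and numerical choices behind `fluorisk`:
the exposure model and its conventions, what the synthetic-data generator
does and does not emulate, and the places where the design was genuinely
open.

## Exposure model

Non-carcinogenic risk from fluoride ingestion via brewed tea is modelled as

    CDI = C · DI · EF · ED / (BW · AT),      HQ = CDI / RfD,

with units mg/L (C), L/day (DI), days/year (EF), years (ED), kg (BW), days
(AT). The model assumes ingestion is the only route, tea the only fluoride
source, and inputs mutually independent. No correlation between inputs is
imposed (none is known for this system); `run_monte_carlo` samples each
input from its own substream, which doubles as the extension point if a
correlation structure is ever added.

**Averaging time.** For chronic non-carcinogenic endpoints the standard
convention is AT = ED · 365 days, and that is the default rule. A direct
consequence — worth stating because it surprises users — is that ED cancels
from CDI entirely, so the ED distribution only matters under a fixed-AT
rule. The test suite checks the cancellation explicitly.

**Reference doses.** 0.06 mg-F/kg/day (dental fluorosis) for children
(0–10 y) and teenagers (11–20 y); 0.12 mg-F/kg/day (skeletal fluorosis) for
adults (21–70 y). Both are overridable per scenario. Because HQ = CDI/RfD
per draw, P(HQ > 1) and P(CDI > RfD) are identically equal — an invariant
the suite asserts rather than a numerical coincidence.

## Input distributions

`DistributionSpec` supports point, uniform, triangular, normal and
lognormal families with optional truncation. Two numerical conventions:

- **Truncation is inverse-CDF restriction, never rejection.** Draws are
  `F⁻¹(u)` with `u ~ Uniform(F(lo), F(hi))`. This guarantees exactly n
  outputs, keeps streams seed-stable under truncation changes, and is exact.
  Physical inputs (concentrations, intakes, weights) should be truncated at
  0 when given normal-family specs; the scenario validator rejects supports
  extending below 0.
- **Substreams by name.** Every parameter's generator is
  `SeedSequence(root_seed, spawn_key=(crc32(name),))`. Adding or removing a
  parameter never perturbs the draws of another, so scenario edits are
  minimally disruptive to reproducibility.

**Triangular fitting.** Commercial risk tools fit distributions with opaque
estimators; `fit_triangular` instead uses a deterministic moment method:
endpoints at the sample min/max, mode `c = clamp(3·mean − a − b, a, b)`
(from E[X] = (a+b+c)/3 with endpoints fixed). It is optimizer-free,
reproducible, and exact on a {min, mean, max} triple — which is precisely
the form in which sparse concentration data are often published. Its known
bias: with n in the thousands the sample extremes converge to the true
endpoints (recovery tests use n = 10⁴), but at n = 3–15 the range is
underestimated, so fitted spreads from few brands are conservative-narrow.

**Quantiles.** All reported percentiles use linear interpolation between
order statistics (the spreadsheet-compatible estimator). Other software may
differ in the third decimal at n = 10⁴; the estimator name is embedded in
every `RiskSummary`.

## Statistics for the measurement stage

- `weighted_overall_mean` and `pooled_sd` reconstruct all-product digests
  from per-type (n, mean, sd) rows; the pooled variance is
  (SS_within + SS_between)/(N−1) with sample (n−1) group SDs. Note a
  subtlety: pooling groups with identical means and SD s does **not**
  return s exactly under this convention (it returns
  √(Σ(nᵢ−1)s²/(N−1))); it returns exactly the sample SD of the underlying
  raw pool, which the tests verify against brute-force reconstructions.
- `compare_groups` uses the exact Mann–Whitney null distribution whenever
  the combined sample is ≤ 20 without ties — the regime of the study's
  2–5-brand groups — and the tie-corrected normal approximation otherwise;
  the method actually used is recorded on the result. An all-ties input
  short-circuits to U = n_a·n_b/2, p = 1 rather than dividing by a zero
  tie-corrected variance.
- `spearman_censored` makes the detection-limit policy explicit:
  `substitute_dl` (default), `substitute_half_dl`, or `drop_censored`.
  Substitution policies create ties at the substituted value; average ranks
  then determine rho. On the bundled water table (three waters censored at
  0.02 mg/L) the fluoride–infusible correlation comes out 0.941 and the
  pH–infusible correlation 1.0 under any substitution policy. Published
  accounts of these data attach the two labels the other way around; with
  average-rank tie handling the censored triple cannot yield rho = 1, so
  the package documents its policy and reports what that policy computes
  rather than claiming to match the published label assignment.
- p-values are two-sided throughout and unadjusted by default (matching the
  single-comparison reporting style of the measurement stage);
  `pairwise_type_comparisons` exposes an optional Holm adjustment.

## Synthetic study generator

The generator emulates the published study's *shape*: 16 brands over five
product types (5 black, 3 green, 3 oolong, 3 herbal, 2 white), three
brewing times (5/10/20 min), triplicate measurements. Published type-level
SDs are interpreted as between-brand spread: each brand receives one
standard-normal effect z_b, drawn once and reused across brewing times (a
fluoride-rich brand stays rich at every time), and its cell mean is
`cell_mean + z_b · cell_sd`, floored at 0. Replicates add multiplicative
noise with 5% CV by default — an order of magnitude below between-brand
spread, consistent with published brand-level replicate SDs of a few
hundredths of mg/L against type-level SDs near 1 mg/L.

What it does **not** emulate: measurement censoring in infusions (real
assays floor at 0.02 mg/L), brand-by-time interaction beyond the shared
z-score, non-normal brand effects, and any dependence between replicates.
Passing tests therefore demonstrate correctness of the analysis machinery
on data of the right shape and moments — not robustness to the messier
features of real infusion datasets.

With only 2–5 brands per type, the min/max-based triangular refit of a
generated study is highly seed-variable (a 3-brand type can land clustered,
giving a very narrow fitted C). This is faithful to the smallness of the
real design and is why downstream pipeline assertions are about orderings
and signs, not magnitudes.

## Known-truth scenarios

`closed_form_scenario` returns scenarios whose CDI law is exact:
`all_point` (degenerate), `lognormal_C` (single lognormal input, σ = 0.5),
and `all_lognormal` (C, DI, EF, BW lognormal; lognormals are closed under
products and quotients, so CDI is lognormal with summed log-moments, BW
entering negatively). The `all_lognormal` dispersions (σ = 0.15, 0.10,
0.05, 0.12; combined 0.22) are sized for verification power: the relative
standard error of an empirical p5/p95 at n = 10⁴ is
√(p(1−p)/n)·σ/φ(z_p) ≈ 0.5%, so a 2% agreement check sits at ~4 standard
errors and a pass is informative about correctness rather than about luck.
For the σ = 0.5 single-input scenario the same formula gives ≈1.1%, so its
test bounds the error at 3 standard errors of the quantile estimator
instead of a fixed percentage.

## Default exposure scenarios

The packaged per-age-group exposure blocks are reconstructions, not a
transcription of any external table. They were calibrated to two kinds of
published facts about this system: central tendencies (adult tea intake
near 1 L/day in heavy-tea-drinking populations; body-weight centers of
18/52/62 kg for children/teenagers/adults) and the reported sensitivity
structure of the original analysis, in which the infusion concentration
ranked first in every age group (maximum contributions near or above 50%),
exposure frequency and intake were secondary, and body weight contributed
a small negative share. The resulting spreads (DI CV ≈ 0.17–0.20, BW CV ≈
0.10–0.12, EF triangular 180–365–365) reproduce that qualitative pattern;
wider intake distributions would let DI overtake C, contradicting the
reported structure. Absolute HQ percentiles from these defaults are
indicative only and depend on the exposure assumptions; headline published
HQ values rest on exposure tables that are not publicly available, so this
package makes no claim to reproduce them numerically, and its verification
surface is the closed-form scenarios above.

## Degenerate inputs and error policy

Zero-variance inputs to the sensitivity analysis are excluded from the
normalization denominator and reported with contribution exactly 0 and a
`varies=False` flag (never NaN). A constant output, a constant sample
offered to the normality test, an all-identical sample offered to the
triangular fitter, and an empty group in a comparison all raise typed
errors (`DegenerateInputError`, `InsufficientDataError`) rather than
returning undefined numbers. Pipeline output is staged and promoted only on
success, so a failing stage cannot corrupt a previous bundle.
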