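# Methods

## Measures and conventions

A birth record carries a residence municipality and a birth (occurrence)
municipality; a record "traveled" iff the two codes differ as strings.
Codes are opaque fixed-width strings throughout — no arithmetic is ever
performed on them, since registries with numeric codes (e.g. 6-digit IBGE
codes) lose leading zeros the moment they pass through an integer type.

Per unit and year: `F = travelers / births`; `C = mean inter-municipal km
among travelers`; `D = F × C`, the mean over all births with non-travelers
contributing 0 km. C for a unit with zero travelers is *undefined* (NaN),
never 0 — averaging a 0 into a state would deflate its mean. Aggregation
never averages ratios: births, travelers and traveler-kilometres are
pooled and the ratios re-formed, which makes `D = F × C` exact at every
level and makes municipality→state→national equal municipality→national.
An unweighted variant (plain mean of municipal F, C, D) is exposed as an
option because state-level summaries of "the municipal average" appear in
both weighted and unweighted forms in practice; the two differ markedly
when municipal sizes are skewed, and callers should state which they use.

Travelers whose origin–destination pair is absent from the distance matrix
are excluded from the distance-based statistics and counted
(`n_distance_missing`), not imputed; F still counts them as travelers, and
D is defined as F × C with C estimated from the distance-resolved
travelers. A miss on lookup is a raised error, never a silent 0 km.

## Decomposition

From `D = F × C`, the change between t0 and t1 satisfies exactly

    ΔD = ΔF·C₀ + F₀·ΔC + ΔF·ΔC.

The two-term form ΔF·C₀ + F₀·ΔC is the familiar approximation; we always
report the exact three terms, so the approximation and its error
(= the interaction) are recoverable by addition. Whether published
two-term decompositions fold the interaction into either component is
usually unstated; keeping it separate is the only choice that is testable
to machine precision. Units with C undefined in either year produce a
flagged row rather than disappearing. Reversing the period order negates
ΔD exactly.

## Gini, brackets, deciles

The Gini of municipal conditional distances within a state-year uses the
mean-absolute-difference form G = Σᵢⱼ|xᵢ−xⱼ| / (2n²x̄), computed via the
sorted-vector identity (O(n log n)) and cross-checked in the tests against
the brute-force double loop. Only municipalities with ≥1 traveler enter;
fewer than 2 eligible municipalities → flagged undefined. Unweighted by
default (each municipality one observation); a birth-weighted variant is
behind a flag.

The map-classification scheme cuts the pooled distribution (all units, all
years — one fixed scheme so different years share a colour scale) at the
12.5, 25, …, 87.5 percentiles, linear interpolation between order
statistics. A value's bracket is `1 + #{cuts < value}`: values equal to a
cut fall in the *lower* bracket, so tied/degenerate cuts collapse and a
constant distribution sits entirely in bracket 1. Any consistent tie rule
would do; this one is declared so results are reproducible.

The size-decile table ranks municipalities by mean annual births over the
window (ties broken by code), assigns decile `⌊10·rank/n⌋ + 1`, and pools
counts within decile × year; interval columns report the min/max mean
annual births per decile.

## Gaps and gradients

Risk-factor gaps compare mean distance between flag-yes and flag-no
births. Distance is unconditional by default (0 km for non-travelers):
the contrast then reads as a difference in population mean D, which is the
natural measure when the question is "does this group travel more *and*
farther"; a conditional variant (travelers only) is exposed. Records
missing a flag are excluded for that flag only. The SE is Welch's
√(s₁²/n₁ + s₀²/n₀) with sample variances and a normal 95% CI — group sizes
here are thousands, where the normal and t intervals coincide.

Gradients are univariate OLS fits of municipal D (pooled over the window
by default; a single-year option exists) on one z-scored census covariate
at a time: β₁ is km per SD of the covariate, comparable across covariates
and invariant to their rescaling. The z-score's SD convention (n−1 vs n)
is an explicit `ddof` argument, default 1, pinned by tests under both
conventions since β₁ scales with it. Regressions are unweighted across
municipalities by default, with a birth-weighted WLS option. No
multiple-testing correction is applied: the panel is descriptive, reports
estimates and SEs, and makes no causal claim — the covariates are mutually
correlated and each fit omits the others.

## Synthetic scenarios

The generator emulates the structure the analysis relies on, with all
parameters in `ScenarioConfig`:

- **Geography** — municipalities uniform on a square of side
  `plane_extent_km` (default 800 km); states are equal-count longitude
  bands, health regions contiguous latitude chunks of ~5 municipalities
  within a state (regions therefore nest in states by construction).
  Annual birth volume is log-normal (defaults μ=3.5–4.05, σ=1.0 depending
  on scale), matching the heavy right tail of municipal size
  distributions. The largest municipality of each region is its hub; hubs
  always own a delivery facility, others with probability logistic in
  log-size (default intercept −4, slope 1.1 ⇒ facility ownership rises
  steeply with size).
- **Distances** — `detour_factor` × Euclidean (default 1.3, a typical
  road-network detour index), symmetric, zero diagonal. The analysis only
  consumes the matrix, so planar coordinates rather than a geoid cost
  nothing.
- **Travel** — births per municipality-year are Poisson in size. Every
  birth is institutional; facility-less towns always travel. In
  facility-owning towns, P(travel) = logit⁻¹(intercept + slope·d_alt +
  boost·any_risk + dF_per_year·t) with d_alt the km to the nearest
  alternative facility (defaults −1.0, −0.02/km). Destination is the
  regional hub with P = logit⁻¹(hub_logit + boost·any_risk +
  dC_per_year·t), else the nearest facility. `risk_referral_boost`
  (default 0.6 log-odds) raises both travel and hub choice for risk
  pregnancies, producing a positive distance gap whose model expectation
  the generator also returns.
- **Trends** — `dF_per_year` shifts the travel logit (raising F),
  `dC_per_year` the hub logit (lengthening trips). In the shipped study
  conditions the decade's ΔD is dominated by the share term; the observed
  ΔC is small because the hub-preference trend is partly offset by
  composition (marginal travelers from facility-owning towns take shorter
  trips).
- **Covariates** — a latent development index is drawn with correlation
  `ses_gradient` to the town's distance burden (km to nearest facility, 0
  for owners); census-style indicators are monotone transforms of it.
  The sign convention is chosen so that a *negative* `ses_gradient`
  (default −0.6) reproduces the canonical pattern: development-linked
  covariates get negative distance slopes, poverty-linked ones positive.
- **Flag rates** — independent Bernoulli draws at plausible placeholder
  prevalences; nothing asserts their values.

Everything is deterministic in `config.seed` (NumPy Generator;
byte-identical tables on replay).

What the generator does **not** emulate: road-network routing (travel
times, asymmetric detours), spatial autocorrelation of covariates beyond
the facility-driven gradient, dependence among clinical flags,
non-institutional births, migration between registry years, and
reporting errors in municipality codes. Passing recovery tests therefore
shows the estimators are correct under the assumed data-generating
process, not that real registries satisfy those assumptions.

## Study conditions and problem sizes

Three named configurations anchor the validation suite:

- `study_config` — 250 municipalities, 8 states, ~45,000 births over the
  years 2007 and 2017; used for stratum travel-probability recovery
  (within 3 binomial SEs of the model expectation), risk-gap CI coverage
  of the expected gap, and all headline descriptive outputs.
- `recovery_config` — ~5,000 births; 100 replicates for gradient-sign
  recovery (expected ≥95/100 negative development slopes at gradient
  −0.6).
- `null_config` — ~4,000 births with **all** effects and trends zeroed
  (risk boost, gradient, and both temporal trends): the gap, the
  development slope and the trip-length term are then exact nulls, and
  sign tests across 100 replicates must be non-significant at 5%. The
  travel-propensity trend is zeroed too, deliberately: a rising intercept
  shifts the traveler mix between facility-owning and facility-less towns
  and moves C through composition alone, so it is not a valid null for
  the trip-length term. A separate composition-neutral design (facilities
  everywhere, zero distance slope — uniform travel probability, hence a
  stable traveler mix) verifies that a share-only trend leaves the
  trip-length term centred on zero.

## Numerical choices

Identity checks use 1e-9 relative tolerance (the ratios are re-formed
from pooled sums, so agreement is ~1e-16 in practice). The decomposition
computes ΔD as F₁C₁ − F₀C₀ so the three-term identity is exact in floating
point. Degenerate inputs are explicit: empty municipality-years emit no
row; empty gap groups, sub-2-municipality Ginis and undefined-C
decompositions are flagged rather than dropped; constant covariates and
sub-3-point regressions raise.
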