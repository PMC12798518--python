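# Methods

## Model

The estimand is a prevalence θ ∈ (0, 1). Conditional on θ, each person's
case indicator is Bernoulli(θ) with identity parameterization (θ is the
probability itself, not a transformed intercept), and θ carries a Beta(α, β)
prior. The posterior is conjugate:

    θ | (n, k) ~ Beta(α + k, β + n − k)

and the marginal likelihood of the ordered Bernoulli sequence is
B(α + k, β + n − k) / B(α, β), computed in log space.

Informative priors are elicited from an administrative source that
ascertained k′ cases among n′ persons as (α, β) = (k′ + 1, n′ − k′ + 1):
the counts enter as pseudo-observations on top of the uniform Beta(1, 1),
which is itself the non-informative default. Priors carry a provenance label
so reports can cite their source. Jeffreys-type priors and prior-predictive
checking are deliberately out of scope: the package exposes exactly the
summaries used in reporting (mean, sd, equal-tailed quantiles via the exact
inverse CDF, with a hard failure — never a silent fallback — if the quantile
solver does not return a valid probability).

Reported summaries are the posterior mean, posterior sd (the "SE" column of
Bayesian rows), and the 95% equal-tailed credible interval. The reporting
convention rounds Bayesian probabilities to the nearest whole percent and
prints one decimal (0.58561 → "59.0%"); the frequentist row is printed at
one-decimal precision directly (56.6%). The frequentist estimate is the MLE
of the intercept-only identity-link binomial GLM — the sample proportion —
with Wald interval p̂ ± z·√(p̂(1−p̂)/n), z fixed at 1.959964 for bit-stable
output, truncated to [0, 1]. At k = 0 or k = n the interval is degenerate
(se = 0); the result is flagged rather than raised.

## Sampler

The MCMC route exists so that a sampled analysis can be audited against the
closed form. Because the posterior is a one-dimensional beta distribution, a
gradient-based sampler adds nothing testable; the package instead uses
adaptive random-walk Metropolis on η = logit(θ). The target in η includes
the Jacobian θ(1−θ), giving the unnormalized log density
a·η − (a+b)·log(1+e^η) with a = α + k, b = β + n − k. Chains start from
logit of a uniform draw on (0.05, 0.95) (overdispersed relative to any
realistic posterior); during warm-up the proposal scale adapts toward the
scalar-RWM-optimal acceptance rate 0.44 by Robbins–Monro on the log scale
(step t^−0.6), and is frozen afterwards so the retained chain is Markovian.
"Iterations" counts total steps per chain including warm-up; retained draws
per chain = ⌊(iterations − warmup)/thin⌋. Chain c is seeded from the stream
SeedSequence([master_seed, c]), so runs are reproducible and chains
independent. A chain that rejects every post-warm-up proposal raises a
sampler failure.

At the reference settings (4 chains × 20,000 iterations, warm-up 500,
thin 5) the retained 15,600 draws are nearly independent (thinning by 5
exceeds the RWM autocorrelation time at optimal scaling), so bulk/tail ESS
lands around 13,000–15,500. Every sampled analysis also computes its
conjugate twin; the suite records |MCMC mean − exact mean| as a first-class
column and the tests require agreement within 4 Monte-Carlo standard errors
(MCSE = posterior sd / √ESS).

## Diagnostics

R-hat and ESS follow the modern rank-normalized split-chain definitions:
chains are split in half, pooled draws are mapped to normal scores via
Φ⁻¹((rank − 3/8)/(S + 1/4)), and R-hat = √(((N−1)/N·W + B/N)/W) with W the
mean within-half-chain variance and B = N·Var(half-chain means). The classic
non-split R-hat is intentionally not offered (it passes trending chains).
ESS combines per-chain FFT autocovariances through the within/between
variance decomposition and sums correlations under Geyer's
initial-monotone-positive-sequence truncation; bulk ESS uses the
rank-normalized split chains, tail ESS is the minimum over the 5% and 95%
quantile-indicator ESSs, and values are capped at the retained draw count.
Constant chains yield an undefined (NaN) R-hat, which the convergence report
treats as failure. The pass rule is R-hat ≤ 1.01 — the strictest commonly
used cutoff, chosen because 1.0 is treated as converged and 1.05 as clearly
failed — and bulk and tail ESS ≥ 1,000. The report also emits render-free
plotting material (per-chain windowed trace means, a Gaussian-KDE density
grid, the ACF), keeping images out of the core.

## Case ascertainment

Administrative case definition: within the lookback window
[entry − L, entry], a person is a case iff there is ≥1 inpatient
mood/anxiety code, or two outpatient mood/anxiety codes on *distinct* dates
≤ 730 days apart. "Within a 24-month period" is read as a sliding span
between events, the stricter, order-free interpretation; requiring distinct
dates prevents a single visit with duplicate billing from qualifying. The
lookback is inclusive at both ends at whole-day resolution, with L = 1,826
days for five years (one embedded leap year). Checking adjacent gaps of the
sorted distinct outpatient dates is sufficient and is verified against a
brute-force all-pairs oracle in the tests. Adding encounters can only turn a
0 into a 1 (monotonicity).

Linkage is deterministic on (person_id, date_of_birth); conflicting dates of
birth for one id raise a linkage error listing the ids. Among duplicate
records the most complete (highest completeness_score) is retained, ties
broken by earlier enrollment then cohort label. The self-report flag is an
OR over the instrument's diagnostic modules (MDD, bipolar, GAD, social
phobia, PTSD, OCD, panic): missing only if every module is missing.

## Synthetic data

The generator emulates a linked two-cohort structure: cohort A of 1,333 with
272 dual-enrolled in cohort B (2,369), so linkage retains 3,430 unique
persons; instrument completion ~549/1,061 among non-duplicated cohort-A
persons (the instrument is treated as not administered to dual-enrolled
participants, consistent with their exclusion before instrument
accounting); true prevalence 0.59; self-report sens/spec 0.95/0.84
(operating characteristics of the instrument's dominant depression module);
administrative coding sens/spec 0.629/0.938; censoring ~2.4%. Demographics
(sex, marital status, employment, age) are drawn independently given case
status to hit the configured margins in expectation — they are cosmetic, and
no confounding structure is modeled because the analysis uses none.

The generator draws each person's *intended* administrative flag first
(Bernoulli with sens/spec against true status) and then materializes
encounters consistent with it: flagged persons receive one inpatient code or
two outpatient codes ≤730 days apart inside the lookback; unflagged persons
receive nothing, a single code, or two codes >730 days apart; everyone may
additionally receive unrelated ("other") encounters that never qualify.
Encounters are anchored to the enrollment date of the record deduplication
retains, so running the case algorithm on the generated claims reproduces
the intended flags with zero mismatches for any valid configuration — a
property the tests check over randomized configurations. Instrument
missingness is completely at random; real non-completion may well be
informative, so passing tests say nothing about MAR/MNAR robustness.
Encounter dates are uniform over the lookback subject to the pattern
constraints; enrollment dates uniform over the enrollment window. Identical
configuration (including seed) yields bit-identical CSVs.

What the generator does *not* emulate: real diagnostic code dictionaries
(symbolic dx_group labels only), correlation between the two instruments'
errors within a person, informative censoring, or secular trends in claims.

## Problem sizes and numerical choices

Tests run the reference sampler settings (≈80,000 total iterations,
sub-second), the 50,000-person apparent-prevalence checks, a 400-replicate
coverage study of the flat-prior credible interval at n = 549 backed by an
exact binomial-enumeration oracle (true coverage ≈94.9%), and round-trip
property tests on cohorts of a few hundred persons — sizes at which every
stochastic assertion has comfortable margin at fixed seeds. The coverage
band (93–97%) and MC-error tolerances (3–4 standard errors) are stated in
the tests themselves.

## Known limitations

- Instrument misclassification is *not* propagated into the likelihood: the
  analysis estimates apparent prevalence as measured by the self-report
  instrument, informed by an administrative prior — not a
  misclassification-adjusted true prevalence. The generator's sens/spec
  machinery exists to make this distinction measurable on synthetic data.
- The sampler is specific to the one-parameter conjugate model; it is an
  auditable stand-in for general-purpose MCMC, not a replacement.
- Tail-ESS of the deliberately short chains (50 iterations) is
  sampler-specific; only the pass/fail outcome, not the literal diagnostic
  values, is meaningful there.
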