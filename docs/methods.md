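# Methods

## Model and estimands

Patients enter in state 0 (searching for a donor, on chemotherapy).
Patients with an available donor (latent indicator, probability
`donor_prob`) carry a latent waiting time `W ≤ τ` to identification
(state 1); everyone is exposed to the pre-identification event hazard
λ₀₂ until identification. Donor availability is *external*: the latent
donor exists whether or not the patient survives, which is what licenses
treating search-ceasing events as non-informative censoring for the
waiting-time distribution.

The estimands are the survival probabilities at a fixed horizon t\*,

    S0(t*) = exp(−∫₀^{t*} λ02),     S1(t*) = E_W[ S0-path to W · S1(t*|W) ],

and the cumulative hazard ratio cHR(t\*) = log S1(t\*)/log S0(t\*),
which remains interpretable under the non-proportional hazards typical
of transplantation (short-term harm, long-term benefit).

## Weighted pseudo-values (WPV)

One set of jackknife pseudo-values `V̂ᵢ(t*) = n·Ŝ(t*) − (n−1)·Ŝ^{−i}(t*)`
is computed on the raw outcome sample. Membership weighting:

| observed patient      | weight in no-donor group | weight in donor group |
|-----------------------|--------------------------|-----------------------|
| search completed at τ | 1                        | 0                     |
| donor identified      | 0                        | 1                     |
| search ceased at Cᵢ   | q̂ᵢ = Ĝ(τ)/Ĝ(Cᵢ)         | p̂ᵢ = 1 − Ĝ(τ)/Ĝ(Cᵢ)  |

Ĝ is the Kaplan–Meier estimator of the identification waiting time
(identifications are events; ceasing, censoring and completed searches
censor). The grand total weight is exactly n. If a donor is found after
the search was ceased (`late_donor_flag`), p̂ᵢ is set to 1. The weighted
GLM with log(−log) link and identity variance is saturated in the binary
group indicator, so the fit is closed-form: the fitted group means equal
the weighted group means of the pseudo-values. An iterative
Fisher-scoring path exists purely as a cross-check.

**Variance.** The sandwich A⁻¹BA⁻ᵀ aggregates score contributions by
patient before the outer product, because the two rows of a ceased
patient are the same patient and maximally dependent. No small-sample
correction is applied and normal quantiles are used for the Wald
intervals, matching large-sample GEE practice; the empirical coverage of
the resulting intervals is what the evaluation harness checks.
Probability-scale and cHR intervals are the link-scale Wald intervals
mapped through exp(−exp(·)) (decreasing — endpoints swap) and exp(·).

## Generalised pseudo-values (GPV)

The comparator estimator. The no-donor arm uses pseudo-values of the
*direct-transition* sample, in which identified patients are censored at
w_j. For the donor arm the algebra of the original source is partly
unrenderable; this package uses the reconstruction

    V^D_j = Ŝ^N(w_j) · [ n_j·Ŝ_{w_j}(t*) − (n_j−1)·Ŝ^{−j}_{w_j}(t*) ],

where Ŝ^N is the direct-transition Kaplan–Meier, and the bracket is
patient j's jackknife pseudo-value within the cohort of n_j patients
still at risk (event-free, uncensored) at w_j. Although that risk-set
cohort mixes identified and non-identified patients, the *conditional
expectation of the pseudo-value given j's history* is the donor-specific
conditional survival from w_j, so V^D_j targets S1(t\*|w_j). Simpler
factorisations (the conditional Kaplan–Meier without the jackknife, or
j's own direct-transition pseudo-value at horizon w_j as first factor)
were measured to be inconsistent in the evaluation harness and were
rejected. Donor-arm rows are weighted by ω_j = 1/K̂(w_j⁻), where K̂ is
the Kaplan–Meier estimator of time to search-ceasing-or-censoring
(identifications censor); the weights are used unscaled. The left limit
at w_j is used because a patient identified at w_j was necessarily still
search-active there. Each identification time requires its own risk-set
computation, which is why GPV is the slower method.

## Tie and evaluation conventions

* Product-limit estimation: events precede censorings at identical
  times; Ŝ is right-continuous; values are carried forward beyond the
  last observation (with a recorded warning when Ĝ(τ) needs it).
* Ĝ is evaluated right-continuously at the ceasing time Cᵢ: an
  identification tied exactly at Cᵢ counts as observed information.
* An identification tied with the outcome event at the same time stamp
  is honoured (the donor exists independently of the outcome).
* Pseudo-values are never clipped; only fitted group means must lie in
  (0, 1), otherwise the fit raises an error naming the group.
* A risk set smaller than 5 subjects at t\* triggers a warning (the
  asymptotics need a "sufficiently large" risk set; 5 is a pragmatic
  floor, not a hard rule).

## Computation

Pseudo-values use an O(n log n) leave-one-out update: removing subject i
shrinks every risk set at event times ≤ Tᵢ by one and removes one death
at Tᵢ if i died, so all n leave-one-out estimates follow from two
cumulative log-factor arrays. When no censoring precedes the horizon the
jackknife collapses to the survival indicator and is returned exactly.
Degenerate factor patterns (a risk set exhausted by deaths) are detected
as non-finite intermediate values and recomputed by the brute-force
O(n²) path, which also serves as the independent oracle in the tests.

## Synthetic-data generator

Event times are drawn by closed-form inversion of mixture-cure laws
S(t) = π + (1−π)·S_u(t) with Weibull (default exponential) uncured
components; cured patients carry +∞ internally and always become finite
observables through uniform censoring on (0, c_max). Post-identification
survival is either a *continuation* of the pre-identification law
(drawn from its conditional distribution given survival to W — the
exact no-effect model) or a fresh mixture-cure law on the
time-since-identification clock, optionally with the cure fraction
rescaled per waiting time (`plateau_match`) so that only short-term
survival differs. Identification is observed only if the patient is
event-free and uncensored at W; otherwise the search ends by completion
at τ, by the (search-ceasing) outcome event, or by censoring, whichever
comes first.

The generator emulates the structure of transplantation studies — it
does not model competing risks, covariate-dependent waiting times,
calendar-time entry, or dependence between censoring and the disease
process. Passing tests therefore demonstrate correctness of the
estimators under independent censoring and an external donor covariate,
not robustness to violations of those assumptions.

### Scenario library defaults

Exact generating parameters of the published scenario suite are not
available; the library's defaults are this package's own calibrations to
the stated qualitative shapes, version-controlled here and serialisable
to YAML:

* `study1` — four equal latent groups: no donor (25%) and donors with
  discrete waiting times 0.5/1/3 years (25% each); τ = 3, t\* = 5,
  uniform censoring on (0, 6). Pre-identification hazard exponential
  with rate 0.12/yr and no cure; the post law continues the pre law, so
  the scenario isolates the membership-reconstruction problem. With
  these defaults the probability that an available donor is actually
  identified is ≈ 0.86/0.74/0.35 at w = 0.5/1/3.
* `A`–`G` — τ = t\* = 5, censoring uniform on (0, 11), exponential
  waiting times with mean 0.4 yr (mean 3 yr for G), donor probability
  0.25 (A), 0.40 (B–F), 0.45 (G). Baseline pre law: cure 0.30,
  exponential rate 0.8/yr (5-yr no-donor survival ≈ 0.31, a realistic
  paediatric-oncology figure). A: higher post cure 0.45 (long-term
  difference); B, C: faster early post hazard with higher cure
  (crossing curves); D: post cure plateau-matched to the no-donor
  plateau with faster early hazard (short-term difference only); E:
  no cure, pre rate 0.2, post rate 0.12 = 0.6×pre (proportional
  hazards); F: continuation (no effect, cHR ≡ 1 exactly); G: as A with
  mean waiting time 3 yr (identification mostly late or never).

`true_values` computes scenario truth exactly: a finite sum over
discrete waiting masses or adaptive quadrature (tolerance 1e−8 ≈ 1e−10
requested) over continuous ones.

## Evaluation harness

`run_replications` derives replicate r's generator from
`SeedSequence(entropy=base_seed, spawn_key=(r,))`, so WPV and GPV runs
with the same base seed are paired on identical cohorts. Bias is
reported on the link scale (β₀ = log(−log S₀), β₁ = log cHR), with
probability-scale bias secondary. Coverage of a nominal level ℓ over R
replicates is judged against (q₀.₀₂₅, q₀.₉₇₅) of Binomial(R, ℓ)/R —
(0.936, 0.963) for R = 1000, ℓ = 0.95. Failed replicates are recorded
with their indices and excluded from the coverage denominator; more than
5% failures raises an error rather than reporting a summary on a
silently reduced sample.

Problem sizes used by the shipped checks: the coverage runs use
R = 1000 replicates of n = 400 cohorts; parameter recovery uses
R = 200 at n = 4000; frequency restoration uses a single n = 20000
cohort. These sizes give Monte-Carlo errors comfortably below the
effects being checked while keeping a full run in the low minutes on
one core.

## Known limitations

* The GPV donor-arm formula is a reconstruction (see above); its
  empirical bias and coverage are validated by the harness, but it is
  not guaranteed to be algebraically identical to the original GPV
  software.
* Membership probabilities use a single pooled identification curve; no
  stratification (e.g. by ethnicity or registry) is supported.
* No covariate adjustment beyond the group indicator, no competing
  risks, no left truncation.
* With very small risk sets at t\* (heavy censoring near the horizon)
  pseudo-values become unstable; the package warns but does not refuse.
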