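# wpvsurv

Weighted pseudo-values for comparing long-term survival between two
cohorts — patients *with* and *without* an available stem-cell donor —
when a prematurely ceased donor search leaves cohort membership unknown
for part of the patients.

## The problem

In paediatric leukaemia studies comparing allogeneic stem-cell
transplantation (SCT) with chemotherapy alone, the fair ("genetic
randomisation") comparison is between patients for whom a matched donor
*could* be identified within the maximum search time τ and those for
whom it could not — not between transplanted and non-transplanted
patients. Two features make this hard:

* **Immortal time.** A donor can only be identified for a patient who is
  still event-free; naively classifying patients by observed
  identification biases the donor cohort towards survivors.
* **Unknown membership.** If a patient dies, relapses, or is censored
  while the search is still running, the search stops and it is never
  known whether a donor would have been found.

Because SCT trades short-term harm for long-term benefit, hazards are
non-proportional and a Cox hazard ratio is not meaningful; the relevant
estimand is survival at a fixed horizon t\* and the **cumulative hazard
ratio** cHR(t\*) = log S₁(t\*) / log S₀(t\*).

## The estimator

For all *n* patients, jackknife pseudo-values of the Kaplan–Meier
estimator at t\* are computed once:

    V̂ᵢ(t*) = n·Ŝ(t*) − (n−1)·Ŝ^(−i)(t*).

Patients with known membership enter a regression dataset once with
weight 1. A patient whose search was ceased at time Cᵢ enters **twice**:
with weight

    p̂ᵢ = 1 − Ĝ(τ)/Ĝ(Cᵢ)

in the donor group and weight q̂ᵢ = 1 − p̂ᵢ in the no-donor group, where
Ĝ is the Kaplan–Meier estimate of the waiting-time distribution of donor
identification (search-ceasing events and censoring treated as
non-informative censoring — donor availability is an external
covariate). The pseudo-values are then regressed on the group indicator
Z in a weighted GLM with log-minus-log link g(S) = log(−log S), normal
response distribution and a cluster-robust sandwich covariance (the two
rows of a ceased patient share a cluster):

    g(E[V̂ᵢ]) = β₀ + β₁·Zᵢ,    Ŝ₀ = exp(−exp(β̂₀)),  Ŝ₁ = exp(−exp(β̂₀+β̂₁)),  ĉHR = exp(β̂₁).

The package also implements the slower comparator — generalised
pseudo-values (GPV), which instead censor identified patients in a
direct-transition Kaplan–Meier, build a per-identification conditional
pseudo-value with its own starting time and risk set, and reweight
identified patients by inverse-probability-of-censoring weights
ω_j = 1/K̂(w_j⁻) — plus a multistate mixture-cure simulator and a
bias/coverage evaluation harness.

## Worked example

Simulate a 1000-patient cohort from library scenario `A` (mixture-cure
survival with a long-term benefit of donor availability, donor
probability 0.25, exponential waiting times with mean 0.4 years,
uniform censoring on (0, 11) years, t\* = τ = 5):

```sh
wpvsurv simulate A --n 1000 --seed 2 --out cohortA.csv
wpvsurv fit cohortA.csv --t-star 5 --tau 5 --method wpv --out wpv_out
```

prints

```
method: wpv
n = 1000 (no donor 142, donor 207, unknown 651)
clusters: 1000
S0(t*) = 0.3247  (95% CI 0.2884-0.3615)
S1(t*) = 0.4096  (95% CI 0.3489-0.4693)
cHR    = 0.7935  (95% CI 0.6570-0.9584; p = 0.01634)
beta0  = 0.117631 (se 0.051113)
beta1  = -0.231251 (se 0.096303)
expected group sizes: donor 263.30, no donor 736.70
```

Only 207 of 1000 patients have an *observed* donor identification, and
for 651 the search was ceased or censored. The weighted allocation
reconstructs an expected 263 donor-available patients; estimated 5-year
survival is 32.5% without and 41.0% with an available donor, and the
cumulative hazard ratio 0.79 (CI excluding 1) indicates a long-term
benefit. The generating truth for this scenario is S₀ = 0.313,
S₁ = 0.385, cHR = 0.821. The same library interface is available in
Python via `wpvsurv.wpv_fit`, `wpvsurv.gpv_fit`,
`wpvsurv.simulate_cohort` and `wpvsurv.run_replications`.

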