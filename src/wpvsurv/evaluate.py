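"""Replicated-simulation harness: bias and confidence-interval coverage.

Bias is reported on the link scale — the scale of the fitted parameters
``beta0 = log(-log S0)`` and ``beta1 = log cHR`` — with probability-scale
bias as secondary output.  Empirical coverage of the nominal-level Wald
intervals is judged against the band between the 0.025 and 0.975
quantiles of a Binomial(R, level) distribution divided by R: a true
level-``level`` interval falls inside that band with probability 0.95
over R replicates, so coverage below/above it indicates a
liberal/conservative interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import gpv_fit, wpv_fit
from .simulate import ScenarioSpec, observed_cohort, simulate_cohort, true_values
from .survdata import StudyConfig

__all__ = [
    "ReplicationResult",
    "CoverageSummary",
    "EvaluationError",
    "replicate_seed",
    "run_replications",
    "summarise",
    "binomial_band",
]

#: per-scenario cap on the tolerated fraction of failed replicates
MAX_FAILURE_FRACTION = 0.05


class EvaluationError(RuntimeError):
    """Too many replicates failed — scenario/estimator mismatch signal."""


def replicate_seed(base_seed: int, r: int) -> np.random.SeedSequence:
    """Deterministic per-replicate seed derivation from a base seed."""
    return np.random.SeedSequence(entropy=int(base_seed), spawn_key=(int(r),))


@dataclass(frozen=True)
class ReplicationResult:
    """Per-replicate estimates with the scenario truth attached."""

    scenario: str
    method: str
    n: int
    R: int
    ci_level: float
    truth: dict  #: S0, S1, cHR, beta0, beta1 (generative values)
    estimates: pd.DataFrame  #: one row per successful replicate
    failures: tuple[tuple[int, str], ...]  #: (replicate index, message)


@dataclass(frozen=True)
class CoverageSummary:
    """Bias, Monte-Carlo SEs, empirical coverage and the binomial band."""

    scenario: str
    method: str
    n: int
    R: int
    R_used: int
    level: float
    band: tuple[float, float]
    bias: dict         #: parameter -> mean(estimate) - truth (link scale first)
    mcse: dict         #: parameter -> Monte-Carlo SE of the mean estimate
    coverage: dict     #: parameter -> fraction of CIs containing truth
    n_failures: int

    def table(self) -> pd.DataFrame:
        params = sorted(set(self.bias) | set(self.coverage))
        return pd.DataFrame(
            {
                "bias": [self.bias.get(p, np.nan) for p in params],
                "mcse": [self.mcse.get(p, np.nan) for p in params],
                "coverage": [self.coverage.get(p, np.nan) for p in params],
            },
            index=params,
        )


def binomial_band(R: int, level: float) -> tuple[float, float]:
    """(0.025, 0.975) quantiles of Binomial(R, level), divided by R."""
    lo = stats.binom.ppf(0.025, R, level) / R
    hi = stats.binom.ppf(0.975, R, level) / R
    return float(lo), float(hi)


def run_replications(
    spec: ScenarioSpec,
    config: StudyConfig,
    method: str,
    R: int,
    base_seed: int,
    ci_level: float = 0.95,
) -> ReplicationResult:
    """Fit ``method`` on ``R`` independent cohorts from ``spec``.

    Replicate ``r`` uses the seed derived by :func:`replicate_seed`, so
    WPV and GPV runs with the same base seed see identical cohorts.
    Failed replicates are recorded, not silently dropped; more than
    ``MAX_FAILURE_FRACTION`` of failures raises :class:`EvaluationError`.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if method not in ("wpv", "gpv"):
        raise ValueError(f"method must be 'wpv' or 'gpv', got {method!r}")
    fitter = wpv_fit if method == "wpv" else gpv_fit

    s0, s1, chr_true = true_values(spec, config)
    truth = {
        "S0": s0,
        "S1": s1,
        "cHR": chr_true,
        "beta0": math.log(-math.log(s0)),
        "beta1": math.log(chr_true),
    }

    rows = []
    failures: list[tuple[int, str]] = []
    for r in range(R):
        cohort = observed_cohort(
            simulate_cohort(spec, config, replicate_seed(base_seed, r))
        )
        try:
            fit, _report = fitter(cohort, config, ci_level)
        except Exception as exc:  # degenerate cohort for this estimator
            failures.append((r, f"{type(exc).__name__}: {exc}"))
            continue
        eta1 = fit.beta0 + fit.beta1
        var_eta1 = fit.cov[0, 0] + fit.cov[1, 1] + 2.0 * fit.cov[0, 1]
        rows.append(
            {
                "replicate": r,
                "beta0": fit.beta0,
                "beta1": fit.beta1,
                "eta1": eta1,
                "se_beta0": fit.beta0_se,
                "se_beta1": fit.beta1_se,
                "se_eta1": math.sqrt(max(var_eta1, 0.0)),
                "S0": fit.S0_hat,
                "S1": fit.S1_hat,
                "cHR": fit.cHR,
            }
        )
    if len(failures) > MAX_FAILURE_FRACTION * R:
        raise EvaluationError(
            f"{len(failures)}/{R} replicates failed for method {method!r} on "
            f"scenario {spec.label!r}; first: {failures[0][1]}"
        )
    return ReplicationResult(
        scenario=spec.label,
        method=method,
        n=spec.n,
        R=R,
        ci_level=ci_level,
        truth=truth,
        estimates=pd.DataFrame(rows),
        failures=tuple(failures),
    )


def summarise(result: ReplicationResult, level: float | None = None) -> CoverageSummary:
    """Bias, Monte-Carlo SE and empirical CI coverage per parameter.

    Coverage uses the link-scale Wald intervals (the back-transformed
    probability/ratio intervals cover if and only if these do, the maps
    being monotone).  The binomial band is computed for the number of
    *successful* replicates.
    """
    if level is None:
        level = result.ci_level
    est = result.estimates
    if len(est) < 2:
        raise ValueError("need at least 2 successful replicates to summarise")
    truth = result.truth
    zq = stats.norm.ppf(0.5 + level / 2.0)

    eta1_true = math.log(-math.log(truth["S1"]))
    bias, mcse, coverage = {}, {}, {}
    link_targets = {
        "beta0": ("beta0", "se_beta0", truth["beta0"]),
        "beta1": ("beta1", "se_beta1", truth["beta1"]),
        "eta1": ("eta1", "se_eta1", eta1_true),
    }
    for name, (col, se_col, tval) in link_targets.items():
        e = est[col].to_numpy()
        se = est[se_col].to_numpy()
        bias[name] = float(e.mean() - tval)
        mcse[name] = float(e.std(ddof=1) / math.sqrt(len(e)))
        lo, hi = e - zq * se, e + zq * se
        coverage[name] = float(((lo <= tval) & (tval <= hi)).mean())

    # probability/ratio-scale bias, secondary output
    for name in ("S0", "S1", "cHR"):
        e = est[name].to_numpy()
        bias[name] = float(e.mean() - truth[name])
        mcse[name] = float(e.std(ddof=1) / math.sqrt(len(e)))

    return CoverageSummary(
        scenario=result.scenario,
        method=result.method,
        n=result.n,
        R=result.R,
        R_used=len(est),
        level=level,
        band=binomial_band(len(est), level),
        bias=bias,
        mcse=mcse,
        coverage=coverage,
        n_failures=len(result.failures),
    )
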