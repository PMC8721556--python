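"""Product-limit estimation and jackknife pseudo-values at a fixed horizon.

The pseudo-value of patient ``i`` at ``t*`` is the jackknife quantity

    V_i(t*) = n * S(t*) - (n - 1) * S^{-i}(t*),

where ``S`` is the Kaplan–Meier estimate on the full sample and
``S^{-i}`` the estimate with patient ``i`` removed.  Its conditional
expectation approximates the survival indicator ``1{T_i > t*}``, which
is what lets censored survival data be fed into an ordinary regression.

Tie convention: events precede censorings at identical times, and the
risk set at ``t`` contains every subject with observed time ``>= t``.
``S`` is right-continuous (events at exactly ``t`` are included in
``S(t)``) and is carried forward beyond the last observed time.

Two computational paths exist: a vectorised O(n log n) path based on the
leave-one-out update of the product-limit factors (used everywhere), and
a brute-force path recomputing ``n + 1`` Kaplan–Meier fits (the test
oracle, and the fallback for the rare degenerate factor patterns where
the log-space update is undefined).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SurvivalSample",
    "StepSurvival",
    "PseudoValueSet",
    "SmallRiskSetWarning",
    "km_curve",
    "km_estimate",
    "pseudo_values",
    "pseudo_values_bruteforce",
    "loo_km_estimate",
    "pseudo_value_single",
    "direct_transition_sample",
    "direct_transition_pseudo_values",
    "km_table",
    "km_cumlog",
]

#: default minimum risk-set size at the horizon before a warning is raised;
#: the asymptotics behind pseudo-values need the risk set at t* to be
#: "sufficiently large", which is a qualitative condition — this floor only
#: flags clearly degenerate horizons.
DEFAULT_RISK_SET_FLOOR = 5


class SmallRiskSetWarning(UserWarning):
    """Risk set at the evaluation horizon is suspiciously small."""


@dataclass(frozen=True)
class SurvivalSample:
    """Right-censored durations with binary event indicators."""

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events, dtype=int)
        if times.ndim != 1 or events.ndim != 1 or times.size != events.size:
            raise ValueError("times and events must be 1-d arrays of equal length")
        if times.size and times.min() < 0:
            raise ValueError("times must be non-negative")
        if not np.isin(events, (0, 1)).all():
            raise ValueError("events must be 0/1")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events)

    @property
    def n(self) -> int:
        return int(self.times.size)

    def drop(self, i: int) -> "SurvivalSample":
        """Sample with subject ``i`` removed (for the jackknife oracle)."""
        keep = np.ones(self.n, dtype=bool)
        keep[i] = False
        return SurvivalSample(self.times[keep], self.events[keep])


class StepSurvival:
    """Right-continuous non-increasing step function with S(0-) = 1.

    ``jump_times`` are the (sorted) times at which the function drops;
    ``values[k]`` is the function's value on ``[jump_times[k],
    jump_times[k+1])``.  Values are carried forward beyond the last jump.
    """

    def __init__(self, jump_times, values):
        self.jump_times = np.asarray(jump_times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.jump_times.size != self.values.size:
            raise ValueError("jump_times and values must have equal length")

    def __call__(self, t):
        """Evaluate S(t) (right-continuous)."""
        t = np.asarray(t, dtype=float)
        if self.jump_times.size == 0:
            out = np.ones_like(t)
        else:
            idx = np.searchsorted(self.jump_times, t, side="right") - 1
            out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 1.0)
        return float(out) if out.ndim == 0 else out

    def left_limit(self, t):
        """Evaluate S(t-), the value just before ``t``."""
        t = np.asarray(t, dtype=float)
        if self.jump_times.size == 0:
            out = np.ones_like(t)
        else:
            idx = np.searchsorted(self.jump_times, t, side="left") - 1
            out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 1.0)
        return float(out) if out.ndim == 0 else out

    def table(self):
        """(time, value) pairs as a 2-column array, for debug dumps."""
        return np.column_stack([self.jump_times, self.values])


@dataclass(frozen=True)
class PseudoValueSet:
    """Per-subject jackknife pseudo-values at a fixed horizon ``t_star``.

    Values may legitimately fall outside [0, 1]; with no censoring before
    ``t_star`` they are exactly the survival indicators.
    """

    t_star: float
    values: np.ndarray
    km_at_tstar: float
    risk_set_size_at_tstar: int
    warnings: tuple[str, ...] = ()


def km_table(sample: SurvivalSample):
    """Distinct observed times with at-risk counts and death counts.

    Returns ``(times, n_at_risk, deaths)`` over the distinct observed
    times, using the convention that everybody with observed time
    ``>= t`` is at risk at ``t``.
    """
    if sample.n == 0:
        raise ValueError("empty sample")
    order = np.argsort(sample.times, kind="stable")
    t = sample.times[order]
    e = sample.events[order]
    uniq, idx = np.unique(t, return_index=True)
    deaths = np.add.reduceat(e.astype(float), idx)
    n_at_risk = (t.size - idx).astype(float)
    return uniq, n_at_risk, deaths


def km_curve(sample: SurvivalSample) -> StepSurvival:
    """Kaplan–Meier survival curve as a right-continuous step function."""
    uniq, n_at_risk, deaths = km_table(sample)
    has_event = deaths > 0
    factors = 1.0 - deaths[has_event] / n_at_risk[has_event]
    return StepSurvival(uniq[has_event], np.cumprod(factors))


def km_estimate(sample: SurvivalSample, t: float) -> float:
    """Product-limit estimate S(t); events at exactly ``t`` are included."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return float(km_curve(sample)(t))


def loo_km_estimate(sample: SurvivalSample, i: int, t: float) -> float:
    """Kaplan–Meier estimate at ``t`` with subject ``i`` removed."""
    return km_estimate(sample.drop(i), t)


def pseudo_value_single(sample: SurvivalSample, i: int, t: float) -> float:
    """Brute-force jackknife pseudo-value of subject ``i`` at horizon ``t``."""
    n = sample.n
    return n * km_estimate(sample, t) - (n - 1) * loo_km_estimate(sample, i, t)


def pseudo_values_bruteforce(sample: SurvivalSample, t_star: float) -> np.ndarray:
    """O(n^2) pseudo-values by recomputing n + 1 Kaplan–Meier fits."""
    n = sample.n
    s_full = km_estimate(sample, t_star)
    return np.array(
        [n * s_full - (n - 1) * loo_km_estimate(sample, i, t_star) for i in range(n)]
    )


def km_cumlog(sample: SurvivalSample, t_max: float = np.inf):
    """Event-time table with cumulative log survival factors.

    Returns ``(times, n_at_risk, deaths, cum_full, cum_red)`` over event
    times ``<= t_max``; ``cum_full`` accumulates ``log(1 - d/n)`` and
    ``cum_red`` the same with the risk set shrunk by one (the
    leave-one-out factor for a subject at risk at that time).
    Degenerate factors yield ``-inf``/``nan`` entries, which callers
    resolve by brute force.
    """
    uniq, n_at_risk, deaths = km_table(sample)
    keep = (deaths > 0) & (uniq <= t_max)
    tk = uniq[keep]
    nk = n_at_risk[keep]
    dk = deaths[keep]
    with np.errstate(divide="ignore", invalid="ignore"):
        cum_full = np.cumsum(np.log1p(-dk / nk))
        cum_red = np.cumsum(np.log1p(-dk / (nk - 1.0)))
    return tk, nk, dk, cum_full, cum_red


def _loo_log_surv(sample: SurvivalSample, t_star: float):
    """Vectorised leave-one-out log-survival at ``t_star`` for all subjects.

    Removing subject ``i`` shrinks the risk set by one at every event
    time ``<= T_i`` and, if ``i`` died, removes one death at ``T_i``;
    factors after ``T_i`` are unchanged.  Cumulative log-sums of the
    full-sample and reduced-risk-set factors give every leave-one-out
    estimate in one pass.  Entries that hit a degenerate factor (risk set
    exhausted) come back non-finite and are recomputed by brute force.
    """
    tk, nk, dk, cum_full, cum_red = km_cumlog(sample, t_star)
    if tk.size == 0:  # no events up to the horizon: S = S^{-i} = 1
        return np.zeros(sample.n), 1.0

    log_s_star = cum_full[-1]

    Ti = sample.times
    Ei = sample.events
    # last event time <= min(T_i, t_star): tk only contains times <= t_star,
    # so a plain search against T_i does the min automatically
    pos = np.searchsorted(tk, Ti, side="right") - 1
    in_range = pos >= 0
    safe = np.clip(pos, 0, None)
    full_at = np.where(in_range, cum_full[safe], 0.0)
    red_at = np.where(in_range, cum_red[safe], 0.0)
    loo = red_at + (log_s_star - full_at)

    died = (Ei == 1) & (Ti <= t_star)
    if died.any():
        j = np.searchsorted(tk, Ti[died])
        with np.errstate(divide="ignore", invalid="ignore"):
            adj = np.log1p(-(dk[j] - 1.0) / (nk[j] - 1.0)) - np.log1p(
                -dk[j] / (nk[j] - 1.0)
            )
        loo[died] = loo[died] + adj
    return loo, (np.exp(log_s_star) if np.isfinite(log_s_star) else 0.0)


def pseudo_values(
    sample: SurvivalSample,
    t_star: float,
    *,
    risk_set_floor: int = DEFAULT_RISK_SET_FLOOR,
) -> PseudoValueSet:
    """Jackknife pseudo-values ``n S(t*) - (n-1) S^{-i}(t*)`` for all subjects.

    Uses the O(n log n) leave-one-out update; agrees with
    :func:`pseudo_values_bruteforce` to floating tolerance.  A warning is
    recorded (and emitted as :class:`SmallRiskSetWarning`) when the risk
    set at ``t_star`` falls below ``risk_set_floor``, including the empty
    case where the estimate is carried forward from the last observation.
    """
    if sample.n < 2:
        raise ValueError("pseudo-values need a sample of size >= 2")
    if not (t_star > 0):
        raise ValueError("t_star must be > 0")

    n = sample.n
    if not ((sample.events == 0) & (sample.times <= t_star)).any():
        # no censoring up to the horizon (a censoring tied exactly at t*
        # still sits in every risk set and breaks the identity): the
        # jackknife collapses to the survival indicator, returned exactly
        values = (sample.times > t_star).astype(float)
        s_star = float(values.mean())
    else:
        loo_log, s_star = _loo_log_surv(sample, t_star)
        with np.errstate(over="ignore"):
            values = n * s_star - (n - 1) * np.exp(loo_log)

        bad = ~np.isfinite(values)
        if bad.any():
            # degenerate factor pattern (risk set exhausted at an event
            # time); recompute just those subjects exactly
            s_full = km_estimate(sample, t_star)
            for i in np.where(bad)[0]:
                values[i] = n * s_full - (n - 1) * loo_km_estimate(
                    sample, int(i), t_star
                )

    risk_size = int((sample.times >= t_star).sum())
    notes: list[str] = []
    if risk_size == 0:
        notes.append(
            f"risk set empty at t*={t_star}: Kaplan-Meier value carried "
            "forward from the last observed time"
        )
    if risk_size < risk_set_floor:
        msg = (
            f"risk set at t*={t_star} has only {risk_size} subject(s) "
            f"(floor {risk_set_floor}); pseudo-values may be unstable"
        )
        notes.append(msg)
        warnings.warn(msg, SmallRiskSetWarning, stacklevel=2)

    return PseudoValueSet(
        t_star=float(t_star),
        values=values,
        km_at_tstar=float(s_star),
        risk_set_size_at_tstar=risk_size,
        warnings=tuple(notes),
    )


def direct_transition_sample(records, config) -> SurvivalSample:
    """Outcome sample for the *direct* (never-identified) transition risk.

    Donor-identified patients are censored at their identification times
    ``w_j``; everyone else keeps the observed outcome.  The Kaplan–Meier
    curve of this sample estimates survival against a direct transition
    to the event state, i.e. the no-donor path.
    """
    from .survdata import SearchEndReason

    times = np.empty(len(records))
    events = np.empty(len(records), dtype=int)
    for k, r in enumerate(records):
        if r.search_end_reason is SearchEndReason.IDENTIFIED:
            times[k] = r.ident_time
            events[k] = 0
        else:
            times[k] = r.outcome_time
            events[k] = r.outcome_event
    return SurvivalSample(times, events)


def direct_transition_pseudo_values(records, config, **kwargs) -> PseudoValueSet:
    """Pseudo-values at ``t_star`` on the direct-transition sample."""
    sample = direct_transition_sample(records, config)
    return pseudo_values(sample, config.t_star, **kwargs)
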