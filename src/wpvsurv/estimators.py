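"""Assembly of the WPV and GPV regression datasets and end-to-end fits.

Both estimators compare long-term survival at ``t*`` between patients
with and without an available stem-cell donor when a ceased donor search
leaves membership unknown for some patients.

**WPV (weighted pseudo-values).**  Common jackknife pseudo-values are
computed once on the raw outcome sample of all ``n`` patients.  Patients
with known membership enter the regression once with weight 1 in their
group; each unknown-membership patient enters *twice* — once in the
donor group with weight ``p_i`` (the probability a donor would still
have been identified by ``tau``) and once in the no-donor group with
weight ``q_i = 1 - p_i`` — sharing a cluster id so the sandwich treats
the duplicated rows as one patient.  The grand total weight is exactly
``n``.

**GPV (generalised pseudo-values).**  The no-donor arm uses pseudo-values
of the direct-transition sample (donor-identified patients censored at
``w_j``), weight 1.  The donor arm uses, per identified patient ``j``,
the direct-transition Kaplan–Meier at the identification time multiplied
by ``j``'s jackknife pseudo-value computed *within the risk set at
``w_j``* (all patients event-free and uncensored there), so that its
conditional expectation targets the donor path ``S1(t*|w_j)``; the
inverse-probability-of-censoring weight ``omega_j`` compensates for
identifications never observed because of search-ceasing events or
censoring.  Every identification time defines its own starting point and
risk set, which is what makes GPV the slower of the two estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import pv_regression
from .donor_probability import (
    fit_ceasing_curve,
    fit_identification_curve,
    gpv_weights,
    membership_probabilities,
)
from .kaplan_meier import (
    SurvivalSample,
    direct_transition_sample,
    km_cumlog,
    pseudo_values,
)
from .pv_regression import FitResult, ResponseRow
from .survdata import GroupStatus, StudyConfig, cohort_counts, derive_group_status

__all__ = ["AssemblyReport", "wpv_fit", "gpv_fit", "expected_group_sizes"]


@dataclass(frozen=True)
class AssemblyReport:
    """Bookkeeping of one regression dataset: rows, weights, counts."""

    method: str  #: "wpv" or "gpv"
    rows: tuple[ResponseRow, ...]
    n: int
    n_N: int
    m: int
    n_C: int
    total_weight_z0: float
    total_weight_z1: float
    expected_donor_count: float | None = None     #: m + sum p (WPV only)
    expected_no_donor_count: float | None = None  #: n_N + sum q (WPV only)


def expected_group_sizes(report: AssemblyReport) -> tuple[float, float]:
    """WPV-expected latent group sizes ``(m + sum p, n_N + sum q)``.

    These reconstruct how many patients are expected to belong to each
    group once the unknown-membership patients are allocated; they sum
    to ``n``.
    """
    if report.method != "wpv":
        raise ValueError("expected group sizes are defined for WPV reports only")
    return report.expected_donor_count, report.expected_no_donor_count


def wpv_fit(
    records, config: StudyConfig, ci_level: float = 0.95
) -> tuple[FitResult, AssemblyReport]:
    """Weighted pseudo-value fit of the two-group survival comparison.

    With no unknown-membership patients this reduces exactly to a plain
    two-group pseudo-value analysis.  Unknown patients with degenerate
    probabilities (``p in {0, 1}``) keep their zero-weight twin row so
    the row count is always ``n + n_C``.
    """
    records = list(records)
    n = len(records)
    n_N, m, n_C = cohort_counts(records)

    sample = SurvivalSample(
        np.array([r.outcome_time for r in records]),
        np.array([r.outcome_event for r in records]),
    )
    pvs = pseudo_values(sample, config.t_star)

    unknown = [r for r in records if derive_group_status(r) is GroupStatus.UNKNOWN]
    if unknown:
        curve = fit_identification_curve(records, config)
        memb = membership_probabilities(curve, unknown, config)
        p_by_id = dict(zip(memb.subject_ids, memb.p_hat))
    else:
        p_by_id = {}

    rows: list[ResponseRow] = []
    sum_p = 0.0
    for r, v in zip(records, pvs.values):
        status = derive_group_status(r)
        if status is GroupStatus.NO_DONOR:
            rows.append(ResponseRow(float(v), 1.0, 0, r.subject_id))
        elif status is GroupStatus.DONOR:
            rows.append(ResponseRow(float(v), 1.0, 1, r.subject_id))
        else:
            p = float(p_by_id[r.subject_id])
            sum_p += p
            rows.append(ResponseRow(float(v), 1.0 - p, 0, r.subject_id))
            rows.append(ResponseRow(float(v), p, 1, r.subject_id))

    report = AssemblyReport(
        method="wpv",
        rows=tuple(rows),
        n=n,
        n_N=n_N,
        m=m,
        n_C=n_C,
        total_weight_z0=sum(r.weight for r in rows if r.z == 0),
        total_weight_z1=sum(r.weight for r in rows if r.z == 1),
        expected_donor_count=m + sum_p,
        expected_no_donor_count=n_N + (n_C - sum_p),
    )
    result = pv_regression.fit(rows, ci_level)
    return result, report


def _conditional_pseudo_value_single(
    sample: SurvivalSample, idx_in_subset_sample, w: float, t_star: float
) -> float:
    """Brute-force conditional pseudo-value of one subject (fallback path)."""
    keep = sample.times >= w
    sub = SurvivalSample(sample.times[keep], sample.events[keep])
    pos = int(np.flatnonzero(np.flatnonzero(keep) == idx_in_subset_sample)[0])
    n_j = sub.n
    from .kaplan_meier import km_estimate, loo_km_estimate

    if n_j == 1:
        return km_estimate(sub, t_star)
    return n_j * km_estimate(sub, t_star) - (n_j - 1) * loo_km_estimate(
        sub, pos, t_star
    )


def _gpv_donor_values(
    sample: SurvivalSample,
    dsample: SurvivalSample,
    donor_idx,
    entry,
    exit_,
    d_events,
    t_star: float,
) -> np.ndarray:
    """Donor-arm generalised pseudo-values.

    Each identified patient ``j`` gets its own round of computation with
    its own starting time and risk set:

        V_j = S^N(w_j) * [ n_j * S_{w_j}(t*) - (n_j - 1) * S_{w_j}^{-j}(t*) ],

    where ``S^N(w_j)`` is the direct-transition Kaplan–Meier at the
    identification time, ``S_{w_j}(t*)`` is the Kaplan–Meier estimate at
    ``t*`` over the ``n_j`` patients still at risk (event-free,
    uncensored) at ``w_j`` with their subsequent observed outcomes, and
    the bracket is patient ``j``'s jackknife pseudo-value *within that
    risk set*.  Its conditional expectation given ``j``'s history is the
    donor-specific conditional survival from ``w_j``, so
    ``S^N(w_j) x bracket`` targets ``S1(t*|w_j)`` even though the
    risk-set cohort mixes identified and non-identified patients.

    Because risk-set membership is ``T_i >= w_j``, the subset's
    Kaplan–Meier factors coincide with the full-sample factors at event
    times ``>= w_j``, so all ``m`` rounds reduce to cumulative passes
    over the raw outcome sample; degenerate factor patterns fall back to
    direct recomputation.
    """
    m = entry.size

    # direct-transition survival at w_j (right-continuous)
    tk_d, _nk_d, _dk_d, cfull_d, _cred_d = km_cumlog(dsample)
    pos = np.searchsorted(tk_d, entry, side="right") - 1
    log_sn = np.where(pos >= 0, cfull_d[np.clip(pos, 0, None)], 0.0)

    # conditional pseudo-value of j within the risk set at w_j, built from
    # the raw outcome sample: factors at event times in [w_j, t*]
    tk, nk, dk, cum_full, cum_red = km_cumlog(sample, t_star)
    a_star = cum_full[-1] if tk.size else 0.0
    b_star = cum_red[-1] if tk.size else 0.0

    def _before(cum, t):
        """Cumulative log just *before* time t (factors at times < t)."""
        p = np.searchsorted(tk, t, side="left") - 1
        return np.where(p >= 0, cum[np.clip(p, 0, None)], 0.0)

    def _through(cum, t):
        """Cumulative log through time t (factors at times <= t)."""
        p = np.searchsorted(tk, t, side="right") - 1
        return np.where(p >= 0, cum[np.clip(p, 0, None)], 0.0)

    times_sorted = np.sort(sample.times)
    n_j = sample.n - np.searchsorted(times_sorted, entry, side="left")

    log_p = a_star - _before(cum_full, entry)
    cut = np.minimum(exit_, t_star)
    # j at risk at event times in [w_j, T_j]; full factors beyond T_j
    log_p_loo = (
        (_through(cum_red, cut) - _before(cum_red, entry))
        + (a_star - _through(cum_full, cut))
    )
    died = (d_events == 1) & (exit_ <= t_star)
    if died.any():
        jj = np.searchsorted(tk, exit_[died])
        with np.errstate(divide="ignore", invalid="ignore"):
            adj = np.log1p(-(dk[jj] - 1.0) / (nk[jj] - 1.0)) - np.log1p(
                -dk[jj] / (nk[jj] - 1.0)
            )
        log_p_loo[died] = log_p_loo[died] + adj

    with np.errstate(over="ignore", invalid="ignore"):
        v_cond = n_j * np.exp(log_p) - (n_j - 1) * np.exp(log_p_loo)
        values = np.exp(log_sn) * v_cond

    bad = ~np.isfinite(values)
    for k in np.where(bad)[0]:
        v_c = _conditional_pseudo_value_single(
            sample, int(donor_idx[k]), float(entry[k]), t_star
        )
        values[k] = np.exp(log_sn[k]) * v_c
    return values


def gpv_fit(
    records, config: StudyConfig, ci_level: float = 0.95
) -> tuple[FitResult, AssemblyReport]:
    """Generalised pseudo-value fit (the comparator estimator).

    Computationally heavier than WPV: every identified patient needs its
    own pseudo-value horizon ``w_j`` and risk-set redefinition.
    """
    records = list(records)
    n = len(records)
    n_N, m, n_C = cohort_counts(records)
    if m < 1:
        raise pv_regression.FitError(
            "GPV requires at least one donor-identified patient (z=1 arm empty)"
        )

    dsample = direct_transition_sample(records, config)
    pvs_n = pseudo_values(dsample, config.t_star)

    rows: list[ResponseRow] = [
        ResponseRow(float(v), 1.0, 0, r.subject_id)
        for r, v in zip(records, pvs_n.values)
    ]

    ceasing = fit_ceasing_curve(records, config)
    omega = gpv_weights(ceasing, records)

    donor_idx = np.array(
        [
            i
            for i, r in enumerate(records)
            if derive_group_status(r) is GroupStatus.DONOR
        ],
        dtype=int,
    )
    entry = np.array([records[i].ident_time for i in donor_idx], dtype=float)
    exit_ = np.array([records[i].outcome_time for i in donor_idx], dtype=float)
    d_events = np.array([records[i].outcome_event for i in donor_idx], dtype=int)

    sample = SurvivalSample(
        np.array([r.outcome_time for r in records]),
        np.array([r.outcome_event for r in records]),
    )
    v_d = _gpv_donor_values(
        sample, dsample, donor_idx, entry, exit_, d_events, config.t_star
    )
    for k, idx in enumerate(donor_idx):
        r = records[idx]
        rows.append(ResponseRow(float(v_d[k]), omega[r.subject_id], 1, r.subject_id))

    report = AssemblyReport(
        method="gpv",
        rows=tuple(rows),
        n=n,
        n_N=n_N,
        m=m,
        n_C=n_C,
        total_weight_z0=sum(row.weight for row in rows if row.z == 0),
        total_weight_z1=sum(row.weight for row in rows if row.z == 1),
    )
    result = pv_regression.fit(rows, ci_level)
    return result, report
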