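"""Waiting-time distribution of donor identification and derived weights.

Two Kaplan–Meier curves over the *search* histories drive the weighting:

* ``G`` — survival function of the time ``W`` to donor identification,
  where search-ceasing events and censoring are treated as non-informative
  censoring (the external-covariate assumption: the latent donor exists
  whether or not the patient survives the search).
* ``K`` — survival function of the time to search-ceasing-or-censoring,
  where identifications are the censorings instead.

From ``G``, a patient whose search was ceased at ``C_i < tau`` gets the
membership probability

    p_i = P(W <= tau | W > C_i) = 1 - G(tau) / G(C_i),

the probability that a donor would still have been identified by ``tau``;
``q_i = 1 - p_i`` is the probability of belonging to the no-donor group.
From ``K``, each identified patient gets the inverse-probability-of-
censoring weight ``omega_j = 1 / K(w_j-)`` that reconstructs the
waiting-time distribution despite unobserved transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kaplan_meier import SurvivalSample, StepSurvival, km_curve
from .survdata import GroupStatus, SearchEndReason, StudyConfig, derive_group_status

__all__ = [
    "IdentificationCurve",
    "CeasingCurve",
    "MembershipProbabilities",
    "fit_identification_curve",
    "fit_ceasing_curve",
    "membership_probabilities",
    "gpv_weights",
    "waiting_time_allocation",
]


@dataclass(frozen=True)
class IdentificationCurve:
    """Kaplan–Meier survival function of time to donor identification."""

    curve: StepSurvival
    max_followed: float  #: latest search time observed (any reason)

    def __call__(self, t):
        return self.curve(t)

    def left_limit(self, t):
        return self.curve.left_limit(t)


@dataclass(frozen=True)
class CeasingCurve:
    """Kaplan–Meier survival function of time to search ceasing/censoring."""

    curve: StepSurvival

    def __call__(self, t):
        return self.curve(t)

    def left_limit(self, t):
        return self.curve.left_limit(t)


@dataclass(frozen=True)
class MembershipProbabilities:
    """Donor-group membership probabilities for unknown-status patients."""

    subject_ids: tuple[str, ...]
    p_hat: np.ndarray  #: probability of belonging to the donor group
    warnings: tuple[str, ...] = ()

    @property
    def q_hat(self) -> np.ndarray:
        return 1.0 - self.p_hat


def _search_sample(records, config: StudyConfig, *, event_reasons) -> SurvivalSample:
    times = np.empty(len(records))
    events = np.empty(len(records), dtype=int)
    for k, r in enumerate(records):
        times[k] = r.search_end_time
        events[k] = int(r.search_end_reason in event_reasons)
    return SurvivalSample(times, events)


def fit_identification_curve(records, config: StudyConfig) -> IdentificationCurve:
    """Fit ``G``: identifications are events; everything else censors.

    Patients whose search completed at ``tau`` are censored at ``tau``;
    ceased/censored searches censor at their (earlier) end times.
    """
    if not records:
        raise ValueError("cannot fit identification curve on an empty cohort")
    sample = _search_sample(
        records, config, event_reasons=(SearchEndReason.IDENTIFIED,)
    )
    return IdentificationCurve(
        curve=km_curve(sample), max_followed=float(sample.times.max())
    )


def fit_ceasing_curve(records, config: StudyConfig) -> CeasingCurve:
    """Fit ``K``: search-ceasing events *and* censoring count as events;
    identifications censor at ``w_j``; completed searches censor at ``tau``."""
    if not records:
        raise ValueError("cannot fit ceasing curve on an empty cohort")
    sample = _search_sample(
        records,
        config,
        event_reasons=(SearchEndReason.CEASED, SearchEndReason.CENSORED),
    )
    return CeasingCurve(curve=km_curve(sample))


def membership_probabilities(
    curve: IdentificationCurve, records, config: StudyConfig
) -> MembershipProbabilities:
    """``p_i = 1 - G(tau) / G(C_i)`` for every unknown-status patient.

    ``G`` is evaluated right-continuously at the ceasing time ``C_i`` (an
    identification tied exactly at ``C_i`` counts as having happened
    before the ceasing).  ``p_i`` is clipped to [0, 1] against floating
    error and forced to 1 where a donor was in fact found after the
    search had been ceased (``late_donor_flag``).
    """
    notes: list[str] = []
    g_tau = float(curve(config.tau))
    if curve.max_followed < config.tau:
        notes.append(
            f"no search history reaches tau={config.tau}; G(tau) carried "
            f"forward from {curve.max_followed}"
        )

    ids: list[str] = []
    p: list[float] = []
    for r in records:
        status = derive_group_status(r)
        if status is not GroupStatus.UNKNOWN:
            raise ValueError(
                f"subject {r.subject_id!r} has known status {status.value!r}; "
                "membership probabilities apply only to unknown-status patients"
            )
        g_c = float(curve(r.search_end_time))
        if g_c <= 0.0:
            raise ValueError(
                f"subject {r.subject_id!r}: G({r.search_end_time}) = 0, "
                "membership probability undefined"
            )
        if r.late_donor_flag:
            p_i = 1.0
        else:
            p_i = float(np.clip(1.0 - g_tau / g_c, 0.0, 1.0))
        ids.append(r.subject_id)
        p.append(p_i)
    return MembershipProbabilities(
        subject_ids=tuple(ids), p_hat=np.asarray(p), warnings=tuple(notes)
    )


def gpv_weights(curve: CeasingCurve, records) -> dict[str, float]:
    """IPC weights ``omega_j = 1 / K(w_j-)`` for donor-identified patients.

    The left limit is used: a patient identified at ``w_j`` was
    necessarily still search-active at ``w_j``, so only strictly earlier
    ceasings/censorings inform the weight.  ``omega_j >= 1`` always.
    """
    out: dict[str, float] = {}
    offending = []
    for r in records:
        if derive_group_status(r) is not GroupStatus.DONOR:
            continue
        k_left = float(curve.left_limit(r.ident_time))
        if k_left <= 0.0:
            offending.append((r.subject_id, r.ident_time))
            continue
        out[r.subject_id] = 1.0 / k_left
    if offending:
        raise ValueError(
            "K(w-) = 0 for identification time(s) "
            + ", ".join(f"{sid}@{w}" for sid, w in offending)
        )
    return out


def waiting_time_allocation(
    curve: IdentificationCurve, search_end_time: float, config: StudyConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Apportion a ceased patient's membership probability over waiting times.

    Returns the identification-curve jump times in ``(C_i, tau]`` and the
    probability mass assigned to each: ``[G(t-) - G(t)] / G(C_i)``.  The
    masses sum to ``p_i``; they let the expected group frequency be
    reconstructed per waiting time (used e.g. with discrete waiting-time
    designs).
    """
    g_c = float(curve(search_end_time))
    if g_c <= 0.0:
        raise ValueError(f"G({search_end_time}) = 0, allocation undefined")
    jumps = curve.curve.jump_times
    vals = curve.curve.values
    prev = np.concatenate([[1.0], vals[:-1]])
    mask = (jumps > search_end_time) & (jumps <= config.tau)
    return jumps[mask], (prev[mask] - vals[mask]) / g_c
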