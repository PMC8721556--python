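"""Domain types, tabular I/O and validation for donor-search survival cohorts.

A cohort is one row per patient with two parallel histories on the
study-entry time scale (years):

* the *outcome* history — time to the outcome-related event (death,
  relapse, or a composite) or to censoring; and
* the *donor-search* history — the search for a suitable stem-cell donor,
  which ends by identification of a donor at waiting time ``W``, by
  reaching the maximum search time ``tau`` without success, or
  prematurely through a search-ceasing event or censoring, in which case
  donor availability remains unknown.

Group membership (donor available / not available) is a property of the
search history only: a patient whose search is ceased or censored before
``tau`` has *unknown* membership, which is what the weighted pseudo-value
machinery downstream resolves probabilistically.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "StudyConfig",
    "SearchEndReason",
    "GroupStatus",
    "SubjectRecord",
    "CohortValidationError",
    "derive_group_status",
    "cohort_counts",
    "read_cohort",
    "write_cohort",
    "load_config",
    "save_config",
]

#: relative tolerance used when comparing recorded times against ``tau``
_TIME_RTOL = 1e-9


class CohortValidationError(ValueError):
    """A cohort file or record violates the domain invariants."""


class SearchEndReason(str, enum.Enum):
    """How the donor search ended for one patient."""

    IDENTIFIED = "identified"  #: a donor was found at ``ident_time <= tau``
    COMPLETED = "completed"    #: search ran to ``tau`` without a donor
    CEASED = "ceased"          #: a search-ceasing event occurred before ``tau``
    CENSORED = "censored"      #: follow-up ended before ``tau`` without an event


class GroupStatus(str, enum.Enum):
    """Observed donor-availability status (the covariate Z where known)."""

    DONOR = "donor"        #: Z = 1 known
    NO_DONOR = "no_donor"  #: Z = 0 known
    UNKNOWN = "unknown"    #: membership latent; search ceased or censored early


@dataclass(frozen=True)
class StudyConfig:
    """Analysis horizon and maximum donor search time, both in years.

    ``t_star`` is the pre-specified time point at which long-term survival
    is compared; ``tau`` is the time up to which a donor must be
    identified for a patient to count as "donor available".  No ordering
    between the two is imposed.
    """

    t_star: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.t_star > 0):
            raise ValueError(f"t_star must be > 0, got {self.t_star}")
        if not (self.tau > 0):
            raise ValueError(f"tau must be > 0, got {self.tau}")


@dataclass(frozen=True)
class SubjectRecord:
    """One patient's outcome follow-up plus donor-search history.

    ``ident_time`` is the waiting time ``W`` until donor identification
    (``None`` unless ``search_end_reason`` is ``identified``).
    ``late_donor_flag`` marks a donor found after the search was already
    ceased; it forces the membership probability to 1 downstream but does
    not change the observed :class:`GroupStatus`.
    """

    subject_id: str
    outcome_time: float
    outcome_event: int
    search_end_time: float
    search_end_reason: SearchEndReason
    ident_time: float | None = None
    late_donor_flag: int = 0


def _close(a: float, b: float) -> bool:
    return math.isclose(a, b, rel_tol=_TIME_RTOL, abs_tol=1e-12)


def validate_record(record: SubjectRecord, config: StudyConfig) -> None:
    """Raise :class:`CohortValidationError` if ``record`` is inconsistent.

    The invariants tie the search-end reason to the recorded times:
    identification must happen at the search end and no later than
    ``tau``; a completed search ends exactly at ``tau``; ceasing and
    censoring end strictly before ``tau`` with no identification.  A
    ceasing event need not be the outcome event (e.g. relapse under an
    overall-survival endpoint), so ``search_end_time <= outcome_time`` is
    only enforced for censored searches.
    """
    r = record
    sid = r.subject_id

    def bad(msg: str) -> None:
        raise CohortValidationError(f"subject {sid!r}: {msg}")

    if not (r.outcome_time >= 0):
        bad(f"outcome_time must be >= 0, got {r.outcome_time}")
    if r.outcome_event not in (0, 1):
        bad(f"outcome_event must be 0 or 1, got {r.outcome_event}")
    if r.late_donor_flag not in (0, 1):
        bad(f"late_donor_flag must be 0 or 1, got {r.late_donor_flag}")
    if not (r.search_end_time >= 0):
        bad(f"search_end_time must be >= 0, got {r.search_end_time}")

    reason = r.search_end_reason
    if reason is SearchEndReason.IDENTIFIED:
        if r.ident_time is None:
            bad("reason 'identified' requires ident_time")
        if not _close(r.ident_time, r.search_end_time):
            bad(
                f"ident_time ({r.ident_time}) must equal search_end_time "
                f"({r.search_end_time}) when reason is 'identified'"
            )
        if r.ident_time > config.tau and not _close(r.ident_time, config.tau):
            bad(f"ident_time ({r.ident_time}) exceeds tau ({config.tau})")
    else:
        if r.ident_time is not None:
            bad(f"ident_time must be absent when reason is {reason.value!r}")
        if reason is SearchEndReason.COMPLETED:
            if not _close(r.search_end_time, config.tau):
                bad(
                    f"reason 'completed' requires search_end_time == tau "
                    f"({config.tau}), got {r.search_end_time}"
                )
        else:  # ceased / censored
            if r.search_end_time >= config.tau and not _close(
                r.search_end_time, config.tau
            ):
                bad(
                    f"reason {reason.value!r} requires search_end_time < tau "
                    f"({config.tau}), got {r.search_end_time}"
                )
            if _close(r.search_end_time, config.tau):
                bad(
                    f"reason {reason.value!r} requires search_end_time < tau; "
                    f"a search reaching tau is 'completed'"
                )
            if reason is SearchEndReason.CENSORED:
                if r.search_end_time > r.outcome_time and not _close(
                    r.search_end_time, r.outcome_time
                ):
                    bad(
                        "censored search cannot end after outcome follow-up "
                        f"({r.search_end_time} > {r.outcome_time})"
                    )


def derive_group_status(record: SubjectRecord) -> GroupStatus:
    """Map the search-end reason to the observed donor-availability status.

    Identification yields a known donor, a search completed at ``tau``
    yields a known non-donor, and a ceased or censored search leaves the
    status unknown.  ``late_donor_flag`` is deliberately ignored here; it
    is consumed only by the membership-probability step.
    """
    reason = record.search_end_reason
    if reason is SearchEndReason.IDENTIFIED:
        return GroupStatus.DONOR
    if reason is SearchEndReason.COMPLETED:
        return GroupStatus.NO_DONOR
    return GroupStatus.UNKNOWN


def cohort_counts(records: list[SubjectRecord]) -> tuple[int, int, int]:
    """Return ``(n_N, m, n_C)``: known no-donor, known donor, unknown.

    These are the three blocks of the weighting scheme; they always sum
    to the cohort size ``n``.
    """
    n_N = m = n_C = 0
    for r in records:
        status = derive_group_status(r)
        if status is GroupStatus.NO_DONOR:
            n_N += 1
        elif status is GroupStatus.DONOR:
            m += 1
        else:
            n_C += 1
    return n_N, m, n_C


_COLUMNS = [
    "subject_id",
    "outcome_time",
    "outcome_event",
    "ident_time",
    "search_end_time",
    "search_end_reason",
    "late_donor_flag",
]


def read_cohort(
    path, config: StudyConfig, *, delimiter: str = ","
) -> list[SubjectRecord]:
    """Read a delimited cohort file and validate every record.

    Required columns: ``subject_id, outcome_time, outcome_event,
    ident_time, search_end_time, search_end_reason``; ``late_donor_flag``
    is optional (default 0).  An empty ``ident_time`` field encodes a
    missing identification.  Records are returned in file order;
    duplicate subject ids are rejected.
    """
    frame = pd.read_csv(
        path, sep=delimiter, dtype={"subject_id": str}, float_precision="round_trip"
    )
    required = set(_COLUMNS) - {"late_donor_flag"}
    missing = required - set(frame.columns)
    if missing:
        raise CohortValidationError(
            f"{path}: missing required column(s) {sorted(missing)}"
        )
    if "late_donor_flag" not in frame.columns:
        frame["late_donor_flag"] = 0
    frame["late_donor_flag"] = frame["late_donor_flag"].fillna(0)

    records: list[SubjectRecord] = []
    seen: set[str] = set()
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        sid = str(row.subject_id)
        if sid in seen:
            raise CohortValidationError(
                f"{path} row {row_no}: duplicate subject_id {sid!r}"
            )
        seen.add(sid)
        try:
            reason = SearchEndReason(str(row.search_end_reason))
        except ValueError as exc:
            raise CohortValidationError(
                f"{path} row {row_no}: unknown search_end_reason "
                f"{row.search_end_reason!r}"
            ) from exc
        ident = None if pd.isna(row.ident_time) else float(row.ident_time)
        record = SubjectRecord(
            subject_id=sid,
            outcome_time=float(row.outcome_time),
            outcome_event=int(row.outcome_event),
            ident_time=ident,
            search_end_time=float(row.search_end_time),
            search_end_reason=reason,
            late_donor_flag=int(row.late_donor_flag),
        )
        try:
            validate_record(record, config)
        except CohortValidationError as exc:
            raise CohortValidationError(f"{path} row {row_no}: {exc}") from exc
        records.append(record)
    return records


def write_cohort(records: list[SubjectRecord], path, *, delimiter: str = ",") -> None:
    """Write records to a delimited file in the canonical column order."""
    frame = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "outcome_time": [r.outcome_time for r in records],
            "outcome_event": [r.outcome_event for r in records],
            "ident_time": [r.ident_time for r in records],
            "search_end_time": [r.search_end_time for r in records],
            "search_end_reason": [r.search_end_reason.value for r in records],
            "late_donor_flag": [r.late_donor_flag for r in records],
        }
    )
    frame.to_csv(path, sep=delimiter, index=False)


def load_config(path) -> StudyConfig:
    """Read a ``t_star``/``tau`` key-value (YAML) config file."""
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return StudyConfig(t_star=float(payload["t_star"]), tau=float(payload["tau"]))


def save_config(config: StudyConfig, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump({"t_star": config.t_star, "tau": config.tau}, fh)
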