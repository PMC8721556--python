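import numpy as np
import pytest

from wpvsurv.survdata import SearchEndReason, StudyConfig, SubjectRecord


def make_record(
    sid,
    outcome_time,
    outcome_event,
    reason,
    search_end_time,
    ident_time=None,
    late_donor_flag=0,
):
    return SubjectRecord(
        subject_id=sid,
        outcome_time=outcome_time,
        outcome_event=outcome_event,
        ident_time=ident_time,
        search_end_time=search_end_time,
        search_end_reason=SearchEndReason(reason),
        late_donor_flag=late_donor_flag,
    )


@pytest.fixture
def config():
    return StudyConfig(t_star=5.0, tau=3.0)


@pytest.fixture
def four_patient_cohort():
    """Identifications at 0.5 and 1.0, one search ceased at 0.7, one
    completed at tau=3; hand product-limit gives G(0.5)=3/4, G(1)=3/8."""
    return [
        make_record("a", 4.0, 0, "identified", 0.5, ident_time=0.5),
        make_record("b", 4.5, 0, "identified", 1.0, ident_time=1.0),
        make_record("c", 0.7, 1, "ceased", 0.7),
        make_record("d", 6.0, 0, "completed", 3.0),
    ]


def random_survival_data(rng, n, censor_scale=2.0, event_scale=1.5):
    """Random censored sample: exponential events vs exponential censoring."""
    t_event = rng.exponential(event_scale, n)
    t_cens = rng.exponential(censor_scale, n)
    times = np.minimum(t_event, t_cens)
    events = (t_event <= t_cens).astype(int)
    return times, events
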