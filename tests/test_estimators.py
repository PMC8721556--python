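import math
import warnings

import numpy as np
import pytest

import wpvsurv as wp
from wpvsurv.estimators import expected_group_sizes, gpv_fit, wpv_fit
from wpvsurv.kaplan_meier import SurvivalSample, pseudo_values_bruteforce
from wpvsurv.pv_regression import FitError
from wpvsurv.survdata import StudyConfig

from conftest import make_record


@pytest.fixture(autouse=True)
def _quiet_risk_set_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def known_status_cohort():
    """All memberships known: 3 donors, 3 non-donors, varied outcomes."""
    cfg = StudyConfig(t_star=3.0, tau=2.0)
    records = [
        make_record("d1", 4.0, 0, "identified", 0.5, ident_time=0.5),
        make_record("d2", 1.5, 1, "identified", 0.4, ident_time=0.4),
        make_record("d3", 3.5, 0, "identified", 1.0, ident_time=1.0),
        make_record("n1", 2.5, 1, "completed", 2.0),
        make_record("n2", 5.0, 0, "completed", 2.0),
        make_record("n3", 3.2, 0, "completed", 2.0),
    ]
    return records, cfg


class TestWPV:
    def test_reduces_to_plain_two_group_fit_without_unknowns(self):
        records, cfg = known_status_cohort()
        fit, report = wpv_fit(records, cfg)
        assert report.n_C == 0
        assert len(report.rows) == len(records)
        # group means are the plain per-group pseudo-value means
        pvs = pseudo_values_bruteforce(
            SurvivalSample(
                [r.outcome_time for r in records],
                [r.outcome_event for r in records],
            ),
            cfg.t_star,
        )
        mu1 = pvs[:3].mean()
        mu0 = pvs[3:].mean()
        assert fit.beta0 == pytest.approx(math.log(-math.log(mu0)), abs=1e-12)
        assert fit.beta1 == pytest.approx(
            math.log(-math.log(mu1)) - math.log(-math.log(mu0)), abs=1e-12
        )

    def test_bitwise_reduction_to_plain_pseudo_value_fit(self):
        """With no unknown patients WPV is exactly the plain two-group
        pseudo-value regression (same rows, same code path)."""
        from wpvsurv import pseudo_values, pv_regression
        from wpvsurv.pv_regression import ResponseRow

        records, cfg = known_status_cohort()
        fit, _ = wpv_fit(records, cfg)
        pvs = pseudo_values(
            SurvivalSample(
                [r.outcome_time for r in records],
                [r.outcome_event for r in records],
            ),
            cfg.t_star,
        )
        rows = [
            ResponseRow(float(v), 1.0, int(i < 3), r.subject_id)
            for i, (v, r) in enumerate(zip(pvs.values, records))
        ]
        plain = pv_regression.fit(rows)
        assert fit.beta0 == plain.beta0
        assert fit.beta1 == plain.beta1

    def test_uncensored_known_cohort_gives_empirical_survival(self):
        cfg = StudyConfig(t_star=2.0, tau=1.5)
        records = [
            make_record("d1", 3.0, 1, "identified", 0.5, ident_time=0.5),
            make_record("d2", 2.5, 1, "identified", 0.5, ident_time=0.5),
            make_record("d3", 1.0, 1, "identified", 0.2, ident_time=0.2),
            make_record("n1", 0.8, 1, "completed", 1.5),
            make_record("n2", 2.6, 1, "completed", 1.5),
            make_record("n3", 2.9, 1, "completed", 1.5),
            make_record("n4", 1.9, 1, "completed", 1.5),
        ]
        fit, _ = wpv_fit(records, cfg)
        assert fit.S1_hat == pytest.approx(2 / 3)
        assert fit.S0_hat == pytest.approx(2 / 4)

    def test_eight_patient_fixture_matches_hand_calculation(self):
        """End-to-end oracle: pseudo-values, membership probabilities and
        the weighted group means all recomputed independently by hand."""
        cfg = StudyConfig(t_star=4.0, tau=3.0)
        records = [
            make_record("d1", 5.0, 0, "identified", 0.5, ident_time=0.5),
            make_record("d2", 2.0, 1, "identified", 1.0, ident_time=1.0),
            make_record("n1", 4.5, 0, "completed", 3.0),
            make_record("n2", 1.5, 1, "completed", 3.0),
            make_record("n3", 6.0, 0, "completed", 3.0),
            make_record("n4", 3.0, 1, "completed", 3.0),
            make_record("u1", 0.7, 1, "ceased", 0.7),
            make_record("u2", 2.5, 0, "censored", 2.5),
        ]
        fit, report = wpv_fit(records, cfg)

        # identification curve by hand: searches at risk sorted by end time:
        # 0.5(id), 0.7(cease), 1.0(id), 2.5(cens), 3.0 x4 (completed)
        # G(0.5) = 7/8; G(1.0) = 7/8 * 5/6 = 35/48
        g_05, g_10 = 7 / 8, 35 / 48
        p_u1 = 1.0 - g_10 / g_05        # ceased at 0.7: jumps in (0.7, 3]
        p_u2 = 0.0                      # censored at 2.5: no jumps after
        assert report.expected_donor_count == pytest.approx(2 + p_u1 + p_u2)

        pvs = pseudo_values_bruteforce(
            SurvivalSample(
                [r.outcome_time for r in records],
                [r.outcome_event for r in records],
            ),
            cfg.t_star,
        )
        w1 = np.array([1, 1, 0, 0, 0, 0, p_u1, p_u2])
        w0 = np.array([0, 0, 1, 1, 1, 1, 1 - p_u1, 1 - p_u2])
        mu1 = np.dot(w1, pvs) / w1.sum()
        mu0 = np.dot(w0, pvs) / w0.sum()
        assert fit.beta0 == pytest.approx(math.log(-math.log(mu0)), abs=1e-12)
        assert fit.beta1 == pytest.approx(
            math.log(-math.log(mu1)) - math.log(-math.log(mu0)), abs=1e-12
        )

    def test_grand_total_weight_is_n(self):
        spec, cfg = wp.scenario_library()["study1"]
        records = wp.observed_cohort(wp.simulate_cohort(spec, cfg, 17))
        _fit, report = wpv_fit(records, cfg)
        total = report.total_weight_z0 + report.total_weight_z1
        assert total == pytest.approx(report.n, abs=1e-9)
        assert len(report.rows) == report.n + report.n_C

    def test_subject_order_invariance(self):
        spec, cfg = wp.scenario_library()["study1"]
        records = wp.observed_cohort(wp.simulate_cohort(spec, cfg, 23))
        fit_a, _ = wpv_fit(records, cfg)
        rng = np.random.default_rng(0)
        shuffled = list(records)
        rng.shuffle(shuffled)
        fit_b, _ = wpv_fit(shuffled, cfg)
        assert fit_b.beta0 == pytest.approx(fit_a.beta0, abs=1e-12)
        assert fit_b.beta1 == pytest.approx(fit_a.beta1, abs=1e-12)


class TestExpectedGroupSizes:
    def test_degenerate_probabilities(self):
        records, cfg = known_status_cohort()
        _fit, report = wpv_fit(records, cfg)
        donor, no_donor = expected_group_sizes(report)
        assert donor == pytest.approx(report.m)
        assert no_donor == pytest.approx(report.n_N + report.n_C)

    def test_rejects_gpv_report(self):
        records, cfg = known_status_cohort()
        _fit, report = gpv_fit(records, cfg)
        with pytest.raises(ValueError):
            expected_group_sizes(report)

    def test_recovers_latent_counts_in_large_cohort(self):
        import dataclasses

        spec, cfg = wp.scenario_library()["study1"]
        spec = dataclasses.replace(spec, n=8000)
        latents = wp.simulate_cohort(spec, cfg, 31)
        _fit, report = wpv_fit(wp.observed_cohort(latents), cfg)
        donor_expected, no_donor_expected = expected_group_sizes(report)
        true_donor = sum(lr.has_donor for lr in latents)
        # Monte-Carlo error of a binomial count at this n is ~40
        assert donor_expected == pytest.approx(true_donor, abs=150)
        assert donor_expected + no_donor_expected == pytest.approx(spec.n)


class TestGPV:
    def test_hand_computed_donor_values_no_prior_events(self):
        """No events before either identification: the direct-transition
        factor is 1 and each donor value is its conditional jackknife
        pseudo-value within the risk set at w (all computed by hand)."""
        cfg = StudyConfig(t_star=3.0, tau=2.0)
        records = [
            make_record("d1", 4.0, 0, "identified", 0.5, ident_time=0.5),
            make_record("d2", 2.0, 1, "identified", 1.0, ident_time=1.0),
            make_record("n1", 3.5, 0, "completed", 2.0),
            make_record("n2", 2.6, 1, "completed", 2.0),
            make_record("n3", 5.0, 0, "completed", 2.0),
        ]
        fit, report = gpv_fit(records, cfg)
        donor_rows = [r for r in report.rows if r.z == 1]
        assert len(donor_rows) == 2
        # no ceasing/censoring of searches at all: omega = 1
        assert all(r.weight == pytest.approx(1.0) for r in donor_rows)
        # risk set at w=0.5 is everyone: S = (4/5)(3/4) = 0.6 at t* = 3,
        # without d1: (3/4)(2/3) = 0.5 -> V = 5*0.6 - 4*0.5 = 1
        # risk set at w=1.0 is everyone: without d2 only 2.6 remains:
        # S^{-d2} = 3/4 -> V = 5*0.6 - 4*0.75 = 0
        by_id = {r.cluster_id: r.value for r in donor_rows}
        assert by_id["d1"] == pytest.approx(1.0, abs=1e-12)
        assert by_id["d2"] == pytest.approx(0.0, abs=1e-12)
        assert fit.S1_hat == pytest.approx(0.5)

    def test_no_donor_arm_errors(self):
        cfg = StudyConfig(t_star=3.0, tau=2.0)
        records = [
            make_record("n1", 3.5, 0, "completed", 2.0),
            make_record("n2", 2.6, 1, "completed", 2.0),
        ]
        with pytest.raises(FitError, match="donor-identified"):
            gpv_fit(records, cfg)

    def test_row_structure(self):
        records, cfg = known_status_cohort()
        _fit, report = gpv_fit(records, cfg)
        assert len(report.rows) == report.n + report.m
        assert sum(r.z == 0 for r in report.rows) == report.n
        assert report.total_weight_z0 == pytest.approx(report.n)

    def test_subject_order_invariance(self):
        spec, cfg = wp.scenario_library()["study1"]
        records = wp.observed_cohort(wp.simulate_cohort(spec, cfg, 29))
        fit_a, _ = gpv_fit(records, cfg)
        rng = np.random.default_rng(1)
        shuffled = list(records)
        rng.shuffle(shuffled)
        fit_b, _ = gpv_fit(shuffled, cfg)
        assert fit_b.beta0 == pytest.approx(fit_a.beta0, abs=1e-10)
        assert fit_b.beta1 == pytest.approx(fit_a.beta1, abs=1e-10)


class TestConsistency:
    @pytest.mark.parametrize("method", ["wpv", "gpv"])
    def test_estimates_approach_truth_with_n(self, method):
        """Single large cohorts from the proportional-hazards scenario:
        the link-scale estimates tighten around the generative truth."""
        import dataclasses

        spec0, cfg = wp.scenario_library()["E"]
        s0, s1, chr_true = wp.true_values(spec0, cfg)
        beta0_true = math.log(-math.log(s0))
        beta1_true = math.log(chr_true)
        fitter = wpv_fit if method == "wpv" else gpv_fit
        errors = []
        for n in (400, 1000, 4000):
            spec = dataclasses.replace(spec0, n=n)
            records = wp.observed_cohort(wp.simulate_cohort(spec, cfg, 101))
            fit, _ = fitter(records, cfg)
            errors.append(
                abs(fit.beta0 - beta0_true) + abs(fit.beta1 - beta1_true)
            )
        assert errors[-1] < 0.12
        assert errors[-1] <= errors[0] + 0.05

    def test_wpv_and_gpv_agree_on_large_cohort(self):
        import dataclasses

        spec, cfg = wp.scenario_library()["F"]
        spec = dataclasses.replace(spec, n=8000)
        records = wp.observed_cohort(wp.simulate_cohort(spec, cfg, 7))
        fit_w, _ = wpv_fit(records, cfg)
        fit_g, _ = gpv_fit(records, cfg)
        assert fit_w.S1_hat == pytest.approx(fit_g.S1_hat, abs=0.04)
        assert fit_w.S0_hat == pytest.approx(fit_g.S0_hat, abs=0.04)
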