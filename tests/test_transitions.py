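"""Transition estimation, propagation, microsimulation and summaries."""

import numpy as np
import pandas as pd
import pytest

import cppflow as cf
from cppflow.states import N_STATES, StateId
from cppflow.transitions import DEFAULT_SOJOURN_STATES

from conftest import make_traj


def _simple_cohort(n_at_risk=100, reject_day=20, n_reject=1, horizon=40):
    """n patients in CPP; n_reject of them rejected at reject_day."""
    trajs = []
    for i in range(n_reject):
        trajs.append(
            make_traj(
                segments=[
                    (StateId.IN_CPP_NO_DX, 0, reject_day),
                    (StateId.REJECTED, reject_day, None),
                ],
                censor_day=horizon + 1,
                patient_id=f"r{i}",
            )
        )
    for i in range(n_at_risk - n_reject):
        trajs.append(
            make_traj(
                segments=[(StateId.IN_CPP_NO_DX, 0, None)],
                censor_day=horizon + 1,
                patient_id=f"s{i}",
            )
        )
    return trajs


class TestEstimate:
    def test_direct_count_oracle(self):
        # 1 of 100 at risk rejected at day 20 -> P_20 = 0.01 by direct count
        est = cf.estimate(_simple_cohort(), "calendar_time", horizon=40)
        P = est.transition_matrix(19)  # transition between day 19 and 20
        assert P[StateId.IN_CPP_NO_DX, StateId.REJECTED] == pytest.approx(0.01)
        assert P[StateId.IN_CPP_NO_DX, StateId.IN_CPP_NO_DX] == pytest.approx(0.99)

    def test_unobserved_state_row_is_identity(self):
        est = cf.estimate(_simple_cohort(), "calendar_time", horizon=40)
        P = est.transition_matrix(5)
        row = P[StateId.TREAT_NO_DX]
        assert row[StateId.TREAT_NO_DX] == 1.0
        assert row.sum() == 1.0

    def test_rows_stochastic_with_and_without_smoothing(self):
        trajs = _simple_cohort(n_at_risk=50, n_reject=10)
        for smoothing in (0, 3):
            est = cf.estimate(trajs, "calendar_time", smoothing=smoothing, horizon=40)
            for t in range(est.horizon):
                assert np.allclose(est.transition_matrix(t).sum(axis=1), 1.0, atol=1e-9)

    def test_censored_leave_risk_set(self):
        trajs = _simple_cohort(n_at_risk=100, n_reject=1)
        trajs.append(
            make_traj(
                segments=[(StateId.IN_CPP_NO_DX, 0, None)], censor_day=10, patient_id="c"
            )
        )
        est = cf.estimate(trajs, "calendar_time", horizon=40)
        assert est.at_risk[int(StateId.IN_CPP_NO_DX)][5] == 101
        assert est.at_risk[int(StateId.IN_CPP_NO_DX)][15] == 100

    def test_unknown_mode_and_negative_smoothing_rejected(self):
        trajs = _simple_cohort(10)
        with pytest.raises(ValueError, match="mode"):
            cf.estimate(trajs, "weekly")
        with pytest.raises(ValueError, match="smoothing"):
            cf.estimate(trajs, "calendar_time", smoothing=-1)

    def test_serialization_round_trip(self):
        est = cf.estimate(_simple_cohort(), "sojourn_time", horizon=40)
        text = est.to_json()
        back = cf.TransitionEstimate.from_json(text)
        assert back.mode == est.mode
        assert back.sojourn_states == est.sojourn_states
        for s in range(N_STATES):
            np.testing.assert_array_equal(back.counts[s], est.counts[s])


class TestPropagate:
    def test_identity_estimate_keeps_initial(self):
        trajs = [make_traj(segments=[(StateId.IN_CPP_NO_DX, 0, None)], censor_day=30)]
        est = cf.estimate(trajs, "calendar_time", horizon=20)
        init = cf.InitialDistribution(p_no_dx=0.8, p_with_dx=0.2)
        curve = cf.propagate(est, init, 20)
        # the only observed state self-transitions; WITH_DX row defaults to identity
        assert np.allclose(curve.values["IN_CPP_NO_DX"], 0.8)
        assert np.allclose(curve.values["IN_CPP_WITH_DX"], 0.2)

    def test_equals_empirical_on_uncensored_data(self, catalogue):
        sc = cf.preset_scenarios(seed=5)["high_rejection"]
        sc = cf.ScenarioConfig(
            cpps=(cf.synthetic.replace(sc.cpps[0], n_patients=200),),
            censor_date="2019-12-31",
            seed=5,
        )
        ref, canc, pat = cf.generate(sc, catalogue)
        cfg = cf.CohortConfig(study_year=2018, censor_date=pd.Timestamp("2020-06-30"))
        cohort, _ = cf.build_cohort(ref, pat, cfg)
        linked = cf.link_diagnoses(cohort, canc, catalogue, cfg)
        trajs = cf.map_cohort(linked, cfg)
        horizon = 60
        emp = cf.occupancy_empirical(trajs, horizon)
        est = cf.estimate(trajs, "calendar_time", horizon=horizon)
        day0 = emp.values.iloc[0]
        init = cf.InitialDistribution(
            p_no_dx=float(day0["IN_CPP_NO_DX"]), p_with_dx=float(day0["IN_CPP_WITH_DX"])
        )
        prop = cf.propagate(est, init, horizon)
        np.testing.assert_allclose(
            prop.values.to_numpy(), emp.values.to_numpy(), atol=1e-9
        )

    def test_absorbing_death_non_decreasing(self):
        trajs = _simple_cohort(50, n_reject=5)
        trajs.append(
            make_traj(
                segments=[(StateId.IN_CPP_NO_DX, 0, 7), (StateId.DEATH, 7, None)],
                censor_day=50,
                patient_id="d",
            )
        )
        est = cf.estimate(trajs, "calendar_time", horizon=40)
        curve = cf.propagate(est, cf.InitialDistribution(1.0, 0.0), 40)
        death = curve.values["DEATH"].to_numpy()
        assert np.all(np.diff(death) >= -1e-12)
        assert death[-1] > 0

    def test_horizon_beyond_range_needs_carry_forward(self):
        est = cf.estimate(_simple_cohort(horizon=20), "calendar_time", horizon=20)
        init = cf.InitialDistribution(1.0, 0.0)
        with pytest.raises(ValueError, match="carry_forward"):
            cf.propagate(est, init, 50)
        curve = cf.propagate(est, init, 50, carry_forward=True)
        assert len(curve.values) == 51

    def test_sojourn_marginal_matches_calendar_for_markov_data(self):
        # time-homogeneous generator => sojourn-expanded chain marginalizes
        # back to the calendar-time result
        rng = np.random.default_rng(42)
        trajs = []
        for i in range(400):
            day = int(rng.geometric(0.08))
            segs = (
                [(StateId.IN_CPP_NO_DX, 0, day), (StateId.REJECTED, day, None)]
                if day <= 60
                else [(StateId.IN_CPP_NO_DX, 0, None)]
            )
            trajs.append(make_traj(segments=segs, censor_day=61, patient_id=f"p{i}"))
        horizon = 40
        init = cf.InitialDistribution(1.0, 0.0)
        cal = cf.propagate(cf.estimate(trajs, "calendar_time", horizon=horizon), init, horizon)
        soj = cf.propagate(cf.estimate(trajs, "sojourn_time", horizon=horizon), init, horizon)
        # hazards are sojourn-independent only in expectation; both estimates
        # are nonparametric so agreement is statistical, not exact
        assert np.nanmax(np.abs(cal.values.to_numpy() - soj.values.to_numpy())) < 0.08

    def test_rows_sum_to_one_in_sojourn_mode(self):
        trajs = _simple_cohort(50, n_reject=10)
        est = cf.estimate(trajs, "sojourn_time", horizon=40)
        curve = cf.propagate(est, cf.InitialDistribution(1.0, 0.0), 40)
        assert np.allclose(curve.values.sum(axis=1), 1.0, atol=1e-9)


class TestMicrosimulate:
    def test_same_seed_identical_paths(self):
        est = cf.estimate(_simple_cohort(50, n_reject=10), "calendar_time", horizon=40)
        a = cf.microsimulate(est, n=500, seed=9, horizon=30)
        b = cf.microsimulate(est, n=500, seed=9, horizon=30)
        np.testing.assert_array_equal(a, b)

    def test_single_path_identity_estimate_constant(self):
        trajs = [make_traj(segments=[(StateId.IN_CPP_NO_DX, 0, None)], censor_day=30)]
        est = cf.estimate(trajs, "calendar_time", horizon=20)
        paths = cf.microsimulate(est, n=1, seed=0, horizon=20)
        assert (paths == int(StateId.IN_CPP_NO_DX)).all()

    def test_monte_carlo_matches_exact_propagation(self):
        est = cf.estimate(
            _simple_cohort(200, n_reject=60, reject_day=10), "calendar_time", horizon=40
        )
        init = cf.InitialDistribution(1.0, 0.0)
        exact = cf.propagate(est, init, 40)
        paths = cf.microsimulate(est, n=20000, seed=3, horizon=40, initial=init)
        mc = cf.occupancy_from_paths(paths)
        gap = np.max(np.abs(mc.values.to_numpy() - exact.values.to_numpy()))
        assert gap <= 0.01

    def test_sojourn_mode_paths_respect_designated_hazards(self):
        trajs = _simple_cohort(100, n_reject=30, reject_day=5)
        est = cf.estimate(trajs, "sojourn_time", horizon=30)
        paths = cf.microsimulate(est, n=2000, seed=1, horizon=30)
        share_rejected = (paths[:, -1] == int(StateId.REJECTED)).mean()
        assert share_rejected == pytest.approx(0.30, abs=0.04)


class TestParameterRecovery:
    def test_constant_exit_hazard_recovered_within_3_se(self, catalogue):
        # generator: constant rejection hazard 0.1/day, complete follow-up
        sc = cf.ScenarioConfig(
            cpps=(
                cf.CppScenario(
                    cpp_id="urothelial",
                    n_patients=5000,
                    hazards={"rejection": 0.1},
                    p_treatment_without_dx=1.0,
                ),
            ),
            censor_date="2019-12-31",
            seed=12,
        )
        ref, canc, pat = cf.generate(sc, catalogue)
        cfg = cf.CohortConfig(study_year=2018, censor_date=pd.Timestamp("2020-06-30"))
        cohort, _ = cf.build_cohort(ref, pat, cfg)
        linked = cf.link_diagnoses(cohort, canc, catalogue, cfg)
        trajs = cf.map_cohort(linked, cfg)
        est = cf.estimate(trajs, "sojourn_time", horizon=60)
        s = int(StateId.IN_CPP_NO_DX)
        for u in range(10):
            n_risk = est.at_risk[s][u]
            h = est.counts[s][u, int(StateId.REJECTED)] / n_risk
            se = np.sqrt(0.1 * 0.9 / n_risk)
            assert abs(h - 0.1) <= 3 * se, f"sojourn day {u}: {h:.4f}"


class TestSummarize:
    def test_all_diagnosed_same_day(self):
        trajs = [
            make_traj(
                segments=[
                    (StateId.IN_CPP_NO_DX, 0, 7),
                    (StateId.IN_CPP_WITH_DX, 7, None),
                ],
                psd_dx_day=7,
                patient_id=f"p{i}",
            )
            for i in range(4)
        ]
        out = cf.summarize(trajs)
        assert out["mean_days_to_diagnosis"]["value"] == 7.0

    def test_mean_over_diagnosed_only(self):
        trajs = [
            make_traj(
                segments=[(StateId.IN_CPP_NO_DX, 0, 4), (StateId.IN_CPP_WITH_DX, 4, None)],
                psd_dx_day=4,
                patient_id="a",
            ),
            make_traj(
                segments=[(StateId.IN_CPP_NO_DX, 0, 10), (StateId.IN_CPP_WITH_DX, 10, None)],
                psd_dx_day=10,
                patient_id="b",
            ),
            make_traj(segments=[(StateId.IN_CPP_NO_DX, 0, None)], patient_id="c"),
        ]
        out = cf.summarize(trajs)
        assert out["mean_days_to_diagnosis"]["value"] == 7.0
        assert out["mean_days_to_diagnosis"]["n"] == 2

    def test_treated_after_diagnosis_share(self):
        trajs = []
        for i in range(98):
            trajs.append(
                make_traj(
                    segments=[(StateId.IN_CPP_WITH_DX, 0, 20), (StateId.TREAT_WITH_DX, 20, None)],
                    psd_dx_day=-3,
                    stop_day=20,
                    stop_code="TREATMENT_START",
                    patient_id=f"w{i}",
                )
            )
        for i in range(2):
            trajs.append(
                make_traj(
                    segments=[(StateId.IN_CPP_NO_DX, 0, 20), (StateId.TREAT_NO_DX, 20, None)],
                    stop_day=20,
                    stop_code="TREATMENT_START",
                    patient_id=f"n{i}",
                )
            )
        out = cf.summarize(trajs)
        assert out["share_treated_after_diagnosis"]["value"] == pytest.approx(0.98)

    def test_undefined_statistic_is_none_not_zero(self):
        trajs = [make_traj(segments=[(StateId.IN_CPP_NO_DX, 0, None)])]
        out = cf.summarize(trajs)
        assert out["mean_days_to_treatment"]["value"] is None
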