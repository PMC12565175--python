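"""Pump controller: no-overshoot induction, pauses, and the brute-force resume oracle."""

import numpy as np
import numpy.linalg as la
import pytest

from tcisim import (
    NO_RESUME,
    PKState,
    PumpConfig,
    controller_step,
    find_pause_end,
    induction_dose,
    run_tci,
)
from tcisim.pk import PumpTrace

from conftest import euler_trace


def steady_state(params, ce_target):
    """Closed-form steady state of the linear system at Cp = Ce = target."""
    r = params.CL1 * ce_target
    x = -la.solve(params.system_matrix(), np.array([1.0, 0.0, 0.0, 0.0]) * r)
    return PKState(a1=x[0], a2=x[1], a3=x[2], ce=x[3])


class TestPumpConfig:
    def test_rate_cap_unit_conversion(self):
        assert PumpConfig(max_rate_ml_h=720.0, drug_mg_ml=10.0).max_rate == 120.0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            PumpConfig(max_rate_ml_h=0.0)
        with pytest.raises(ValueError):
            PumpConfig(update_interval=0.5)
        with pytest.raises(ValueError):
            PumpConfig(ce_tolerance=0.2)


class TestControllerStep:
    def test_steady_state_rate_is_metabolic_replacement(self, params_tpeak, pump_cfg):
        target = 2.5
        rate = controller_step(params_tpeak, steady_state(params_tpeak, target), target, pump_cfg)
        assert rate == pytest.approx(params_tpeak.CL1 * target, rel=0.02)

    def test_pause_when_above_target(self, params_tpeak, pump_cfg):
        state = steady_state(params_tpeak, 6.0)
        assert controller_step(params_tpeak, state, 2.5, pump_cfg) == 0.0

    def test_rate_bounded_by_cap(self, params_tpeak, pump_cfg):
        rate = controller_step(params_tpeak, PKState(), 8.0, pump_cfg)
        assert rate == pump_cfg.max_rate


class TestInductionDose:
    def test_zero_when_target_not_above_predicted_peak(self, params_tpeak, pump_cfg):
        state = steady_state(params_tpeak, 4.0)
        assert induction_dose(params_tpeak, state, 4.0, pump_cfg) == 0.0

    def test_approximate_linearity_from_zero_state(self, params_tpeak, pump_cfg):
        # exact only for an impulse bolus; the rate-capped delivery bends it
        d1 = induction_dose(params_tpeak, PKState(), 2.5, pump_cfg)
        d2 = induction_dose(params_tpeak, PKState(), 5.0, pump_cfg)
        assert d2 == pytest.approx(2 * d1, rel=0.1)

    def test_closed_loop_delivers_the_same_bolus(self, params_tpeak, pump_cfg):
        d = induction_dose(params_tpeak, PKState(), 6.0, pump_cfg)
        tr = run_tci(params_tpeak, [(0.0, 6.0)], pump_cfg, 300.0)
        bolus = tr.cumulative_dose[np.argmax(tr.rate < pump_cfg.max_rate)]
        assert bolus == pytest.approx(d, abs=pump_cfg.max_rate / 60.0 + 0.5)


class TestRunTci:
    def test_tracking_constant_target(self, params_tpeak, pump_cfg):
        tr = run_tci(params_tpeak, [(0.0, 3.0)], pump_cfg, 1500.0)
        tail = tr.ce[tr.t >= 1200.0]
        assert np.all(np.abs(tail - 3.0) / 3.0 < 0.01)

    def test_no_effect_site_overshoot(self, params_tpeak, pump_cfg):
        for target in (2.5, 4.0, 8.0):
            tr = run_tci(params_tpeak, [(0.0, target)], pump_cfg, 900.0)
            assert tr.ce.max() <= target * (1 + pump_cfg.ce_tolerance) + 1e-6

    def test_cumulative_dose_flat_while_pump_off(self, params_tpeak, pump_cfg):
        tr = run_tci(params_tpeak, [(0.0, 6.0), (180.0, 2.5)], pump_cfg, 900.0)
        off = ~tr.pump_on[:-1]
        deltas = np.diff(tr.cumulative_dose)
        assert np.all(deltas[off] == 0.0)

    def test_pause_monotone_in_induction_target(self, params_tpeak, pump_cfg):
        pauses = []
        for target in (4.0, 6.0, 8.0):
            tr = run_tci(params_tpeak, [(0.0, target), (150.0, 2.5)], pump_cfg, 1200.0)
            pauses.append(find_pause_end(tr, 150.0))
        assert pauses[0] < pauses[1] < pauses[2]

    def test_schedule_must_start_at_zero(self, params_tpeak, pump_cfg):
        with pytest.raises(ValueError):
            run_tci(params_tpeak, [(30.0, 4.0)], pump_cfg, 300.0)

    def test_short_duration_warns(self, params_tpeak, pump_cfg):
        with pytest.warns(UserWarning, match="truncated"):
            run_tci(params_tpeak, [(0.0, 4.0), (600.0, 2.5)], pump_cfg, 300.0)

    def test_plasma_overshoot_ratio_cohort_typical(self, params_tpeak, pump_cfg):
        # the study observes plasma peaking at roughly triple the effect target
        for target in (6.0, 8.0):
            tr = run_tci(params_tpeak, [(0.0, target)], pump_cfg, 600.0)
            assert 2.0 <= tr.cp.max() / target <= 3.5

    def test_resume_time_matches_brute_force(self, params_tpeak, pump_cfg):
        """Step-down 6 -> 2.5: the pause must end when Ce decays to the new target.

        Brute-force oracle: fine-step zero-input integration from the
        step-down state, located crossing of Ce = 2.5.
        """
        from tcisim import PKState as S
        from tcisim import advance

        p = params_tpeak
        t_step = 150.0
        tr = run_tci(p, [(0.0, 6.0), (t_step, 2.5)], pump_cfg, 1200.0)
        pause = find_pause_end(tr, t_step)

        # rebuild the full state at step-down by replaying the recorded rate
        # schedule (the kinetics are shared; the decision logic under test is
        # not), then decay it with an independent fine-step Euler loop
        st = S()
        for k in range(tr.index_at(t_step)):
            st = advance(st, p, float(tr.rate[k]), float(tr.dt))
        a1, a2, a3, ce = st.a1, st.a2, st.a3, st.ce
        dt_s = 0.01
        dt_min = dt_s / 60.0
        t_cross = None
        for k in range(int(600.0 / dt_s)):
            if ce <= 2.5:
                t_cross = k * dt_s
                break
            da1 = -(p.k10 + p.k12 + p.k13) * a1 + p.k21 * a2 + p.k31 * a3
            da2 = p.k12 * a1 - p.k21 * a2
            da3 = p.k13 * a1 - p.k31 * a3
            dce = p.ke0 * (a1 / p.V1 - ce)
            a1 += da1 * dt_min
            a2 += da2 * dt_min
            a3 += da3 * dt_min
            ce += dce * dt_min
        assert t_cross is not None
        assert abs(pause - t_cross) <= pump_cfg.update_interval + 0.02


class TestFindPauseEnd:
    def _trace(self, rates):
        n = len(rates)
        t = np.arange(n, dtype=float)
        return PumpTrace(
            t=t, rate=np.asarray(rates, dtype=float), cp=np.zeros(n), ce=np.zeros(n),
            cumulative_dose=np.zeros(n),
        )

    def test_pump_already_on(self):
        tr = self._trace([5.0] * 10)
        assert find_pause_end(tr, 3.0) == 0.0

    def test_exact_off_interval(self):
        tr = self._trace([1.0] * 10 + [0.0] * 300 + [2.0] * 10)
        assert find_pause_end(tr, 10.0) == 300.0

    def test_never_resumes(self):
        tr = self._trace([1.0] * 5 + [0.0] * 50)
        assert find_pause_end(tr, 5.0) == NO_RESUME
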