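import dataclasses

import numpy as np
import pytest

from fpetki.frames import FrameSchedule
from fpetki.glm import GlmDesign, fit_glm
from fpetki.kinetics import conv_1tc, internal_grid
from fpetki.patlak import (
    fit_ki,
    patlak_transform,
    percent_signal_change,
    task_ki,
    task_ki_patlak_difference,
    weight_and_average,
)
from fpetki.synthetic import simulate_tac
from fpetki.types import InputFunctionSet, KineticParams, TaskSchedule, k3_for_ki


class TestTransformAndFit:
    def test_linear_uptake_constant_plasma_closed_form(self, constant_plasma_inputs, frames):
        """Cp = c, Ct = Ki*c*t: x equals t, y equals Ki*t, slope exactly Ki."""
        ki = 0.01
        tac = ki * 10.0 * frames.mid
        x, y = patlak_transform(tac, frames, constant_plasma_inputs)
        np.testing.assert_allclose(x, frames.mid, rtol=1e-9)
        np.testing.assert_allclose(y, ki * frames.mid, rtol=1e-9)
        res = fit_ki(x, y, frames.mid)
        assert res.ki == pytest.approx(ki, rel=1e-9)
        assert res.n_points == 25  # midpoints >= 25 min

    def test_zero_tissue_gives_zero_slope(self, constant_plasma_inputs, frames):
        x, y = patlak_transform(np.zeros(frames.n_frames), frames, constant_plasma_inputs)
        res = fit_ki(x, y, frames.mid)
        assert res.ki == pytest.approx(0.0, abs=1e-15)

    def test_reversible_tissue_slope_vanishes_intercept_is_volume(self, frames):
        """Pure 1TC tissue at late times: slope -> 0 and intercept -> K1/k2
        (the steady-state distribution volume)."""
        t = internal_grid(300.0)
        cp = np.full_like(t, 10.0)
        K1, k2 = 0.1, 0.2
        tissue = conv_1tc(t, cp, K1, k2)
        ifs = InputFunctionSet(t=t, whole_blood=cp, parent=cp, metabolite=np.zeros_like(t))
        fs = FrameSchedule.uniform(300.0, 1.0)
        x, y = patlak_transform(fs.average(t, tissue), fs, ifs)
        res = fit_ki(x, y, fs.mid, t_star=150.0)
        assert abs(res.ki) < 1e-6
        assert res.intercept == pytest.approx(K1 / k2, rel=1e-3)

    def test_exact_line_recovered_to_machine_precision(self, frames):
        x = frames.mid.astype(float)
        y = 0.01 * x + 0.2
        res = fit_ki(x, y, frames.mid)
        assert res.ki == pytest.approx(0.01, rel=1e-12)
        assert res.intercept == pytest.approx(0.2, rel=1e-12)
        assert res.r_squared == pytest.approx(1.0)

    def test_noise_free_irreversible_2tc_constant_plasma(self, constant_plasma_inputs, frames):
        """Patlak slope equals K1*k3/(k2+k3) within 1% (fine grid) and 2%
        (frame-averaged data)."""
        p = KineticParams(K1=0.6, k2=8.0, k3=k3_for_ki(0.6, 8.0, 0.009), vB=0.0)
        tac, truth = simulate_tac(p, constant_plasma_inputs, None, frames, metabolite_kinetics=(0.0, 1.0))
        x, y = patlak_transform(tac.activity, frames, constant_plasma_inputs)
        res = fit_ki(x, y, frames.mid)
        assert res.ki == pytest.approx(truth.ki_baseline, rel=0.01)

    def test_scale_invariance(self, constant_plasma_inputs, frames):
        """Multiplying Cp and the TAC by a common constant leaves the slope
        unchanged."""
        p = KineticParams(K1=0.6, k2=8.0, k3=0.12, vB=0.0)
        tac, _ = simulate_tac(p, constant_plasma_inputs, None, frames, metabolite_kinetics=(0.0, 1.0))
        x1, y1 = patlak_transform(tac.activity, frames, constant_plasma_inputs)
        scaled = InputFunctionSet(
            t=constant_plasma_inputs.t,
            whole_blood=3.0 * constant_plasma_inputs.whole_blood,
            parent=3.0 * constant_plasma_inputs.parent,
            metabolite=constant_plasma_inputs.metabolite,
        )
        x2, y2 = patlak_transform(3.0 * tac.activity, frames, scaled)
        assert fit_ki(x2, y2, frames.mid).ki == pytest.approx(fit_ki(x1, y1, frames.mid).ki, rel=1e-9)

    def test_nonpositive_plasma_rejected(self, frames):
        t = internal_grid(50.0)
        cp = np.zeros_like(t)
        ifs = InputFunctionSet(t=t, whole_blood=cp, parent=cp, metabolite=cp)
        with pytest.raises(ValueError):
            patlak_transform(np.ones(frames.n_frames), frames, ifs)

    def test_insufficient_late_points_rejected(self, frames):
        x = frames.mid
        with pytest.raises(ValueError):
            fit_ki(x, x, frames.mid, t_star=49.0)


class TestTaskKi:
    def _fit(self, inputs, frames, task, block_ki, baseline_scale=0.9):
        k3 = k3_for_ki(0.6, 8.0, 0.009)
        p = KineticParams(K1=0.6, k2=8.0, k3=k3, vB=0.0).with_task_ki(block_ki)
        tac, truth = simulate_tac(p, inputs, task, frames, metabolite_kinetics=(0.0, 1.0))
        gm, _ = simulate_tac(
            KineticParams(K1=0.6 * baseline_scale, k2=8.0, k3=k3, vB=0.0),
            inputs,
            None,
            frames,
            metabolite_kinetics=(0.0, 1.0),
        )
        design = GlmDesign.build(frames, task, gm.activity)
        return fit_glm(tac.activity, design), truth

    def test_zero_beta_gives_zero_ki(self, default_inputs, frames, task):
        fit, _ = self._fit(default_inputs, frames, task, {})
        kis = task_ki(fit, default_inputs, task)
        np.testing.assert_allclose(kis, 0.0, atol=1e-7)

    def test_recovers_generative_block_influx(self, default_inputs, frames, task):
        block_ki = {0: 0.014, 1: 0.009, 2: 0.014, 3: 0.009}
        fit, truth = self._fit(default_inputs, frames, task, block_ki)
        kis = task_ki(fit, default_inputs, task)
        np.testing.assert_allclose(kis, truth.ki_blocks, rtol=0.02)

    def test_joint_scaling_invariance(self, default_inputs, frames, task):
        fit, _ = self._fit(default_inputs, frames, task, {0: 0.014})
        kis = task_ki(fit, default_inputs, task)
        scaled_inputs = InputFunctionSet(
            t=default_inputs.t,
            whole_blood=2 * default_inputs.whole_blood,
            parent=2 * default_inputs.parent,
            metabolite=2 * default_inputs.metabolite,
        )
        fit2 = dataclasses.replace(fit, beta=2 * fit.beta, fitted_tac=2 * fit.fitted_tac)
        kis2 = task_ki(fit2, scaled_inputs, task)
        np.testing.assert_allclose(kis2, kis, rtol=1e-9)

    def test_beta_conversion_agrees_with_patlak_difference(self, default_inputs, frames, task):
        """The module's central consistency check: both task-Ki
        constructions agree within 2% on noise-free data."""
        fit, _ = self._fit(default_inputs, frames, task, {0: 0.014, 1: 0.009, 2: 0.014, 3: 0.009})
        beta_ki = task_ki(fit, default_inputs, task)
        pat_ki = task_ki_patlak_difference(fit, default_inputs)
        np.testing.assert_allclose(pat_ki, beta_ki, rtol=0.02)

    def test_recovered_ki_monotone_in_trapping_increment(self, default_inputs, frames, task):
        recovered = []
        for dki in (0.005, 0.010, 0.015, 0.020):
            fit, _ = self._fit(default_inputs, frames, task, {1: dki})
            recovered.append(task_ki(fit, default_inputs, task)[1])
        assert np.all(np.diff(recovered) > 0)


class TestConditionAveraging:
    def test_equal_weights_give_plain_mean(self):
        c = weight_and_average(
            np.array([0.01, 0.02]), ("gain", "gain"), np.array([0.5, 0.5]), 0.01
        )
        assert c.ki_gain == pytest.approx(0.015)
        assert c.ki_gain == c.ki_gain_unweighted

    def test_zero_weight_drops_block(self):
        c = weight_and_average(
            np.array([0.01, 0.02]), ("loss", "loss"), np.array([1.0, 0.0]), 0.01
        )
        assert c.ki_loss == pytest.approx(0.01)

    def test_weighted_average_arithmetic(self):
        c = weight_and_average(
            np.array([0.010, 0.016]), ("gain", "gain"), np.array([0.8, 0.4]), 0.009
        )
        assert c.ki_gain == pytest.approx(0.012)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            weight_and_average(np.array([0.01]), ("gain",), np.array([0.0]), 0.009)


class TestPercentSignalChange:
    @pytest.mark.parametrize(
        "task_val,base,expected",
        [(0.009, 0.009, 100.0), (0.0, 0.004, 0.0), (0.014, 0.009, 155.6)],
    )
    def test_values(self, task_val, base, expected):
        assert percent_signal_change(task_val, base) == pytest.approx(expected, abs=0.05)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_signal_change(0.01, 0.0)
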