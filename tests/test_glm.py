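import dataclasses

import numpy as np
import pytest

from fpetki.frames import FrameSchedule
from fpetki.glm import (
    GlmDesign,
    adjust_tac,
    build_baseline_regressor,
    fit_glm,
    lowpass_filter,
    motion_regressor,
    task_ramp,
)
from fpetki.synthetic import simulate_tac
from fpetki.types import KineticParams, TaskSchedule, k3_for_ki


def _sine_amplitude(y, t, period):
    """Least-squares amplitude of a sinusoid of known period."""
    X = np.column_stack([np.sin(2 * np.pi * t / period), np.cos(2 * np.pi * t / period), np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(np.hypot(coef[0], coef[1]))


class TestLowpassFilter:
    def test_constant_series_unchanged(self):
        y = np.full(50, 7.3)
        np.testing.assert_allclose(lowpass_filter(y, 1.0), y, rtol=1e-12)

    @pytest.mark.parametrize(
        "period,check",
        [
            (1.0, lambda g: g <= 0.10),  # short period strongly attenuated
            (10.0, lambda g: abs(g - 1.0) <= 0.05),  # long period preserved
        ],
    )
    def test_frequency_response_bounds(self, period, check):
        dt = 0.1  # sample finely so both periods are representable
        t = np.arange(0.0, 50.0, dt)
        y = np.sin(2 * np.pi * t / period)
        filtered = lowpass_filter(y, dt, cutoff_period=2.5)
        # interior, away from boundary transients
        sl = slice(100, -100)
        gain = _sine_amplitude(filtered[sl], t[sl], period) / _sine_amplitude(y[sl], t[sl], period)
        assert check(gain)

    def test_half_power_at_cutoff(self):
        dt = 0.05
        t = np.arange(0.0, 100.0, dt)
        y = np.sin(2 * np.pi * t / 2.5)
        filtered = lowpass_filter(y, dt, cutoff_period=2.5)
        sl = slice(400, -400)
        gain = _sine_amplitude(filtered[sl], t[sl], 2.5) / _sine_amplitude(y[sl], t[sl], 2.5)
        assert gain == pytest.approx(np.sqrt(0.5), abs=0.02)

    def test_linearity_over_columns(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 3))
        w = np.array([0.5, -1.0, 2.0])
        np.testing.assert_allclose(
            lowpass_filter(X @ w, 1.0), lowpass_filter(X, 1.0) @ w, rtol=1e-10, atol=1e-12
        )

    def test_non_uniform_frames_rejected(self):
        frames = FrameSchedule(np.array([0.0, 1.0, 3.0]), np.array([1.0, 3.0, 6.0]))
        with pytest.raises(ValueError):
            lowpass_filter(np.ones(3), frames)


class TestBaselineRegressor:
    def test_identical_series_returned(self):
        series = np.linspace(0, 5, 20)
        out = build_baseline_regressor({"a": series, "b": series.copy()})
        np.testing.assert_array_equal(out, series)

    def test_exclusion_leaves_other_series(self):
        a, b = np.ones(10), np.full(10, 3.0)
        out = build_baseline_regressor({"a": a, "b": b}, exclude={"a"})
        np.testing.assert_array_equal(out, b)

    def test_mean_matches_direct_average(self):
        rng = np.random.default_rng(0)
        tacs = {f"r{i}": rng.random(30) for i in range(5)}
        out = build_baseline_regressor(tacs, exclude={"r0"})
        np.testing.assert_allclose(out, np.mean([tacs[f"r{i}"] for i in range(1, 5)], axis=0))

    def test_empty_after_exclusion_rejected(self):
        with pytest.raises(ValueError):
            build_baseline_regressor({"a": np.ones(5)}, exclude={"a"})


class TestMotionRegressor:
    def test_repeated_column_recovered_up_to_scale(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=40)
        motion = np.tile(col[:, None], (1, 6))
        pc1 = motion_regressor(motion)
        centered = col - col.mean()
        corr = np.corrcoef(pc1, centered)[0, 1]
        assert corr == pytest.approx(1.0, abs=1e-10)  # sign fixed positive

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        motion = rng.normal(size=(60, 6)) * np.array([3.0, 1.0, 0.5, 0.2, 0.1, 0.05])
        pc1 = motion_regressor(motion)
        centered = motion - motion.mean(axis=0)
        evals, evecs = np.linalg.eigh(centered.T @ centered)
        oracle = centered @ evecs[:, -1]
        assert abs(np.corrcoef(pc1, oracle)[0, 1]) == pytest.approx(1.0, abs=1e-10)
        assert np.var(pc1) == pytest.approx(evals[-1] / motion.shape[0], rel=1e-9)

    def test_constant_motion_gives_zero_with_warning(self):
        with pytest.warns(UserWarning):
            pc1 = motion_regressor(np.ones((20, 6)))
        np.testing.assert_array_equal(pc1, 0.0)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            motion_regressor(np.ones((20, 5)))


class TestDesignAndFit:
    def _design(self, frames, task, baseline, motion=None):
        return GlmDesign.build(frames, task, baseline, motion)

    def test_ramp_slope_is_one_per_frame_inside_block(self, frames, task):
        ramp = task_ramp(frames, 10.0, 5.0)
        inside = slice(11, 15)
        np.testing.assert_allclose(np.diff(ramp[inside]), 1.0, rtol=1e-12)
        assert ramp[5] == 0.0
        np.testing.assert_allclose(ramp[20:], ramp[20], rtol=1e-12)  # held after block

    def test_tac_equal_to_baseline_regressor(self, frames, task):
        baseline = np.linspace(1, 40, frames.n_frames)
        design = self._design(frames, task, baseline)
        fit = fit_glm(baseline, design)
        assert fit.beta_of("baseline") == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(fit.task_betas, 0.0, atol=1e-10)

    def test_exact_task_component_recovered(self, frames, task):
        baseline = np.linspace(1, 40, frames.n_frames)
        design = self._design(frames, task, baseline)
        y = baseline + 0.5 * design.column("task_2")
        fit = fit_glm(y, design)
        assert fit.beta_of("task_2") == pytest.approx(0.5, abs=1e-10)
        assert fit.beta_of("task_1") == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equation_oracle(self, frames, task):
        rng = np.random.default_rng(4)
        baseline = np.cumsum(rng.random(frames.n_frames))
        motion = rng.normal(size=frames.n_frames)
        design = self._design(frames, task, baseline, motion)
        y = rng.normal(size=frames.n_frames)
        fit = fit_glm(y, design)
        X = design.matrix
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.beta, oracle, rtol=1e-10)

    def test_reconstruction_identity(self, frames, task):
        rng = np.random.default_rng(5)
        baseline = np.cumsum(rng.random(frames.n_frames))
        design = self._design(frames, task, baseline)
        y = rng.normal(size=frames.n_frames)
        fit = fit_glm(y, design)
        np.testing.assert_allclose(fit.components.sum(axis=1) + fit.residual, y, rtol=1e-10)

    def test_frame_permutation_leaves_betas_unchanged(self, frames, task):
        rng = np.random.default_rng(6)
        baseline = np.cumsum(rng.random(frames.n_frames))
        design = self._design(frames, task, baseline)
        y = rng.normal(size=frames.n_frames)
        perm = rng.permutation(frames.n_frames)
        fit = fit_glm(y, design)
        fit_p = fit_glm(y[perm], dataclasses.replace(design, matrix=design.matrix[perm]))
        np.testing.assert_allclose(fit.beta, fit_p.beta, rtol=1e-9)

    def test_rank_deficient_design_rejected(self, frames, task):
        baseline = np.linspace(0, 1, frames.n_frames)
        design = self._design(frames, task, baseline)
        bad = np.column_stack([design.matrix, design.matrix[:, 0]])
        with pytest.raises(ValueError):
            fit_glm(np.zeros(frames.n_frames), dataclasses.replace(design, matrix=bad, names=design.names + ("dup",)))

    def test_block_beta_signs_follow_task_modulation(self, default_inputs, frames, task):
        """Noise-free synthetic TAC: each block's beta is positive exactly
        when its trapping increment is positive."""
        k3 = k3_for_ki(0.6, 8.0, 0.009)
        p = KineticParams(K1=0.6, k2=8.0, k3=k3, vB=0.0)
        p = p.with_task_ki({0: 0.014, 2: 0.010})  # blocks 2 and 4 unmodulated
        tac, _ = simulate_tac(p, default_inputs, task, frames, metabolite_kinetics=(0.0, 1.0))
        gm, _ = simulate_tac(
            KineticParams(K1=0.54, k2=8.0, k3=k3, vB=0.0),
            default_inputs,
            None,
            frames,
            metabolite_kinetics=(0.0, 1.0),
        )
        fit = fit_glm(tac.activity, self._design(frames, task, gm.activity))
        betas = fit.task_betas
        assert betas[0] > 0 and betas[2] > 0
        assert abs(betas[1]) < 0.05 * betas[0] and abs(betas[3]) < 0.05 * betas[0]

    def test_adjust_removes_task_and_motion_components(self, frames, task):
        rng = np.random.default_rng(8)
        baseline = np.cumsum(rng.random(frames.n_frames))
        motion = rng.normal(size=frames.n_frames)
        design = self._design(frames, task, baseline, motion)
        y = 2.0 * baseline + 0.3 * design.column("task_1") + 0.1 * motion
        fit = fit_glm(y, design)
        adjusted = adjust_tac(y, fit)
        np.testing.assert_allclose(adjusted, 2.0 * baseline, rtol=1e-9)
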