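"""Fidelity, exact gradients, and the projected GRAPE optimizer."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from decop.dynamics import IX, IZ, PulseShape, net_rotation, rotation_axis_angle
from decop.grape import (
    GrapeProblem,
    fidelity,
    fidelity_and_gradient,
    gradient,
    optimize,
    per_target_fidelity,
)
from decop.targets import (
    DesignSpec,
    SpectrometerConfig,
    TargetSpec,
    build_targets,
    builtin_spec,
)


def oracle_fidelity(pulse, targets):
    """Independent re-implementation via scipy Rotation (different code path)."""
    dt = pulse.segment_duration
    total, wsum = 0.0, 0.0
    for t in targets:
        m = t.initial.copy()
        for amp, phi in zip(pulse.amplitudes, pulse.phases):
            n = np.array([amp * np.cos(phi), amp * np.sin(phi), t.offset])
            m = Rotation.from_rotvec(2 * np.pi * dt * n).apply(m)
        total += t.weight * float(np.dot(m, t.desired))
        wsum += t.weight
    return total / wsum


def random_targets(rng, n=20):
    out = []
    for _ in range(n):
        v0 = rng.standard_normal(3)
        v0 /= np.linalg.norm(v0)
        v1 = rng.standard_normal(3)
        v1 /= np.linalg.norm(v1)
        out.append(
            TargetSpec(
                offset=float(rng.uniform(-25_000, 25_000)),
                initial=v0, desired=v1, kind="invert",
                weight=float(rng.uniform(0.5, 2.0)),
            )
        )
    return out


def random_pulse(rng, n=16, dt=2e-6, amp=8_000.0):
    return PulseShape.from_xy(
        rng.uniform(-amp, amp, n), rng.uniform(-amp, amp, n), dt
    )


class TestFidelity:
    def test_free_precession_satisfies_uncontracted_tracking(self):
        # a = 1: the desired map IS free precession, so a zero pulse is exact
        spec = DesignSpec(
            name="unit", duration=1e-4, max_amplitude=1e4, contraction=1.0,
            rotation_band=(35.0, 75.0), n_rotation=11,
        )
        targets = build_targets(spec, SpectrometerConfig())
        pulse = PulseShape.zero(spec.duration, 20)
        assert fidelity(pulse, targets) == pytest.approx(1.0, abs=1e-12)

    def test_untouched_inversion_target_scores_minus_one(self):
        t = TargetSpec(offset=0.0, initial=IZ, desired=-IZ, kind="invert")
        assert fidelity(PulseShape.zero(1e-4, 8), [t]) == pytest.approx(-1.0)

    def test_matches_independent_oracle(self, rng):
        pulse = random_pulse(rng)
        targets = random_targets(rng)
        assert fidelity(pulse, targets) == pytest.approx(
            oracle_fidelity(pulse, targets), abs=1e-9
        )

    def test_per_target_bounded(self, rng):
        pt = per_target_fidelity(random_pulse(rng), random_targets(rng))
        assert np.all(pt >= -1 - 1e-12) and np.all(pt <= 1 + 1e-12)

    def test_empty_targets_rejected(self, rng):
        with pytest.raises(ValueError):
            fidelity(random_pulse(rng), [])


class TestGradient:
    def test_matches_central_finite_differences(self, rng):
        pulse = random_pulse(rng)
        targets = random_targets(rng)
        _, g = fidelity_and_gradient(pulse, targets)
        ux, uy = pulse.xy_controls()
        h = 1e-6 * 15_000.0
        scale = np.abs(g).max()
        for k in range(0, pulse.n_segments, 3):
            for c in range(2):
                up = np.stack([ux, uy], 1)
                um = up.copy()
                up[k, c] += h
                um[k, c] -= h
                fd = (
                    fidelity(PulseShape.from_xy(up[:, 0], up[:, 1], 2e-6), targets)
                    - fidelity(PulseShape.from_xy(um[:, 0], um[:, 1], 2e-6), targets)
                ) / (2 * h)
                assert abs(g[k, c] - fd) <= 1e-4 * max(abs(fd), 0.1 * scale)

    def test_stationary_at_exact_optimum(self):
        # all targets satisfied exactly by free precession (a = 1), interior point
        spec = DesignSpec(
            name="unit", duration=1e-4, max_amplitude=1e4, contraction=1.0,
            rotation_band=(35.0, 75.0), n_rotation=10,
        )
        targets = build_targets(spec, SpectrometerConfig())
        g = gradient(PulseShape.zero(spec.duration, 16), targets)
        assert np.abs(g).max() < 1e-6

    def test_invariant_under_uniform_weight_scaling(self, rng):
        # the objective is a weighted *mean*: rescaling all weights together
        # changes neither the fidelity nor its gradient
        pulse = random_pulse(rng)
        targets = random_targets(rng)
        doubled = [
            TargetSpec(offset=t.offset, initial=t.initial, desired=t.desired,
                       weight=2 * t.weight, kind=t.kind)
            for t in targets
        ]
        f1, g1 = fidelity_and_gradient(pulse, targets)
        f2, g2 = fidelity_and_gradient(pulse, doubled)
        assert f1 == pytest.approx(f2, abs=1e-12)
        assert np.abs(g1 - g2).max() < 1e-12


class TestOptimize:
    def test_single_inversion_reaches_hard_pi(self):
        spec = DesignSpec(
            name="pi", duration=1e-4, max_amplitude=50_000.0, contraction=0.9,
            rotation_band=(200.0, 210.0), n_rotation=1,
        )
        # single on-resonance inversion target; generous amplitude ceiling
        targets = [TargetSpec(offset=0.0, initial=IZ, desired=-IZ, kind="invert")]
        problem = GrapeProblem(spec=spec, targets=targets, n_segments=16)
        result = optimize(problem)
        assert result.fidelity >= 0.999
        _, angle = rotation_axis_angle(net_rotation(result.pulse, 0.0))
        assert angle == pytest.approx(np.pi, rel=0.05)

    def test_deterministic_given_seed(self):
        spec = builtin_spec("GOODCOP")
        kw = dict(spec=spec, n_segments=32, max_iterations=40)
        r1 = optimize(GrapeProblem(**kw))
        r2 = optimize(GrapeProblem(**kw))
        assert np.array_equal(r1.fidelity_history, r2.fidelity_history)
        assert np.array_equal(r1.pulse.amplitudes, r2.pulse.amplitudes)

    def test_monotone_history_and_ceiling(self, goodcop_result):
        hist = goodcop_result.fidelity_history
        assert np.all(np.diff(hist) >= 0)
        spec = builtin_spec("GOODCOP")
        assert goodcop_result.pulse.max_amplitude <= spec.max_amplitude * (1 + 1e-12)

    def test_smoothness_penalty_reduces_control_roughness(self):
        spec = builtin_spec("GOODCOP")
        kw = dict(spec=spec, n_segments=64, max_iterations=300, n_restarts=1)

        def roughness(pulse):
            ux, uy = pulse.xy_controls()
            u = np.stack([ux, uy], 1)
            return float(np.sum(np.diff(u, axis=0) ** 2))

        plain = optimize(GrapeProblem(**kw))
        smooth = optimize(GrapeProblem(**kw, smoothness_weight=0.1))
        assert roughness(smooth.pulse) < roughness(plain.pulse)

    def test_nonconvergence_reported_not_raised(self):
        spec = builtin_spec("GOODCOP")
        result = optimize(GrapeProblem(spec=spec, n_segments=32, max_iterations=3))
        assert result.converged is False

    def test_transverse_linearity_at_calpha_offsets(self, goodcop_result, cfg):
        # a pulse correct on +x and +y is correct for every transverse state:
        # check 8 azimuths against the target z-rotation
        from decop.dynamics import free_precession_rotation, propagate
        from decop.targets import ppm_to_offset

        spec = builtin_spec("GOODCOP")
        aT = spec.contraction * spec.duration
        for ppm in (40.0, 55.0, 70.0):
            w = float(ppm_to_offset(ppm, cfg))
            target_rot = free_precession_rotation(w, aT)
            for az in np.linspace(0, 2 * np.pi, 8, endpoint=False):
                s0 = np.array([np.cos(az), np.sin(az), 0.0])
                out = propagate(goodcop_result.pulse, w, s0)
                assert float(np.dot(out, target_rot @ s0)) > 0.99
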