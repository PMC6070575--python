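"""Spin-1/2 dynamics under piecewise-constant RF in the rotating frame.

This is the physics engine of the package.  A shaped pulse is a sequence of
segments, each with a constant RF amplitude (nutation frequency, Hz) and
phase (rad).  At a chemical-shift offset ``Δν`` (Hz) the magnetization during
one segment precesses about the effective-field vector

    n = (ν1 cos φ, ν1 sin φ, Δν)        [Hz]

by the angle ``2π |n| dt`` — a closed-form rotation, so piecewise-constant
propagation is exact (no time-stepping error).  The sign convention is fixed
globally: a positive offset rotates +x toward +y (right-handed about +z).

A weakly coupled two-spin system (observed spin + coupled partner, e.g.
Cα–Cβ or Cα–CO) is propagated exactly as a 4×4 density matrix under the
secular coupling Hamiltonian ``2π J Iz Sz`` with the RF acting on both spins
at their respective offsets.  Relaxation is not modeled anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.linalg import expm

__all__ = [
    "IX",
    "IY",
    "IZ",
    "PulseShape",
    "TwoSpinSystem",
    "bloch_state",
    "propagate",
    "net_rotation",
    "rotation_axis_angle",
    "simulate_profile",
    "two_spin_interferogram",
    "free_precession_rotation",
]

#: Canonical Bloch basis states (Ix, Iy, Iz at unit polarization).
IX = np.array([1.0, 0.0, 0.0])
IY = np.array([0.0, 1.0, 0.0])
IZ = np.array([0.0, 0.0, 1.0])


def bloch_state(mx: float, my: float, mz: float) -> NDArray[np.float64]:
    """Build a Bloch vector, validating finiteness."""
    s = np.array([mx, my, mz], dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("Bloch state components must be finite")
    return s


@dataclass(frozen=True)
class PulseShape:
    """Piecewise-constant RF control.

    Parameters
    ----------
    segment_duration : float
        Duration of each segment in seconds.
    amplitudes : ndarray
        Per-segment RF nutation frequencies in Hz (non-negative).
    phases : ndarray
        Per-segment RF phases in radians.
    """

    segment_duration: float
    amplitudes: NDArray[np.float64]
    phases: NDArray[np.float64]

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=float)
        phis = np.asarray(self.phases, dtype=float)
        object.__setattr__(self, "amplitudes", amps)
        object.__setattr__(self, "phases", phis)
        if amps.ndim != 1 or phis.ndim != 1 or amps.shape != phis.shape:
            raise ValueError("amplitudes and phases must be 1-D arrays of equal length")
        if amps.size == 0:
            raise ValueError("pulse must have at least one segment")
        if not (np.all(np.isfinite(amps)) and np.all(np.isfinite(phis))):
            raise ValueError("pulse controls must be finite")
        if np.any(amps < 0):
            raise ValueError("amplitudes must be non-negative")
        if not (self.segment_duration > 0 and np.isfinite(self.segment_duration)):
            raise ValueError("segment_duration must be positive and finite")

    @property
    def n_segments(self) -> int:
        return int(self.amplitudes.size)

    @property
    def duration(self) -> float:
        """Total pulse duration T = n_segments × segment_duration (s)."""
        return self.n_segments * self.segment_duration

    @property
    def max_amplitude(self) -> float:
        return float(self.amplitudes.max())

    def xy_controls(self) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
        """Cartesian controls (ν1 cos φ, ν1 sin φ) in Hz."""
        return (
            self.amplitudes * np.cos(self.phases),
            self.amplitudes * np.sin(self.phases),
        )

    @classmethod
    def from_xy(
        cls, ux: ArrayLike, uy: ArrayLike, segment_duration: float
    ) -> "PulseShape":
        ux = np.asarray(ux, dtype=float)
        uy = np.asarray(uy, dtype=float)
        return cls(
            segment_duration=segment_duration,
            amplitudes=np.hypot(ux, uy),
            phases=np.arctan2(uy, ux),
        )

    @classmethod
    def constant(
        cls, amplitude: float, phase: float, duration: float, n_segments: int = 1
    ) -> "PulseShape":
        """Rectangular pulse of given amplitude (Hz), phase (rad), duration (s)."""
        return cls(
            segment_duration=duration / n_segments,
            amplitudes=np.full(n_segments, amplitude),
            phases=np.full(n_segments, phase),
        )

    @classmethod
    def zero(cls, duration: float, n_segments: int = 1) -> "PulseShape":
        """Free-precession placeholder (all-zero controls)."""
        return cls.constant(0.0, 0.0, duration, n_segments)

    def concatenate(self, other: "PulseShape") -> "PulseShape":
        if not np.isclose(self.segment_duration, other.segment_duration):
            raise ValueError("can only concatenate pulses with equal segment duration")
        return PulseShape(
            segment_duration=self.segment_duration,
            amplitudes=np.concatenate([self.amplitudes, other.amplitudes]),
            phases=np.concatenate([self.phases, other.phases]),
        )


@dataclass(frozen=True)
class TwoSpinSystem:
    """Observed spin weakly coupled to a partner (Cα–Cβ or Cα–CO).

    Offsets are chemical-shift frequencies relative to the carrier, in Hz.
    ``j_range`` bounds the scalar coupling; the default covers the one-bond
    Cα–Cβ range (33–42 Hz).  Set ``j_range=None`` to disable the check
    (e.g. for the ~55 Hz Cα–CO coupling or for J = 0 controls).
    """

    offset_a: float
    offset_b: float
    j: float
    j_range: tuple[float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.j_range is not None:
            lo, hi = self.j_range
            if not (lo <= self.j <= hi):
                raise ValueError(
                    f"J = {self.j} Hz outside physical range [{lo}, {hi}] Hz"
                )


# ---------------------------------------------------------------------------
# Rotations


def _rodrigues(v: NDArray[np.float64]) -> NDArray[np.float64]:
    """Rotation matrices exp([v]×) for rotation vectors v of shape (..., 3).

    Uses the series-safe form R = I + a [v]× + b [v]×² with a = sin θ/θ,
    b = (1−cos θ)/θ², valid at θ → 0.
    """
    v = np.asarray(v, dtype=float)
    theta2 = np.einsum("...i,...i->...", v, v)
    theta = np.sqrt(theta2)
    small = theta < 1e-8
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(small, 1.0 - theta2 / 6.0, np.sin(theta) / np.where(small, 1.0, theta))
        b = np.where(
            small, 0.5 - theta2 / 24.0, (1.0 - np.cos(theta)) / np.where(small, 1.0, theta2)
        )
    K = _skew(v)
    K2 = K @ K
    eye = np.broadcast_to(np.eye(3), K.shape)
    return eye + a[..., None, None] * K + b[..., None, None] * K2


def _skew(v: NDArray[np.float64]) -> NDArray[np.float64]:
    """Cross-product matrices [v]× for v of shape (..., 3)."""
    out = np.zeros(v.shape[:-1] + (3, 3))
    out[..., 0, 1] = -v[..., 2]
    out[..., 0, 2] = v[..., 1]
    out[..., 1, 0] = v[..., 2]
    out[..., 1, 2] = -v[..., 0]
    out[..., 2, 0] = -v[..., 1]
    out[..., 2, 1] = v[..., 0]
    return out


def segment_rotation_vectors(
    pulse: PulseShape, offsets: ArrayLike
) -> NDArray[np.float64]:
    """Rotation vectors (rad) per offset and segment, shape (n_offsets, n_seg, 3)."""
    offsets = np.atleast_1d(np.asarray(offsets, dtype=float))
    if not np.all(np.isfinite(offsets)):
        raise ValueError("offsets must be finite")
    ux, uy = pulse.xy_controls()
    n_off, n_seg = offsets.size, pulse.n_segments
    v = np.empty((n_off, n_seg, 3))
    v[:, :, 0] = ux
    v[:, :, 1] = uy
    v[:, :, 2] = offsets[:, None]
    v *= 2.0 * np.pi * pulse.segment_duration
    return v


def segment_rotations(pulse: PulseShape, offsets: ArrayLike) -> NDArray[np.float64]:
    """Per-segment rotation matrices, shape (n_offsets, n_segments, 3, 3)."""
    return _rodrigues(segment_rotation_vectors(pulse, offsets))


def free_precession_rotation(offset: float, duration: float) -> NDArray[np.float64]:
    """Analytic z-rotation by 2π·offset·duration (the zero-control limit)."""
    phi = 2.0 * np.pi * offset * duration
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def propagate(
    pulse: PulseShape, offset: float, state0: ArrayLike
) -> NDArray[np.float64]:
    """Propagate a Bloch vector through the pulse at a given offset (Hz)."""
    state0 = np.asarray(state0, dtype=float)
    return simulate_profile(pulse, [offset], state0)[0]


def net_rotation(pulse: PulseShape, offset: float) -> NDArray[np.float64]:
    """Net 3×3 rotation of the whole pulse at one offset.

    Applying the result to any Bloch state equals :func:`propagate`.
    """
    R = segment_rotations(pulse, [offset])[0]
    out = np.eye(3)
    for k in range(pulse.n_segments):
        out = R[k] @ out
    return out


def rotation_axis_angle(R: ArrayLike) -> tuple[NDArray[np.float64], float]:
    """Axis (unit vector) and angle in [0, π] of a rotation matrix."""
    from scipy.spatial.transform import Rotation

    rotvec = Rotation.from_matrix(np.asarray(R)).as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    if angle < 1e-15:
        return IZ.copy(), 0.0
    return rotvec / angle, angle


def simulate_profile(
    pulse: PulseShape, offsets: ArrayLike, state0: ArrayLike
) -> NDArray[np.float64]:
    """Final Bloch states over an offset grid, shape (n_offsets, 3).

    Vectorized over offsets; reproduces offset profiles of shaped pulses
    (transverse encoding in the rotation band, Mz inversion in the invert
    bands) when applied to an optimized decoupling pulse.
    """
    offsets = np.atleast_1d(np.asarray(offsets, dtype=float))
    if offsets.size == 0:
        raise ValueError("offset grid must be non-empty")
    state0 = np.asarray(state0, dtype=float)
    R = segment_rotations(pulse, offsets)
    states = np.broadcast_to(state0, (offsets.size, 3)).copy()
    for k in range(pulse.n_segments):
        states = np.einsum("oij,oj->oi", R[:, k], states)
    return states


# ---------------------------------------------------------------------------
# Two-spin (weak coupling) quantum simulation

_SIGMA_X = np.array([[0.0, 1.0], [1.0, 0.0]], dtype=complex)
_SIGMA_Y = np.array([[0.0, -1.0j], [1.0j, 0.0]], dtype=complex)
_SIGMA_Z = np.array([[1.0, 0.0], [0.0, -1.0]], dtype=complex)
_EYE2 = np.eye(2, dtype=complex)

# Observed spin I (first factor), partner S (second factor); spin-1/2 operators.
_IXo = np.kron(_SIGMA_X / 2, _EYE2)
_IYo = np.kron(_SIGMA_Y / 2, _EYE2)
_IZo = np.kron(_SIGMA_Z / 2, _EYE2)
_SXo = np.kron(_EYE2, _SIGMA_X / 2)
_SYo = np.kron(_EYE2, _SIGMA_Y / 2)
_SZo = np.kron(_EYE2, _SIGMA_Z / 2)
_IZSZ = _IZo @ _SZo
_DETECT = _IXo + 1.0j * _IYo

#: Basis z quantum numbers (mI, mS) for |αα⟩, |αβ⟩, |βα⟩, |ββ⟩.
_MI = np.array([0.5, 0.5, -0.5, -0.5])
_MS = np.array([0.5, -0.5, 0.5, -0.5])


def _delay_phases(system: TwoSpinSystem, d: float) -> NDArray[np.complex128]:
    """Diagonal of the free-evolution propagator over delay d (seconds)."""
    e = system.offset_a * _MI + system.offset_b * _MS + system.j * _MI * _MS
    return np.exp(-2.0j * np.pi * e * d)


def two_spin_pulse_propagator(
    pulse: PulseShape, system: TwoSpinSystem
) -> NDArray[np.complex128]:
    """Exact 4×4 propagator of the shaped pulse acting on both spins."""
    dt = pulse.segment_duration
    U = np.eye(4, dtype=complex)
    h_static = (
        system.offset_a * _IZo + system.offset_b * _SZo + system.j * _IZSZ
    )
    for amp, phi in zip(pulse.amplitudes, pulse.phases):
        h_rf = amp * (
            np.cos(phi) * (_IXo + _SXo) + np.sin(phi) * (_IYo + _SYo)
        )
        U = expm(-2.0j * np.pi * (h_static + h_rf) * dt) @ U
    return U


_IDEAL_PI_PARTNER = expm(-1.0j * np.pi * _SXo)


def two_spin_interferogram(
    system: TwoSpinSystem,
    pulse: "PulseShape | str",
    t1_grid: ArrayLike,
    contraction: float | None = None,
    skip_short: bool = True,
) -> NDArray[np.complex128]:
    """Complex observed-spin signal vs indirect evolution time t1.

    For each t1 the observed spin's transverse magnetization evolves for
    d0, the decoupling element runs, and a further d0 of evolution follows.
    The recorded signal is ⟨I+⟩ of the observed spin.

    ``pulse`` may be:

    - ``"none"``     — no decoupling; d0 = t1/2 each side (doublet retained)
    - ``"ideal_pi"`` — instantaneous π on the partner only, at the midpoint
    - a :class:`PulseShape` — full propagation with RF on both spins;
      requires ``contraction`` (the pulse's contraction factor a), and each
      t1 must satisfy t1 ≥ a·T unless ``skip_short`` lets the pulse be
      skipped for shorter increments.
    """
    t1_grid = np.asarray(t1_grid, dtype=float)
    if np.any(t1_grid < 0):
        raise ValueError("t1 values must be non-negative")

    rho0 = _IXo.astype(complex)
    signal = np.empty(t1_grid.size, dtype=complex)

    if isinstance(pulse, str):
        if pulse not in ("none", "ideal_pi"):
            raise ValueError(f"unknown pulse mode {pulse!r}")
        mid = _IDEAL_PI_PARTNER if pulse == "ideal_pi" else np.eye(4, dtype=complex)
        for i, t1 in enumerate(t1_grid):
            ph = _delay_phases(system, 0.5 * t1)
            D = np.diag(ph)
            U = D @ mid @ D
            rho = U @ rho0 @ U.conj().T
            signal[i] = np.trace(rho @ _DETECT)
        return signal

    if contraction is None:
        raise ValueError("contraction factor a is required for shaped-pulse simulation")
    a, T = float(contraction), pulse.duration
    min_t1 = a * T
    Upulse = two_spin_pulse_propagator(pulse, system)
    for i, t1 in enumerate(t1_grid):
        if t1 + 1e-15 < min_t1:
            if not skip_short:
                raise ValueError(
                    f"t1 = {t1:g} s below the minimum evolution time aT = {min_t1:g} s"
                )
            D = np.diag(_delay_phases(system, 0.5 * t1))
            U = D @ D
        else:
            d0 = 0.5 * (t1 - min_t1)
            D = np.diag(_delay_phases(system, d0))
            U = D @ Upulse @ D
        rho = U @ rho0 @ U.conj().T
        signal[i] = np.trace(rho @ _DETECT)
    return signal
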