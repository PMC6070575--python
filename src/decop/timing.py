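"""Contracted-time bookkeeping for mid-t1 decoupling pulses.

During the shaped pulse the observed spins accrue chemical-shift phase at a
uniformly contracted rate: a pulse of real duration T encodes T' = a·T of
evolution.  Inserting the pulse between two free delays of duration

    d0 = (t1 − a·T) / 2

therefore encodes exactly t1 of chemical-shift evolution in 2·d0 + T of
real time — the elapsed time exceeds t1 by the fixed overhead (1 − a)·T,
and, because the contraction is uniform across the band, no offset acquires
an offset-dependent (Bloch–Siegert) frequency error.  The shortest
realizable encoded time with the pulse is t1 = a·T (d0 = 0); shorter
increments skip the pulse and use plain free evolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .targets import DesignSpec

__all__ = ["TimingScheme", "TimingSummary", "encode_delays", "timing_summary"]


@dataclass(frozen=True)
class TimingScheme:
    """Delays for one indirect increment.

    If ``use_pulse``: t1 = 2·d0 + a·T exactly and the real elapsed time is
    2·d0 + T = t1 + (1−a)·T.  Otherwise d0 = t1/2 and there is no overhead.
    ``d0_residual`` is nonzero only when a hardware raster was applied.
    """

    t1: float
    a: float
    T: float
    d0: float
    use_pulse: bool
    overhead: float
    min_t1: float
    d0_residual: float = 0.0

    @property
    def elapsed(self) -> float:
        """Real elapsed time of the encoding element (s)."""
        return 2 * self.d0 + (self.T if self.use_pulse else 0.0)


@dataclass(frozen=True)
class TimingSummary:
    contracted_time: float  # a·T: encoded evolution during the pulse (s)
    overhead: float  # (1−a)·T: elapsed minus encoded time (s)
    min_t1: float  # shortest encoded time with the pulse (s)


def encode_delays(
    t1: float, spec: DesignSpec, raster: float | None = None
) -> TimingScheme:
    """Compute the delay scheme for a desired encoded evolution time t1 (s).

    For t1 ≥ a·T the pulse runs between two delays d0 = (t1 − a·T)/2; at
    exactly t1 = a·T the pulse is used with d0 = 0.  For shorter t1 the
    pulse is skipped.  If ``raster`` is given (s), d0 is rounded *down* to
    that grid and the remainder reported in ``d0_residual``.
    """
    if not (t1 >= 0 and math.isfinite(t1)):
        raise ValueError("t1 must be non-negative and finite")
    a, T = spec.contraction, spec.duration
    aT = a * T
    if t1 >= aT:
        d0 = 0.5 * (t1 - aT)
        use_pulse = True
        overhead = (1 - a) * T
    else:
        d0 = 0.5 * t1
        use_pulse = False
        overhead = 0.0
    residual = 0.0
    if raster is not None:
        if raster <= 0:
            raise ValueError("raster must be positive")
        snapped = math.floor(d0 / raster) * raster
        residual = d0 - snapped
        d0 = snapped
    return TimingScheme(
        t1=t1, a=a, T=T, d0=d0, use_pulse=use_pulse,
        overhead=overhead, min_t1=aT, d0_residual=residual,
    )


def timing_summary(spec: DesignSpec) -> TimingSummary:
    """Contracted time a·T, overhead (1−a)·T, and minimum t1 for a variant."""
    a, T = spec.contraction, spec.duration
    return TimingSummary(contracted_time=a * T, overhead=(1 - a) * T, min_t1=a * T)
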