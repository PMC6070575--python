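"""Optimization target construction for the decoupling pulse variants.

Each pulse variant is described by a :class:`DesignSpec`: one rotation band
(the Cα region, where the pulse must act as a universal z-rotation by
2π·ω·aT — i.e. chemical-shift evolution at a uniformly contracted rate),
one or more inversion bands (CO and selected Cβ regions, where longitudinal
magnetization must be flipped), and optionally preservation bands (Cβ
regions that must be left untouched).

Band edges are given in p.p.m.; the spectrometer field converts them to
rotating-frame offsets in Hz.  The carrier defaults to 55 p.p.m. (mid-Cα).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.typing import NDArray

from .dynamics import IX, IY, IZ, free_precession_rotation

__all__ = [
    "SpectrometerConfig",
    "DesignSpec",
    "TargetSpec",
    "ppm_to_offset",
    "offset_to_ppm",
    "build_targets",
    "builtin_spec",
    "BUILTIN_VARIANTS",
]

#: 13C/1H gyromagnetic-ratio quotient (γC/γH).
CARBON_GAMMA_RATIO = 0.25145


@dataclass(frozen=True)
class SpectrometerConfig:
    """Field strength and carrier placement.

    proton_frequency is in MHz (e.g. 800.0); the 13C base frequency is
    proton_frequency × carbon_gamma_ratio.  carrier_ppm is the 13C carrier
    position; offsets are measured from it.
    """

    proton_frequency: float = 800.0
    carbon_gamma_ratio: float = CARBON_GAMMA_RATIO
    carrier_ppm: float = 55.0

    def __post_init__(self) -> None:
        if not self.proton_frequency > 0:
            raise ValueError("proton_frequency must be positive")
        if not 0 < self.carbon_gamma_ratio < 1:
            raise ValueError("carbon_gamma_ratio must be in (0, 1)")

    @property
    def carbon_frequency(self) -> float:
        """13C base frequency in MHz; 1 p.p.m. equals this many Hz."""
        return self.proton_frequency * self.carbon_gamma_ratio


def ppm_to_offset(ppm: float, cfg: SpectrometerConfig) -> float:
    """Chemical shift (p.p.m.) → rotating-frame offset (Hz)."""
    return (np.asarray(ppm, dtype=float) - cfg.carrier_ppm) * cfg.carbon_frequency


def offset_to_ppm(offset_hz: float, cfg: SpectrometerConfig) -> float:
    """Rotating-frame offset (Hz) → chemical shift (p.p.m.)."""
    return np.asarray(offset_hz, dtype=float) / cfg.carbon_frequency + cfg.carrier_ppm


@dataclass(frozen=True)
class DesignSpec:
    """One pulse variant: bands, duration, amplitude ceiling, contraction.

    Attributes
    ----------
    name : str
    duration : float
        Pulse duration T in seconds.
    max_amplitude : float
        RF amplitude ceiling in Hz.
    contraction : float
        Contraction factor a in (0, 1]; the pulse encodes a·T of
        chemical-shift evolution in the rotation band.
    rotation_band : (lo, hi)
        Cα band in p.p.m.
    invert_bands, preserve_bands : list of (lo, hi)
        Bands (p.p.m.) where Iz → −Iz, respectively Iz → Iz, is required.
    n_rotation, n_invert, n_preserve
        Chemical-shift sample counts per band.
    segment_duration : float
        Default control discretization for optimization (s).
    """

    name: str
    duration: float
    max_amplitude: float
    contraction: float
    rotation_band: tuple[float, float]
    invert_bands: tuple[tuple[float, float], ...] = ()
    preserve_bands: tuple[tuple[float, float], ...] = ()
    n_rotation: int = 100
    n_invert: tuple[int, ...] = ()
    n_preserve: tuple[int, ...] = ()
    segment_duration: float = 1e-6

    def __post_init__(self) -> None:
        if not 0 < self.contraction <= 1:
            raise ValueError("contraction factor a must satisfy 0 < a <= 1")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if not self.max_amplitude > 0:
            raise ValueError("max_amplitude must be positive")
        if self.n_rotation <= 0:
            raise ValueError("sample counts must be positive")
        if len(self.n_invert) != len(self.invert_bands):
            raise ValueError("n_invert must match invert_bands")
        if len(self.n_preserve) != len(self.preserve_bands):
            raise ValueError("n_preserve must match preserve_bands")
        if any(n <= 0 for n in (*self.n_invert, *self.n_preserve)):
            raise ValueError("sample counts must be positive")
        bands = [self.rotation_band, *self.invert_bands, *self.preserve_bands]
        for lo, hi in bands:
            if not lo < hi:
                raise ValueError(f"band [{lo}, {hi}] must have lo < hi")
        for i, (lo1, hi1) in enumerate(bands):
            for lo2, hi2 in bands[i + 1 :]:
                if lo1 < hi2 and lo2 < hi1:
                    raise ValueError(
                        f"bands [{lo1}, {hi1}] and [{lo2}, {hi2}] p.p.m. overlap"
                    )

    @property
    def n_segments(self) -> int:
        return int(round(self.duration / self.segment_duration))

    def with_segments(self, n_segments: int) -> "DesignSpec":
        """Re-discretize the control grid keeping the total duration."""
        return replace(self, segment_duration=self.duration / n_segments)


@dataclass(frozen=True)
class TargetSpec:
    """One optimization target: offset, initial/desired Bloch state, weight."""

    offset: float  # Hz
    initial: NDArray[np.float64]
    desired: NDArray[np.float64]
    weight: float = 1.0
    kind: str = "rotation-tracking"  # rotation-tracking | invert | preserve

    def __post_init__(self) -> None:
        for name in ("initial", "desired"):
            v = np.asarray(getattr(self, name), dtype=float)
            if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-9):
                raise ValueError(f"{name} state must be a unit vector")
            object.__setattr__(self, name, v)
        if self.kind == "rotation-tracking" and abs(self.initial[2]) > 1e-9:
            raise ValueError("rotation-tracking targets must start transverse")


def build_targets(
    spec: DesignSpec, cfg: SpectrometerConfig
) -> list[TargetSpec]:
    """Construct the full target list for a variant.

    Rotation-tracking targets sample the rotation band uniformly; initial
    states alternate +x / +y with sample parity, and the desired state is
    the initial state rotated about z by 2π·ω·aT (the contracted-evolution
    map).  Inversion targets are +z → −z; preservation targets +z → +z.
    """
    targets: list[TargetSpec] = []
    aT = spec.contraction * spec.duration

    lo, hi = spec.rotation_band
    for i, ppm in enumerate(np.linspace(lo, hi, spec.n_rotation)):
        w = ppm_to_offset(ppm, cfg)
        initial = IX if i % 2 == 0 else IY
        desired = free_precession_rotation(w, aT) @ initial
        targets.append(
            TargetSpec(offset=float(w), initial=initial, desired=desired,
                       kind="rotation-tracking")
        )
    for (lo, hi), n in zip(spec.invert_bands, spec.n_invert):
        for ppm in np.linspace(lo, hi, n):
            w = ppm_to_offset(ppm, cfg)
            targets.append(
                TargetSpec(offset=float(w), initial=IZ, desired=-IZ, kind="invert")
            )
    for (lo, hi), n in zip(spec.preserve_bands, spec.n_preserve):
        for ppm in np.linspace(lo, hi, n):
            w = ppm_to_offset(ppm, cfg)
            targets.append(
                TargetSpec(offset=float(w), initial=IZ, desired=IZ, kind="preserve")
            )
    return targets


def targets_as_arrays(
    targets: list[TargetSpec],
) -> tuple[NDArray, NDArray, NDArray, NDArray]:
    """(offsets, initials, desireds, weights) arrays for vectorized code."""
    offsets = np.array([t.offset for t in targets])
    initials = np.stack([t.initial for t in targets])
    desireds = np.stack([t.desired for t in targets])
    weights = np.array([t.weight for t in targets])
    return offsets, initials, desireds, weights


# ---------------------------------------------------------------------------
# Built-in variants.
#
# GOODCOP: CO inversion while Cα encodes (no Cβ decoupling); 150 µs at up to
# 15 kHz, a = 0.9.  BADCOP1: adds inversion of Cβ below ~35 p.p.m.; 1 ms at
# up to 5.94 kHz, a = 0.91.  BADCOP2/3 vary the inverted Cβ band; BADCOP2
# explicitly preserves the remaining upfield Cβ (2 p.p.m. guard bands around
# the inversion band avoid over-constraining the transition regions).
# BADCOP3's rotation band starts at 47 p.p.m., excluding glycine Cα.
# Amplitude ceilings are quoted at 800 MHz and scale with the field.

BUILTIN_VARIANTS: dict[str, DesignSpec] = {
    "GOODCOP": DesignSpec(
        name="GOODCOP",
        duration=150e-6,
        max_amplitude=15_000.0,
        contraction=0.9,
        rotation_band=(35.0, 75.0),
        invert_bands=((165.0, 185.0),),
        n_rotation=100,
        n_invert=(30,),
        segment_duration=0.5e-6,
    ),
    "BADCOP1": DesignSpec(
        name="BADCOP1",
        duration=1e-3,
        max_amplitude=5_940.0,
        contraction=0.91,
        rotation_band=(40.0, 72.0),
        invert_bands=((165.0, 185.0), (5.0, 37.0)),
        n_rotation=100,
        n_invert=(30, 60),
        segment_duration=1e-6,
    ),
    "BADCOP2": DesignSpec(
        name="BADCOP2",
        duration=1e-3,
        max_amplitude=4_870.0,
        contraction=0.91,
        rotation_band=(40.0, 72.0),
        invert_bands=((165.0, 185.0), (28.0, 35.0)),
        preserve_bands=((5.0, 26.0),),
        n_rotation=100,
        n_invert=(30, 30),
        n_preserve=(40,),
        segment_duration=1e-6,
    ),
    "BADCOP3": DesignSpec(
        name="BADCOP3",
        duration=1e-3,
        max_amplitude=7_220.0,
        contraction=0.91,
        rotation_band=(47.0, 72.0),
        invert_bands=((165.0, 185.0), (10.0, 45.0)),
        n_rotation=100,
        n_invert=(30, 60),
        segment_duration=1e-6,
    ),
    # Alternative preset: inversion band upper edge at 43 p.p.m. instead of
    # 45 (both bounds are in circulation for this variant).
    "BADCOP3_ALT": DesignSpec(
        name="BADCOP3_ALT",
        duration=1e-3,
        max_amplitude=7_220.0,
        contraction=0.91,
        rotation_band=(47.0, 72.0),
        invert_bands=((165.0, 185.0), (10.0, 43.0)),
        n_rotation=100,
        n_invert=(30, 60),
        segment_duration=1e-6,
    ),
}


def builtin_spec(name: str, cfg: SpectrometerConfig | None = None) -> DesignSpec:
    """Look up a built-in variant by name (case-insensitive).

    Durations and amplitude ceilings of the built-ins are quoted at 800 MHz;
    if ``cfg`` specifies a different field, duration and ceiling are scaled
    to keep bandwidths (in p.p.m.) and flip angles unchanged.
    """
    key = name.upper()
    if key not in BUILTIN_VARIANTS:
        raise KeyError(
            f"unknown variant {name!r}; choose from {sorted(BUILTIN_VARIANTS)}"
        )
    spec = BUILTIN_VARIANTS[key]
    if cfg is not None and not np.isclose(cfg.proton_frequency, 800.0):
        s = cfg.proton_frequency / 800.0
        n_seg = spec.n_segments
        spec = replace(
            spec,
            duration=spec.duration / s,
            max_amplitude=spec.max_amplitude * s,
        )
        spec = spec.with_segments(n_seg)
    return spec
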