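"""Shaped-pulse file I/O (Bruker JCAMP-DX shape format) and field rescaling.

Shape files store one amplitude/phase pair per segment: amplitude as percent
of the maximum RF level (0–100, absolute power being set at the console) and
phase in degrees in [0, 360).  The Hz ceiling and the total duration are
carried in ``##$``-prefixed metadata lines so a written file round-trips
without external bookkeeping.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.typing import NDArray

from .dynamics import PulseShape

__all__ = ["ShapeFile", "ShapeParseError", "write_shape", "read_shape", "scale_to_field"]


class ShapeParseError(ValueError):
    """Malformed JCAMP-DX shape file; message names the offending line."""


@dataclass
class ShapeFile:
    """Parsed/written shape-file content."""

    title: str
    date: str
    points: int
    amplitudes_percent: NDArray[np.float64]
    phases_deg: NDArray[np.float64]
    metadata: dict[str, str] = field(default_factory=dict)


def write_shape(
    pulse: PulseShape,
    max_amplitude_hz: float,
    path: str | Path,
    title: str | None = None,
) -> ShapeFile:
    """Write a pulse as a JCAMP-DX shape file.

    Amplitudes are normalized so that ``max_amplitude_hz`` maps to 100%.
    A pulse amplitude above the ceiling is an error — shapes are never
    silently clipped on export.  Zero-amplitude segments are written with
    the canonical phase 0.
    """
    if max_amplitude_hz <= 0:
        raise ValueError("max_amplitude_hz must be positive")
    if pulse.max_amplitude > max_amplitude_hz * (1 + 1e-12):
        raise ValueError(
            f"pulse amplitude {pulse.max_amplitude:.3f} Hz exceeds the "
            f"ceiling {max_amplitude_hz:.3f} Hz"
        )
    amp_pct = 100.0 * pulse.amplitudes / max_amplitude_hz
    phase_deg = np.degrees(pulse.phases) % 360.0
    phase_deg[pulse.amplitudes == 0] = 0.0

    title = title or "decop shaped pulse"
    date = _dt.date.today().isoformat()
    n = pulse.n_segments
    lines = [
        f"##TITLE= {title}",
        "##JCAMP-DX= 5.00 $$ decop shape export",
        "##DATA TYPE= Shape Data",
        "##ORIGIN= decop",
        f"##DATE= {date}",
        "##MINX= %.6e" % amp_pct.min(),
        "##MAXX= %.6e" % amp_pct.max(),
        "##MINY= %.6e" % phase_deg.min(),
        "##MAXY= %.6e" % phase_deg.max(),
        "##$SHAPE_EXMODE= None",
        "##$SHAPE_TOTROT= 0.000000e+00",
        "##$SHAPE_BWFAC= 0.000000e+00",
        "##$SHAPE_INTEGFAC= 1.000000e+00",
        "##$SHAPE_MODE= 1",
        "##$SHAPE_MAXAMP_HZ= %.6e" % max_amplitude_hz,
        "##$SHAPE_DURATION_S= %.9e" % pulse.duration,
        f"##NPOINTS= {n}",
        "##XYPOINTS= (XY..XY)",
    ]
    lines += [f"{a:.6f}, {p:.6f}" for a, p in zip(amp_pct, phase_deg)]
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")
    return ShapeFile(
        title=title,
        date=date,
        points=n,
        amplitudes_percent=amp_pct,
        phases_deg=phase_deg,
        metadata={
            "SHAPE_MAXAMP_HZ": f"{max_amplitude_hz:.6e}",
            "SHAPE_DURATION_S": f"{pulse.duration:.9e}",
        },
    )


def parse_shape_file(path: str | Path) -> ShapeFile:
    """Parse a JCAMP-DX shape file into a :class:`ShapeFile`."""
    text = Path(path).read_text()
    lines = text.replace("\r\n", "\n").replace("\r", "\n").split("\n")
    meta: dict[str, str] = {}
    npoints: int | None = None
    data_start: int | None = None
    for i, raw in enumerate(lines):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            body = line[2:]
            if "=" not in body:
                raise ShapeParseError(f"line {i + 1}: malformed header {raw!r}")
            key, _, value = body.partition("=")
            key = key.strip().lstrip("$")
            value = value.split("$$")[0].strip()
            meta[key] = value
            if key == "NPOINTS":
                try:
                    npoints = int(value)
                except ValueError as exc:
                    raise ShapeParseError(f"line {i + 1}: bad NPOINTS {value!r}") from exc
            if key == "XYPOINTS":
                data_start = i + 1
                break
    if npoints is None:
        raise ShapeParseError("missing ##NPOINTS header")
    if data_start is None:
        raise ShapeParseError("missing ##XYPOINTS data block")

    amps, phases = [], []
    for i in range(data_start, len(lines)):
        line = lines[i].strip()
        if not line:
            continue
        if line.startswith("##"):
            break
        parts = line.split(",")
        if len(parts) != 2:
            raise ShapeParseError(f"line {i + 1}: expected 'amplitude, phase', got {line!r}")
        try:
            amps.append(float(parts[0]))
            phases.append(float(parts[1]))
        except ValueError as exc:
            raise ShapeParseError(f"line {i + 1}: non-numeric data {line!r}") from exc
    if len(amps) != npoints:
        raise ShapeParseError(
            f"NPOINTS = {npoints} but {len(amps)} data rows found"
        )
    return ShapeFile(
        title=meta.get("TITLE", ""),
        date=meta.get("DATE", ""),
        points=npoints,
        amplitudes_percent=np.asarray(amps),
        phases_deg=np.asarray(phases),
        metadata=meta,
    )


def read_shape(
    path: str | Path,
    max_amplitude_hz: float | None = None,
    duration: float | None = None,
) -> PulseShape:
    """Read a shape file back into a :class:`PulseShape`.

    The Hz ceiling and duration default to the file's own metadata
    (written by :func:`write_shape`); pass them explicitly for files from
    other sources.
    """
    sf = parse_shape_file(path)
    if max_amplitude_hz is None:
        if "SHAPE_MAXAMP_HZ" not in sf.metadata:
            raise ShapeParseError(
                "file carries no SHAPE_MAXAMP_HZ metadata; pass max_amplitude_hz"
            )
        max_amplitude_hz = float(sf.metadata["SHAPE_MAXAMP_HZ"])
    if duration is None:
        if "SHAPE_DURATION_S" not in sf.metadata:
            raise ShapeParseError(
                "file carries no SHAPE_DURATION_S metadata; pass duration"
            )
        duration = float(sf.metadata["SHAPE_DURATION_S"])
    return PulseShape(
        segment_duration=duration / sf.points,
        amplitudes=sf.amplitudes_percent / 100.0 * max_amplitude_hz,
        phases=np.radians(sf.phases_deg),
    )


def scale_to_field(
    pulse: PulseShape, from_proton_mhz: float, to_proton_mhz: float
) -> PulseShape:
    """Rescale a pulse to a different spectrometer field.

    Band edges in p.p.m. scale with the field in Hz, so stretching the
    duration by from/to and the amplitudes by to/from preserves every
    per-segment flip angle and leaves the offset profile unchanged on a
    p.p.m. axis.
    """
    if from_proton_mhz <= 0 or to_proton_mhz <= 0:
        raise ValueError("field strengths must be positive")
    s = to_proton_mhz / from_proton_mhz
    return PulseShape(
        segment_duration=pulse.segment_duration / s,
        amplitudes=pulse.amplitudes * s,
        phases=pulse.phases.copy(),
    )
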