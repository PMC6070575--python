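"""Shared fixtures: spectrometer config and session-scoped optimized pulses.

The two GRAPE optimizations (GOODCOP, BADCOP1) are the expensive pieces of
the suite, so they run once per session and are reused by every test that
needs a realistic optimized pulse.
"""

import numpy as np
import pytest

from decop.grape import GrapeProblem, GrapeResult, optimize
from decop.targets import SpectrometerConfig, builtin_spec


@pytest.fixture(scope="session")
def cfg() -> SpectrometerConfig:
    return SpectrometerConfig()


@pytest.fixture(scope="session")
def goodcop_result(cfg) -> GrapeResult:
    """Reduced-segment GOODCOP optimization (130 targets, 128 segments)."""
    spec = builtin_spec("GOODCOP")
    problem = GrapeProblem(spec=spec, cfg=cfg, n_segments=128)
    return optimize(problem)


@pytest.fixture(scope="session")
def badcop1_result(cfg) -> GrapeResult:
    """Reduced-segment BADCOP1 optimization (full 190-target set)."""
    spec = builtin_spec("BADCOP1")
    problem = GrapeProblem(spec=spec, cfg=cfg, n_segments=128)
    return optimize(problem)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
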