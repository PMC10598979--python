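"""Shared fixtures: synthetic half-cycles, noise-free configs, tiny records."""

from __future__ import annotations

import numpy as np
import pytest

from ventasync import HalfCycle, SimConfig, VarianceCalibration


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def quiet_cfg():
    """Simulator configuration with measurement noise switched off."""
    return SimConfig(noise_sd_pressure=0.0, noise_sd_flow=0.0)


@pytest.fixture
def floor_calib():
    """Variance calibration at the numerical floor (noise-free data)."""
    return VarianceCalibration(1e-6, 1, "per-breath")


def make_polyline_half(
    slopes,
    break_fracs,
    n=100,
    v_max=0.5,
    intercept=5.0,
    noise_sd=0.0,
    rng=None,
    phase="inspiration",
):
    """Half-cycle whose pressure is an exact polyline in volume.

    ``slopes`` are the segment slopes in traversal order; ``break_fracs`` the
    breakpoint positions as fractions of ``v_max`` (len(slopes) - 1 of them).
    """
    slopes = list(slopes)
    fracs = list(break_fracs)
    assert len(fracs) == len(slopes) - 1
    v = np.linspace(0.0, v_max, n)
    knots_v = [0.0] + [f * v_max for f in fracs] + [v_max]
    knots_p = [intercept]
    for s, a, b in zip(slopes, knots_v[:-1], knots_v[1:]):
        knots_p.append(knots_p[-1] + s * (b - a))
    p = np.interp(v, knots_v, knots_p)
    if noise_sd > 0:
        p = p + (rng or np.random.default_rng(0)).normal(0, noise_sd, n)
    return HalfCycle(phase, v, p)


def random_half(rng, n=None, r=None, noise_sd=0.5, phase="inspiration"):
    """Random polyline half-cycle for property tests."""
    n = n if n is not None else int(rng.integers(60, 200))
    r = r if r is not None else int(rng.integers(1, 5))
    slopes = rng.uniform(-60, 60, r)
    fracs = np.sort(rng.uniform(0.15, 0.85, r - 1)) if r > 1 else []
    return make_polyline_half(slopes, fracs, n=n, noise_sd=noise_sd, rng=rng,
                              phase=phase)
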