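"""Shared phantom fixtures.

Heavy series (multi-time-point, noisy) are session-scoped so unit tests and
the end-to-end property tests reuse one rendering.
"""

from __future__ import annotations

import numpy as np
import pytest

import shg4d as s


@pytest.fixture(scope="session")
def aligned_slab_spec() -> s.PhantomSpec:
    """Noiseless axis-aligned 100×300×30 voxel slab at 1 μm spacing."""
    return s.PhantomSpec(
        nx=128, ny=320, nz=40, dx=1.0, dy=1.0, dz=1.0,
        w0=100.0, length=300.0, h0=30.0,
        swell_amplitude=0.0, mode="inert",
        stripe_contrast=0.2, gain=0.0, read_noise_sd=0.0,
        timestamps=(0.0,), seed=0,
    )


@pytest.fixture(scope="session")
def aligned_slab_stack(aligned_slab_spec):
    return s.generate_stack_series(aligned_slab_spec)[0]


@pytest.fixture(scope="session")
def tilted_slab_stacks():
    """The same slab tilted 18° about y and 15° about x (noiseless)."""
    out = {}
    spec_y = s.PhantomSpec(
        nx=144, ny=320, nz=72, dx=1.0, dy=1.0, dz=1.0,
        w0=100.0, length=300.0, h0=30.0, tilt_y_deg=18.0,
        swell_amplitude=0.0, mode="inert",
        stripe_contrast=0.2, gain=0.0, read_noise_sd=0.0,
        timestamps=(0.0,), seed=0,
    )
    out["y18"] = (spec_y, s.generate_stack_series(spec_y)[0])
    spec_x = s.PhantomSpec(
        nx=128, ny=330, nz=116, dx=1.0, dy=1.0, dz=1.0,
        w0=100.0, length=300.0, h0=30.0, tilt_x_deg=15.0,
        swell_amplitude=0.0, mode="inert",
        stripe_contrast=0.2, gain=0.0, read_noise_sd=0.0,
        timestamps=(0.0,), seed=0,
    )
    out["x15"] = (spec_x, s.generate_stack_series(spec_x)[0])
    return out


@pytest.fixture(scope="session")
def swelling_spec() -> s.PhantomSpec:
    """A = 0.5, τ_s = 10 min, baseline SNR ≈ 10, 10 time points over 50 min."""
    return s.PhantomSpec(
        nx=128, ny=96, nz=44, dx=1.0, dy=1.5, dz=1.0,
        w0=60.0, length=120.0, h0=30.0, tilt_y_deg=5.0,
        swell_amplitude=0.5, tau_s_min=10.0, mode="inert",
        gain=1.0, read_noise_sd=2.0,
        timestamps=tuple(np.linspace(0.0, 50.0, 10)), seed=7,
    )


@pytest.fixture(scope="session")
def swelling_trajectory(swelling_spec):
    return s.build_trajectory(s.generate_stack_series(swelling_spec))


@pytest.fixture(scope="session")
def dilution_spec() -> s.PhantomSpec:
    """Signal-conserving dilution phantom reaching Δw% ≈ +50 by 50 min."""
    return s.PhantomSpec(
        nx=128, ny=96, nz=44, dx=1.0, dy=1.5, dz=1.0,
        w0=60.0, length=120.0, h0=30.0, tilt_y_deg=5.0,
        swell_amplitude=0.5, tau_s_min=6.0, mode="dilution",
        gain=1.0, read_noise_sd=2.0,
        timestamps=tuple(np.linspace(0.0, 50.0, 8)), seed=11,
    )


@pytest.fixture(scope="session")
def dilution_trajectory(dilution_spec):
    return s.build_trajectory(s.generate_stack_series(dilution_spec))


@pytest.fixture(scope="session")
def destruction_spec() -> s.PhantomSpec:
    """Per-voxel decay with τ_d = 10 min; series covers t = 3·τ_d."""
    return s.PhantomSpec(
        nx=128, ny=96, nz=44, dx=1.0, dy=1.5, dz=1.0,
        w0=60.0, length=120.0, h0=30.0, tilt_y_deg=5.0,
        swell_amplitude=0.3, tau_s_min=6.0, mode="destruction", tau_d_min=10.0,
        gain=1.0, read_noise_sd=2.0,
        timestamps=(0.0, 6.0, 12.0, 18.0, 24.0, 30.0), seed=13,
    )


@pytest.fixture(scope="session")
def destruction_trajectory(destruction_spec):
    return s.build_trajectory(s.generate_stack_series(destruction_spec))


def tiny_spec(**overrides) -> s.PhantomSpec:
    """A fast small slab phantom for plumbing tests."""
    params = dict(
        nx=48, ny=40, nz=24, dx=1.5, dy=2.0, dz=1.0,
        w0=30.0, length=60.0, h0=14.0,
        swell_amplitude=0.0, mode="inert",
        gain=0.0, read_noise_sd=0.0,
        timestamps=(0.0, 10.0, 20.0), seed=1,
    )
    params.update(overrides)
    return s.PhantomSpec(**params)
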