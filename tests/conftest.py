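"""Shared fixtures: synthetic channels and trajectories built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from channelgauge.synth import (
    ChannelSpec,
    MotionSchedule,
    linear_schedule,
    make_channel,
    make_trajectory,
    step_schedule,
)


@pytest.fixture(scope="session")
def cylinder_channel():
    """Factory: pore-ring-only channel with constant atom-center radius R."""
    cache: dict[float, tuple] = {}

    def build(R: float):
        if R not in cache:
            spec = ChannelSpec(
                pore_radius=lambda z, R=R: float(R),
                z_range=(-10.0, 10.0),
                ring_spacing=0.5,
            )
            cache[R] = make_channel(spec)
        return cache[R]

    return build


@pytest.fixture(scope="session")
def motif_channel():
    """Tetramer with a surface motif (K21-Q25) and a buried one (Y54-A57)."""
    spec = ChannelSpec(
        z_range=(-12.0, 12.0),
        motif_surface=("K21-Q25",),
        motif_interface=("Y54-A57",),
    )
    return make_channel(spec)


@pytest.fixture(scope="session")
def hinge_trajectory(motif_channel):
    """50-frame noiseless trajectory: PAS −20°, CNBD +10°, occluder slides off."""
    structure, layout = motif_channel
    schedule = MotionSchedule(
        hinge_drift_deg={"PAS": linear_schedule(-20.0), "CNBD": linear_schedule(+10.0)},
        translations={"occluder": ((40.0, 0.0, -15.0), step_schedule(1.0, at=0.5))},
        noise_sigma=0.0,
        seed=7,
    )
    traj, manifest = make_trajectory(structure, schedule, 50, layout)
    return traj, layout, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
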