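"""Shared fixtures: toy models, fixture oscillators, cached heavy screens."""

from __future__ import annotations

import numpy as np
import pytest

import oscidesign as od


@pytest.fixture(scope="session")
def lotka_volterra():
    return od.make_fixture_oscillator("lotka_volterra")


@pytest.fixture(scope="session")
def goodwin():
    return od.make_fixture_oscillator("negative_feedback_3node")


@pytest.fixture(scope="session")
def linear_chain():
    return od.make_fixture_oscillator("linear_chain")


@pytest.fixture(scope="session")
def two_term_toy():
    """dx/dt = a1 + a2 - b*x: the minimal model with a dominance boundary."""
    return od.parse_gma_model("x' = a1 + a2 - b*x")


@pytest.fixture(scope="session")
def cross_toy():
    """dx = a - b*x*y; dy = c*x - d*y: coupled two-variable toy."""
    return od.parse_gma_model("x' = a - b*x*y\ny' = c*x - d*y")


@pytest.fixture(scope="session")
def goodwin_screen(goodwin):
    """Goodwin-loop screen at 100 samples/phenotype (shared by several tests)."""
    return od.run_design_screen(goodwin, samples_per_phenotype=100, seed=1,
                                bounds=(0.1, 10.0))


def make_sine_trajectory(phases_deg, period=20.0, t_end=500.0, dt=0.1,
                         amplitude=0.4, mean=1.0, labels=("Sic1", "Clb5", "Clb3", "Clb2")):
    """Raised sinusoids with prescribed phase lags as a fake Trajectory.

    A positive phase lag delays the peak, so listing increasing lags in
    ``labels`` order produces peaks in that temporal order.
    """
    from oscidesign.limitcycle import Trajectory

    t = np.arange(0.0, t_end + dt / 2, dt)
    ys = []
    for ph in phases_deg:
        ys.append(mean * (1 + amplitude * np.cos(
            2 * np.pi * (t / period) - np.deg2rad(ph))))
    y = np.vstack(ys)
    traj = Trajectory(t, y, tuple(f"v{i}" for i in range(len(phases_deg))))
    traj.windows.append((0, len(t)))
    traj.integrators.append("constructed")
    observables = {lab: f"v{i}" for i, lab in enumerate(labels)}
    return traj, observables
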