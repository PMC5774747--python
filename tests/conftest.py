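"""Shared fixtures: the reference phantom and the (expensive) planning runs
are computed once per session and reused across test modules."""

from __future__ import annotations

import time

import numpy as np
import pytest

from autoplan import (AutoPlanConfig, build_reference_phantom, compute_dose_influence,
                      generate_rings, make_beams, run_autoplan)
from autoplan.autoplanner import initial_optimize, setup_target_and_ring_objectives


@pytest.fixture(scope="session")
def phantom2d():
    return build_reference_phantom("pancreas2d", 0)


@pytest.fixture(scope="session")
def ringed_phantom(phantom2d):
    return generate_rings(phantom2d)


@pytest.fixture(scope="session")
def default_config():
    return AutoPlanConfig()


@pytest.fixture(scope="session")
def dose_influence(ringed_phantom, default_config):
    basis = make_beams(default_config.n_beams, ringed_phantom,
                       beamlet_width=default_config.beamlet_width)
    return compute_dose_influence(basis, ringed_phantom)


@pytest.fixture(scope="session")
def target_ring_objectives(ringed_phantom, default_config):
    return setup_target_and_ring_objectives(ringed_phantom, default_config)


@pytest.fixture(scope="session")
def initial_plan(dose_influence, target_ring_objectives, ringed_phantom, default_config):
    """The normalized target-plus-rings-only plan (controller steps 1-2),
    with its wall-clock runtime."""
    t0 = time.perf_counter()
    res = initial_optimize(dose_influence, target_ring_objectives,
                           ringed_phantom["ptv"], default_config)
    return res, time.perf_counter() - t0


@pytest.fixture(scope="session")
def autoplan_result(phantom2d, default_config, dose_influence):
    """The full automated planning run on the reference phantom, with runtime."""
    t0 = time.perf_counter()
    res = run_autoplan(phantom2d, default_config, dim=dose_influence)
    return res, time.perf_counter() - t0


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
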