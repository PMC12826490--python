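"""Shared fixtures.

Expensive simulations (full-window runs, the calibration grid) are
session-scoped and shared between unit and acceptance tests.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from eggchamber.config import PRESETS, default_config
from eggchamber.geometry import GeometryTimeline
from eggchamber.mesh import build_mesh
from eggchamber.simulator import run


@pytest.fixture(scope="session")
def timeline() -> GeometryTimeline:
    return GeometryTimeline.default()


@pytest.fixture(scope="session")
def sphere_mesh_32():
    return build_mesh(32, 50.0, 50.0)


@pytest.fixture(scope="session")
def prolate_mesh_32():
    return build_mesh(32, 153.5, 64.5)


@pytest.fixture(scope="session")
def default_cfg_n16():
    return default_config(n=16)


@pytest.fixture(scope="session")
def wt_run_n16(default_cfg_n16):
    """Full-window wild-type run at the calibration resolution."""
    return run(default_cfg_n16)


@pytest.fixture(scope="session")
def default_cfg_n32():
    return default_config(n=32)


@pytest.fixture(scope="session")
def wt_run_n32(default_cfg_n32):
    return run(default_cfg_n32)


@pytest.fixture(scope="session")
def perturbation_runs_n32(default_cfg_n32):
    """The three mechanistic perturbation runs of the prediction figure."""
    out = {}
    for name in ("nucleus-stop", "no-fc-shift", "growth-stop"):
        out[name] = run(replace(default_cfg_n32, perturbations=PRESETS[name]))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
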