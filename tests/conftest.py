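"""Shared fixtures.

The heavy session fixtures (the six-condition study matrix and a four-cycle
pulsatile run) are computed once and shared between the integration and
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from dissectflow.conditions import SimulationConfig
from dissectflow.geometry import GeometryParams, generate_dissected_vessel
from dissectflow.simulate import run_pulsatile
from dissectflow.study import StudyPlan, run_condition_matrix


@pytest.fixture(scope="session")
def default_geometry():
    return generate_dissected_vessel(GeometryParams())


@pytest.fixture(scope="session")
def straight_channel_geometry():
    """Single-lumen straight vessel (no dissection, no kink, no bulge)."""
    return generate_dissected_vessel(GeometryParams(
        dissection_length=0.0, kink_angle=0.0, hematoma_bulge_amplitude=0.0))


@pytest.fixture(scope="session")
def normo_run4():
    """Default normotensive/normal-wall run over four cardiac cycles."""
    cfg = SimulationConfig(n_cycles=4, analysis_cycle=3)
    return run_pulsatile(cfg)


@pytest.fixture(scope="session")
def study_matrix():
    """The default six-condition study (3 regimes x 2 wall stiffnesses)."""
    outputs = run_condition_matrix(StudyPlan())
    assert outputs.ok, f"study conditions failed: {list(outputs.errors)}"
    return outputs


@pytest.fixture()
def rng():
    return np.random.default_rng(20240930)
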