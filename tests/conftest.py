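"""Shared fixtures: one steady tube, one pulsatile tube, one synthetic study.

The expensive solves are session-scoped so the oracle checks, the index
invariants and the end-to-end statistics all reuse the same fields.
"""

import numpy as np
import pytest

from hemano import (
    AXISYMMETRIC,
    FluidProperties,
    MeshResolution,
    TransportParameters,
    VesselGeometry,
    Waveform,
    build_mesh,
    solve_no,
    solve_pulsatile,
    solve_steady,
)
from hemano.config import RunConfig
from hemano.synthetic import make_study

TUBE_RADIUS = 0.010
TUBE_LENGTH = 0.060
TUBE_INFLOW = 0.2

WOM_RADIUS = 0.006
WOM_MEAN = 0.15
WOM_AMP = 0.25


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def transport():
    return TransportParameters()


@pytest.fixture(scope="session")
def tube_mesh(fluid):
    geom = VesselGeometry(axial_length=TUBE_LENGTH, inlet_radius=TUBE_RADIUS)
    return build_mesh(
        geom, MeshResolution(n_axial=60, n_lumen=30, n_wall=12), AXISYMMETRIC
    )


@pytest.fixture(scope="session")
def steady_tube_flow(tube_mesh, fluid):
    return solve_steady(tube_mesh, fluid, TUBE_INFLOW)


@pytest.fixture(scope="session")
def steady_tube_no(tube_mesh, steady_tube_flow, transport):
    return solve_no(tube_mesh, steady_tube_flow, transport)


@pytest.fixture(scope="session")
def womersley_waveform():
    return Waveform(period=1.0, a0=WOM_MEAN, a=np.array([0.0]), b=np.array([WOM_AMP]))


@pytest.fixture(scope="session")
def womersley_flow(fluid, womersley_waveform):
    geom = VesselGeometry(axial_length=0.04, inlet_radius=WOM_RADIUS)
    mesh = build_mesh(
        geom, MeshResolution(n_axial=40, n_lumen=28, n_wall=6), AXISYMMETRIC
    )
    return solve_pulsatile(mesh, fluid, womersley_waveform, cycles=4, steps_per_cycle=100)


@pytest.fixture(scope="session")
def study_config():
    """Down-scaled resolution of the default asymmetric-aneurysm study."""
    return RunConfig(
        seed=1,
        resolution=MeshResolution(n_axial=60, n_lumen=20, n_wall=8),
        steps_per_cycle=50,
        cycles=3,
    )


@pytest.fixture(scope="session")
def study(study_config, tmp_path_factory):
    """Generated synthetic study bundle (runs the full simulation once)."""
    outdir = tmp_path_factory.mktemp("study")
    return make_study(study_config, outdir)


@pytest.fixture(scope="session")
def analyzed_study(study):
    """Pipeline results for the session study directory."""
    from hemano import pipeline

    results = pipeline.run_all(study["dir"])
    return {"results": results, **study}
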