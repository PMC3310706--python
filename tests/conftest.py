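"""Shared fixtures: parameter sets and synthetic datasets (generated at test
time; nothing is read from disk)."""

from __future__ import annotations

import numpy as np
import pytest

from hemowave import (
    AnalysisConfig,
    HemoParams,
    NoiseSpec,
    ReducedWaveParams,
    StimulusSpec,
    make_flatmap_dataset,
    recover_parameters,
)
from hemowave.grids import SpatioTemporalGrid

#: Subject-1 empirical wave parameters used as simulation ground truth
SUBJECT1 = {
    "foveal": ReducedWaveParams(v_beta=2.3, Gamma=0.86),
    "peripheral": ReducedWaveParams(v_beta=1.8, Gamma=0.56),
}

NOISELESS = NoiseSpec(white_sd=0.0, ar1_coefficient=0.0, drift_amplitude=0.0, seed=0)


@pytest.fixture(scope="session")
def default_params() -> HemoParams:
    return HemoParams()


@pytest.fixture(scope="session")
def small_grid() -> SpatioTemporalGrid:
    return SpatioTemporalGrid(dx=0.75, dt=0.25, nx=32, nt=128)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Straight-centerline noiseless dataset at the default (v_beta, Gamma)."""
    return make_flatmap_dataset(ReducedWaveParams(3.0, 0.8), noise=NOISELESS)


@pytest.fixture(scope="session")
def subject_fits():
    """Noiseless Subject-1 simulations run through the full pipeline.

    The spatial-decay window 1 mm < |x| <= 5 mm matches the empirical
    regression range.
    """
    cfg = AnalysisConfig(k_fit_range=(1.0, 5.0))
    out = {}
    for name, red in SUBJECT1.items():
        ds = make_flatmap_dataset(red, noise=NOISELESS)
        est, report = recover_parameters(ds, cfg)
        out[name] = (ds, est, report)
    return out


@pytest.fixture(scope="session")
def curved_dataset():
    """Noiseless dataset with a cubic centerline (full 2-D simulation).

    A shorter 4-block session keeps the 2-D spectral solve light.
    """
    spec = StimulusSpec(n_blocks=4)
    centerline = [0.5, 0.03, 0.0, 0.0008]
    return make_flatmap_dataset(ReducedWaveParams(3.0, 0.8), spec=spec,
                                centerline=centerline, noise=NOISELESS)
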