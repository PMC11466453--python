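"""Shared fixtures.

The expensive two-module delay ensemble is session-scoped so the
reduction round-trip and Fisher-information tests reuse one simulation.
"""

from __future__ import annotations

import numpy as np
import pytest

from sensmem.experiments import estimate_pfs, preset_params
from sensmem.network import NetworkParams, SimConfig, simulate


def small_params(**kw) -> NetworkParams:
    """A 60-neuron-per-module network for fast structural tests."""
    return NetworkParams(Ns=60, Nm=60, **kw)


@pytest.fixture(scope="session")
def two_module_pf():
    """Preferred features of the two-module preset (5 s stimulus epoch)."""
    params, mode = preset_params("two_module")
    pf, tc = estimate_pfs(params, mode=mode, grid_n=24)
    return params, mode, pf


@pytest.fixture(scope="session")
def two_module_delay_ensemble(two_module_pf):
    """Stochastic delay ensemble of the two-module network.

    8 cue orientations x 500 realizations, memory rates recorded at 1 s
    and 4 s into the delay.  Shared by the error-statistics,
    Fisher-information and reduction round-trip tests.
    """
    params, mode, pf = two_module_pf
    thetas = np.arange(8) / 8 * 180.0
    cfg = SimConfig(
        t_stim=500.0,
        t_delay=4000.0,
        n_real=500,
        noise_model="poisson_like",
        seed=1234,
        record_times=[1500.0, 4500.0],
    )
    res = simulate(params, thetas, cfg, mode=mode)
    return params, pf, thetas, res
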