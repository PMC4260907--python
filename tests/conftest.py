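"""Shared fixtures: small, session-scoped simulations.

The small fixtures (96x96 sheet, dt = 0.1 ms, shortened recordings) keep
the per-test cost low; the acceptance tests run the full-size study
conditions themselves.
"""

from __future__ import annotations

import numpy as np
import pytest

from rotormap.egm_forward import electrode_grid, unipolar_egm_array
from rotormap.scenarios import simulate_scenario
from rotormap.tissue_sim import (
    AlievPanfilovParams,
    StimulusProtocol,
    TissueGrid,
    run_protocol,
)


@pytest.fixture(scope="session")
def planewave_vm():
    """Plane-wave recording, 2 s at 1 kHz on the full 128x128 sheet."""
    return simulate_scenario("plane-wave", duration_ms=2000.0, seed=0, dt_ms=0.1)


@pytest.fixture(scope="session")
def stable_rotor_vm():
    """Stable-spiral recording, 3 s at 1 kHz on the full sheet."""
    return simulate_scenario("stable-rotor", duration_ms=3000.0, seed=0, dt_ms=0.1)


@pytest.fixture(scope="session")
def meander_rotor_vm():
    """Meandering-spiral recording, 6 s at 1 kHz."""
    return simulate_scenario("meandering-rotor", duration_ms=6000.0, seed=0, dt_ms=0.1)


@pytest.fixture(scope="session")
def stable_rotor_egms(stable_rotor_vm):
    array = electrode_grid(stable_rotor_vm.grid, pitch=1.0, h=1.0)
    rng = np.random.default_rng([0, 977])
    egms = unipolar_egm_array(stable_rotor_vm, array, noise_mv_rms=0.005, rng=rng)
    return egms, array


@pytest.fixture(scope="session")
def planewave_egms(planewave_vm):
    array = electrode_grid(planewave_vm.grid, pitch=1.0, h=1.0)
    rng = np.random.default_rng([0, 977])
    egms = unipolar_egm_array(planewave_vm, array, noise_mv_rms=0.005, rng=rng)
    return egms, array


@pytest.fixture(scope="session")
def small_tissue():
    """Small homogeneous sheet for solver unit tests."""
    return TissueGrid(nx=48, ny=48, dx=0.25, diffusion=0.02,
                      kinetics=AlievPanfilovParams(a=0.15, tau_ms=8.0))


@pytest.fixture()
def edge_protocol():
    def make(tissue: TissueGrid, count: int = 2, cl: float = 300.0) -> StimulusProtocol:
        region = np.zeros((tissue.ny, tissue.nx), dtype=bool)
        region[:, :3] = True
        return StimulusProtocol(
            s1_cycle_length=cl, s1_count=count, s1_region=region, stim_amplitude=1.0
        )

    return make


@pytest.fixture(scope="session")
def figure_of_eight_vm():
    """Cross-field S2 confined to a mid-sheet band creates two
    counter-rotating spirals (figure-of-eight reentry)."""
    tg = TissueGrid(nx=128, ny=128, dx=0.25, diffusion=0.02,
                    kinetics=AlievPanfilovParams(a=0.15, tau_ms=8.0))
    s1 = np.zeros((128, 128), dtype=bool)
    s1[:, :4] = True
    s2 = np.zeros((128, 128), dtype=bool)
    s2[32:96, :80] = True
    proto = StimulusProtocol(
        s1_cycle_length=500.0, s1_count=1, s1_region=s1,
        s2_count=1, s2_coupling_interval=330.0, s2_region=s2,
        stim_amplitude=1.0,
    )
    vm = run_protocol(tg, proto, duration_ms=3500.0, dt_ms=0.1)
    out = vm.crop_time(1000.0, 3500.0)
    out.t0_ms = 0.0
    return out
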