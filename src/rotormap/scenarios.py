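"""Canonical simulation fixtures: plane wave, stable rotor, meandering rotor,
conduction-block line.

Each scenario bundles a tissue, an S1-S2 stimulus protocol and an
initialization transient, and returns a :class:`~rotormap.tissue_sim.VmField`
whose t = 0 is the start of the analysis window (the transient is cropped
off).  Scenario parameters were calibrated once so that:

- the plane-wave sheet is paced periodically from one edge (passive,
  organized activation everywhere);
- the stable-rotor sheet sustains a single anchored spiral (tip excursion
  well under 2.5 mm) via cross-field S1-S2;
- the meandering-rotor sheet (more excitable kinetics, a = 0.12) sustains a
  spiral whose tip wanders over more than 10 mm;
- the block-line sheet is the plane-wave sheet with an inexcitable strip
  whose wake produces intermediate-complexity electrograms.

All scenarios are deterministic for a given seed.
"""

from __future__ import annotations

import numpy as np

from rotormap.tissue_sim import (
    AlievPanfilovParams,
    StimulusProtocol,
    TissueGrid,
    VmField,
    run_protocol,
)

__all__ = ["SCENARIOS", "simulate_scenario", "make_scenario"]

SCENARIOS = ("plane-wave", "stable-rotor", "meandering-rotor", "block-line")

# Pacing period for plane-wave / block-line trains (ms).  Slower than the
# spiral rotation period, faster than sinus rhythm: an organized
# fibrillatory-like passive rate.
_PLANE_CL_MS = 300.0
# Cross-field S2 coupling intervals (ms from the S1 onset) found inside the
# vulnerable window for each kinetics variant.
_STABLE_CI_MS = 330.0
_MEANDER_CI_MS = 180.0
# Fraction of each dimension covered by the cross-field S2 region.  5/8
# anchors the spiral's core well inside the sheet.
_S2_FRACTION = 0.625


def _edge_region(ny: int, nx: int, cells: int = 4) -> np.ndarray:
    r = np.zeros((ny, nx), dtype=bool)
    r[:, :cells] = True
    return r


def _corner_region(ny: int, nx: int, frac: float) -> np.ndarray:
    r = np.zeros((ny, nx), dtype=bool)
    r[: int(ny * frac), : int(nx * frac)] = True
    return r


def make_scenario(
    name: str,
    *,
    nx: int = 128,
    ny: int = 128,
    dx: float = 0.25,
    n_beats: int = 16,
) -> tuple[TissueGrid, StimulusProtocol, float]:
    """Build (tissue, protocol, transient_ms) for a named scenario.

    ``transient_ms`` is the initialization time cropped from the returned
    recording (S1 conditioning and, for rotors, spiral formation).
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")

    if name in ("plane-wave", "block-line"):
        kinetics = AlievPanfilovParams(a=0.15, tau_ms=8.0)
        mask = None
        if name == "block-line":
            # inexcitable strip: x in [12, 20] mm, y in [15.5, 16.25] mm
            # (0.75 mm thick: thin enough that over-strip electrodes still
            # see adjacent tissue, giving block-level rather than
            # rotor-level entropy)
            mask = np.ones((ny, nx), dtype=bool)
            cx0, cx1 = int(12.0 / dx), int(20.0 / dx)
            cy0, cy1 = int(15.5 / dx), int(16.25 / dx)
            mask[cy0:cy1, cx0:cx1] = False
        tissue = TissueGrid(
            nx=nx, ny=ny, dx=dx, diffusion=0.02, kinetics=kinetics,
            conduction_mask=mask,
        )
        protocol = StimulusProtocol(
            s1_cycle_length=_PLANE_CL_MS,
            s1_count=n_beats,
            s1_region=_edge_region(ny, nx),
            stim_amplitude=1.0,
        )
        transient = _PLANE_CL_MS  # skip the first (wavefront-only) beat
        return tissue, protocol, transient

    if name == "stable-rotor":
        # high threshold anchors a rigidly rotating core
        kinetics = AlievPanfilovParams(a=0.15, tau_ms=8.0)
        ci = _STABLE_CI_MS
    else:
        # meandering-rotor: lower excitability -> wandering core; the
        # shorter time constant keeps the rotation cycle atrial-like
        # (~190 ms) so each 500-sample window spans 2-3 activations
        kinetics = AlievPanfilovParams(a=0.18, tau_ms=5.0)
        ci = _MEANDER_CI_MS
    tissue = TissueGrid(nx=nx, ny=ny, dx=dx, diffusion=0.02, kinetics=kinetics)
    protocol = StimulusProtocol(
        s1_cycle_length=500.0,
        s1_count=1,
        s1_region=_edge_region(ny, nx),
        s2_count=1,
        s2_coupling_interval=ci,
        s2_region=_corner_region(ny, nx, _S2_FRACTION),
        stim_amplitude=1.0,
    )
    transient = 1000.0  # S1 + S2 + one rotation to settle
    return tissue, protocol, transient


def simulate_scenario(
    name: str,
    duration_ms: float = 4000.0,
    *,
    seed: int = 0,
    nx: int = 128,
    ny: int = 128,
    dx: float = 0.25,
    dt_ms: float = 0.05,
    dt_sample_ms: float = 1.0,
) -> VmField:
    """Run a named scenario and return ``duration_ms`` of Vm with t0 = 0.

    The scenario's initialization transient is simulated and cropped, so
    frame 0 of the result is the start of the analysis window.
    """
    tissue, protocol, transient = make_scenario(name, nx=nx, ny=ny, dx=dx)
    total = transient + duration_ms
    if name in ("plane-wave", "block-line"):
        # enough beats to cover the requested duration
        n_beats = int(np.ceil(total / _PLANE_CL_MS)) + 1
        protocol = StimulusProtocol(
            s1_cycle_length=protocol.s1_cycle_length,
            s1_count=n_beats,
            s1_region=protocol.s1_region,
            stim_amplitude=protocol.stim_amplitude,
        )
    vm = run_protocol(
        tissue, protocol, total, dt_ms=dt_ms, dt_sample_ms=dt_sample_ms, seed=seed
    )
    out = vm.crop_time(transient, total)
    out.t0_ms = 0.0
    return out
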