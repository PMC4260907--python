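"""2D monodomain excitable-tissue simulator for desk-scale rotor studies.

The tissue is a square sheet of coupled excitable cells obeying the
monodomain reaction-diffusion equation

    du/dt = div(D grad u) + f(u, v) / tau,   dv/dt = g(u, v) / tau,

with two-variable Aliev-Panfilov phenomenological kinetics

    f(u, v) = k u (1 - u)(u - a) - u v,
    g(u, v) = (eps0 + mu1 v / (u + mu2)) (-v - k u (u - a - 1)),

where ``u`` is the dimensionless action potential (0 = rest, ~1 = peak),
``v`` the recovery variable, ``a`` the excitation threshold, and ``tau``
a time scale in ms per dimensionless time unit that calibrates the action
potential duration and rotation period to atrial-like values.  The sheet
supports plane waves, stable (anchored) spiral waves, meandering spirals
and conduction-block lines — the activation patterns whose electrograms
the entropy mapping pipeline is built to discriminate.

Numerics: explicit forward-Euler, 5-point Laplacian, no-flux boundaries;
cells flagged inexcitable in ``conduction_mask`` exchange no diffusive
flux with their neighbours (internal no-flux obstacles).  The dimensionless
``u`` is affinely rescaled to mV, resting -80 mV and peak about +20 mV, so
the downstream electrogram amplitudes and ShEn bin widths are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "AlievPanfilovParams",
    "TissueGrid",
    "StimulusProtocol",
    "VmField",
    "step_monodomain",
    "run_protocol",
    "track_phase_singularities",
    "VM_REST_MV",
    "VM_SPAN_MV",
]

# Affine map from dimensionless u to transmembrane potential:
# Vm = VM_REST_MV + VM_SPAN_MV * u  (u = 0 -> -80 mV, u = 1 -> +20 mV).
VM_REST_MV = -80.0
VM_SPAN_MV = 100.0

# Safety factor applied to the explicit-scheme diffusion stability bound
# dt <= dx^2 / (4 D).
STABILITY_SAFETY = 0.9


@dataclass(frozen=True)
class AlievPanfilovParams:
    """Two-variable phenomenological kinetics parameters.

    ``a`` controls excitability (lower = more excitable, broader action
    potential); ``eps0``, ``mu1``, ``mu2`` shape the recovery dynamics and
    hence the restitution behaviour that decides whether a spiral rotates
    rigidly or meanders.  ``tau_ms`` converts dimensionless model time to
    milliseconds.
    """

    k: float = 8.0
    a: float = 0.10
    eps0: float = 0.002
    mu1: float = 0.2
    mu2: float = 0.3
    tau_ms: float = 12.9


@dataclass
class TissueGrid:
    """Geometry, diffusion and kinetics of the simulated sheet.

    ``diffusion`` is a scalar (isotropic) coefficient in mm^2/ms.
    ``conduction_mask`` is True for excitable cells; False cells are
    inexcitable obstacles that block diffusive flux (conduction-block
    lines are built by masking a strip of cells).
    """

    nx: int = 128
    ny: int = 128
    dx: float = 0.25
    diffusion: float = 0.03
    kinetics: AlievPanfilovParams = field(default_factory=AlievPanfilovParams)
    conduction_mask: NDArray[np.bool_] | None = None

    def __post_init__(self) -> None:
        if self.nx < 16 or self.ny < 16:
            raise ValueError("grid must be at least 16x16 cells")
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if self.diffusion < 0:
            raise ValueError("diffusion must be non-negative")
        if self.conduction_mask is None:
            self.conduction_mask = np.ones((self.ny, self.nx), dtype=bool)
        else:
            self.conduction_mask = np.asarray(self.conduction_mask, dtype=bool)
            if self.conduction_mask.shape != (self.ny, self.nx):
                raise ValueError(
                    f"conduction_mask shape {self.conduction_mask.shape} != "
                    f"(ny, nx) = {(self.ny, self.nx)}"
                )

    @property
    def extent_mm(self) -> tuple[float, float]:
        """Physical sheet size (x, y) in mm."""
        return (self.nx * self.dx, self.ny * self.dx)

    def max_stable_dt(self) -> float:
        """Largest explicit-Euler dt (ms) allowed by the diffusion bound."""
        if self.diffusion == 0:
            return np.inf
        return STABILITY_SAFETY * self.dx**2 / (4.0 * self.diffusion)

    def cell_centers_mm(self) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
        """(x, y) coordinates of cell centers, each shaped (ny, nx)."""
        x = (np.arange(self.nx) + 0.5) * self.dx
        y = (np.arange(self.ny) + 0.5) * self.dx
        return np.meshgrid(x, y)


@dataclass(frozen=True)
class StimulusProtocol:
    """S1-S2 stimulation protocol.

    An S1 train of ``s1_count`` beats at ``s1_cycle_length`` ms is applied
    to ``s1_region``; after a coupling interval measured from the last S1
    onset, a burst of ``s2_count`` ectopic beats at ``s2_cycle_length`` ms
    is delivered to ``s2_region``.  Regions are boolean cell masks.
    Cross-field geometry (S1 along one edge, S2 a quadrant) with a coupling
    interval inside the vulnerable window initiates reentry.
    """

    s1_cycle_length: float = 1000.0
    s1_count: int = 1
    s1_region: NDArray[np.bool_] | None = None
    s2_count: int = 0
    s2_coupling_interval: float = 0.0
    s2_cycle_length: float = 100.0
    s2_region: NDArray[np.bool_] | None = None
    stim_duration_ms: float = 2.0
    stim_amplitude: float = 2.0  # du/dt added while stimulating, per ms
    s2_jitter_ms: float = 0.0  # seeded uniform jitter on S2 onsets

    def __post_init__(self) -> None:
        if self.s1_cycle_length <= 0 or self.s2_cycle_length <= 0:
            raise ValueError("cycle lengths must be positive")
        if self.s1_count < 1:
            raise ValueError("need at least one S1 beat")

    def validate_regions(self, tissue: TissueGrid) -> None:
        shape = (tissue.ny, tissue.nx)
        if self.s1_region is None or not np.any(self.s1_region):
            raise ValueError("s1_region is empty")
        if np.asarray(self.s1_region).shape != shape:
            raise ValueError("s1_region shape does not match grid")
        if self.s2_count > 0:
            if self.s2_region is None or not np.any(self.s2_region):
                raise ValueError("s2_region is empty but s2_count > 0")
            if np.asarray(self.s2_region).shape != shape:
                raise ValueError("s2_region shape does not match grid")


@dataclass
class VmField:
    """Transmembrane-potential movie Vm(y, x, t) on the sheet, in mV.

    ``values`` has shape (n_frames, ny, nx); frame ``i`` is at time
    ``t0_ms + i * dt_sample_ms``.
    """

    values: NDArray[np.float32]
    dt_sample_ms: float
    t0_ms: float
    grid: TissueGrid

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1000.0 / self.dt_sample_ms

    @property
    def times_ms(self) -> NDArray[np.float64]:
        return self.t0_ms + np.arange(self.n_frames) * self.dt_sample_ms

    def frame_at(self, t_ms: float) -> NDArray[np.float32]:
        i = int(round((t_ms - self.t0_ms) / self.dt_sample_ms))
        return self.values[i]

    def crop_time(self, t_start_ms: float, t_end_ms: float) -> "VmField":
        i0 = int(round((t_start_ms - self.t0_ms) / self.dt_sample_ms))
        i1 = int(round((t_end_ms - self.t0_ms) / self.dt_sample_ms))
        return VmField(
            values=self.values[i0:i1],
            dt_sample_ms=self.dt_sample_ms,
            t0_ms=self.t0_ms + i0 * self.dt_sample_ms,
            grid=self.grid,
        )


def _masked_laplacian(u: np.ndarray, mask: np.ndarray, dx: float) -> np.ndarray:
    """5-point Laplacian with no-flux outer boundaries and masked obstacles.

    Flux between a cell and a neighbour is zero if either is masked out,
    which makes obstacle edges internal no-flux boundaries.
    """
    lap = np.zeros_like(u)
    m = mask
    # x-direction fluxes
    d = u[:, 1:] - u[:, :-1]
    d *= m[:, 1:] & m[:, :-1]
    lap[:, :-1] += d
    lap[:, 1:] -= d
    # y-direction fluxes
    d = u[1:, :] - u[:-1, :]
    d *= m[1:, :] & m[:-1, :]
    lap[:-1, :] += d
    lap[1:, :] -= d
    return lap / dx**2


def step_monodomain(
    u: np.ndarray,
    v: np.ndarray,
    tissue: TissueGrid,
    dt: float,
    stim: np.ndarray | float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance the state (u, v) one explicit-Euler step of ``dt`` ms.

    ``stim`` is an additive du/dt source (per ms), scalar or per-cell.
    Raises if ``dt`` violates the explicit diffusion stability bound.
    """
    dt_max = tissue.max_stable_dt()
    if dt > dt_max:
        raise ValueError(
            f"dt = {dt} ms is unstable for dx = {tissue.dx} mm, "
            f"D = {tissue.diffusion} mm^2/ms: require dt <= "
            f"{STABILITY_SAFETY} * dx^2 / (4 D) = {dt_max:.4g} ms"
        )
    p = tissue.kinetics
    mask = tissue.conduction_mask
    lap = _masked_laplacian(u, mask, tissue.dx)
    f = p.k * u * (1.0 - u) * (u - p.a) - u * v
    g = (p.eps0 + p.mu1 * v / (u + p.mu2)) * (-v - p.k * u * (u - p.a - 1.0))
    du = tissue.diffusion * lap + (f / p.tau_ms)
    if np.ndim(stim) or stim:
        du = du + stim
    u_next = u + dt * du
    v_next = v + dt * (g / p.tau_ms)
    # inexcitable cells stay at rest
    u_next[~mask] = 0.0
    v_next[~mask] = 0.0
    return u_next, v_next


def run_protocol(
    tissue: TissueGrid,
    protocol: StimulusProtocol,
    duration_ms: float,
    *,
    dt_ms: float = 0.05,
    dt_sample_ms: float = 1.0,
    seed: int = 0,
    record_recovery: bool = False,
) -> VmField:
    """Run an S1-S2 protocol and record Vm at ``dt_sample_ms`` resolution.

    Deterministic for a given seed; the seed only perturbs S2 beat onsets
    when ``protocol.s2_jitter_ms`` is non-zero.

    Returns a :class:`VmField` in mV.  When ``record_recovery`` is set the
    returned field carries the final (u, v) state in ``_final_state`` for
    protocol chaining.
    """
    if duration_ms < 0:
        raise ValueError("duration must be non-negative")
    n_frames = int(round(duration_ms / dt_sample_ms))
    if n_frames == 0:
        return VmField(
            values=np.empty((0, tissue.ny, tissue.nx), dtype=np.float32),
            dt_sample_ms=dt_sample_ms,
            t0_ms=0.0,
            grid=tissue,
        )
    protocol.validate_regions(tissue)
    if dt_ms > tissue.max_stable_dt():
        raise ValueError(
            f"dt_ms = {dt_ms} violates the stability bound "
            f"{tissue.max_stable_dt():.4g} ms"
        )

    rng = np.random.default_rng(seed)
    s1_onsets = np.arange(protocol.s1_count) * protocol.s1_cycle_length
    last_s1 = s1_onsets[-1]
    s2_onsets = (
        last_s1
        + protocol.s2_coupling_interval
        + np.arange(protocol.s2_count) * protocol.s2_cycle_length
    )
    if protocol.s2_jitter_ms > 0 and protocol.s2_count > 0:
        s2_onsets = s2_onsets + rng.uniform(
            -protocol.s2_jitter_ms, protocol.s2_jitter_ms, size=protocol.s2_count
        )

    mask = tissue.conduction_mask
    u = np.zeros((tissue.ny, tissue.nx))
    v = np.zeros_like(u)
    s1_stim = np.where(protocol.s1_region, protocol.stim_amplitude, 0.0)
    s2_stim = (
        np.where(protocol.s2_region, protocol.stim_amplitude, 0.0)
        if protocol.s2_count > 0
        else None
    )

    values = np.empty((n_frames, tissue.ny, tissue.nx), dtype=np.float32)
    steps_per_frame = max(1, int(round(dt_sample_ms / dt_ms)))
    dt = dt_sample_ms / steps_per_frame  # exact frame alignment
    t = 0.0
    for frame in range(n_frames):
        # recorded Vm is saturated to the physiological range; only the
        # stimulated cells during the 2 ms pulses ever exceed it
        values[frame] = VM_REST_MV + VM_SPAN_MV * np.clip(u, -0.2, 1.2)
        for _ in range(steps_per_frame):
            stim = 0.0
            if np.any((t >= s1_onsets) & (t < s1_onsets + protocol.stim_duration_ms)):
                stim = s1_stim
            if s2_stim is not None and np.any(
                (t >= s2_onsets) & (t < s2_onsets + protocol.stim_duration_ms)
            ):
                stim = stim + s2_stim if np.ndim(stim) else s2_stim
            u, v = step_monodomain(u, v, tissue, dt, stim)
            t += dt

    vm = VmField(values=values, dt_sample_ms=dt_sample_ms, t0_ms=0.0, grid=tissue)
    if record_recovery:
        vm._final_state = (u, v)  # type: ignore[attr-defined]
    return vm


def _plaquette_charges(phase: np.ndarray) -> np.ndarray:
    """Topological charge of every 2x2 plaquette of a phase field.

    Sums the wrapped phase differences around each elementary loop;
    returns an integer array of shape (ny-1, nx-1) with values in
    {-1, 0, +1} (charge = winding / 2 pi).
    """

    def wrap(d: np.ndarray) -> np.ndarray:
        return (d + np.pi) % (2.0 * np.pi) - np.pi

    d1 = wrap(phase[:-1, 1:] - phase[:-1, :-1])
    d2 = wrap(phase[1:, 1:] - phase[:-1, 1:])
    d3 = wrap(phase[1:, :-1] - phase[1:, 1:])
    d4 = wrap(phase[:-1, :-1] - phase[1:, :-1])
    winding = d1 + d2 + d3 + d4
    return np.rint(winding / (2.0 * np.pi)).astype(int)


def track_phase_singularities(
    vm: VmField,
    *,
    frame_stride: int = 10,
    margin_cells: int = 4,
    edge_ms: float = 100.0,
) -> list[tuple[float, float, float, int]]:
    """Locate spiral-wave tips as phase singularities of the Vm movie.

    The per-cell phase is the Hilbert-transform (analytic-signal) phase of
    the mean-subtracted Vm time series; a rotor tip is a plaquette whose
    topological charge is +/-1.  Returns a list of
    ``(t_ms, x_mm, y_mm, charge)`` tuples, one per singularity per
    analyzed frame (every ``frame_stride``-th frame).  A plane wave yields
    an empty list.  ``margin_cells`` suppresses spurious boundary defects;
    ``edge_ms`` excludes frames near the start/end of the recording where
    the analytic-signal phase is distorted by the transform's edge effect.
    """
    from scipy.signal import hilbert

    if vm.n_frames < 3:
        return []
    # analytic-signal phase, computed in row blocks to bound memory
    phase = np.empty(vm.values.shape, dtype=np.float32)
    block = max(1, int(2e7 // max(1, vm.n_frames * vm.grid.nx)))
    for r0 in range(0, vm.grid.ny, block):
        x = vm.values[:, r0 : r0 + block, :].astype(np.float64)
        x -= x.mean(axis=0, keepdims=True)
        phase[:, r0 : r0 + block, :] = np.angle(hilbert(x, axis=0))
    dx = vm.grid.dx
    out: list[tuple[float, float, float, int]] = []
    mask = vm.grid.conduction_mask
    # plaquette must have all four corners excitable
    plaq_ok = mask[:-1, :-1] & mask[:-1, 1:] & mask[1:, :-1] & mask[1:, 1:]
    m = margin_cells
    edge_frames = int(round(edge_ms / vm.dt_sample_ms))
    edge_frames = min(edge_frames, max(0, (vm.n_frames - 1) // 2))
    for i in range(edge_frames, vm.n_frames - edge_frames, frame_stride):
        q = _plaquette_charges(phase[i])
        q[~plaq_ok] = 0
        if m > 0:
            q[:m, :] = 0
            q[-m:, :] = 0
            q[:, :m] = 0
            q[:, -m:] = 0
        ys, xs = np.nonzero(q)
        t = vm.t0_ms + i * vm.dt_sample_ms
        for yy, xx in zip(ys, xs):
            # plaquette center in mm (corner cells at centers (i+.5)dx)
            out.append((t, (xx + 1.0) * dx, (yy + 1.0) * dx, int(q[yy, xx])))
    return out


def singularity_trajectory(
    points: list[tuple[float, float, float, int]],
) -> NDArray[np.float64]:
    """Stack tracked singularities as an (n, 4) array [t, x, y, charge]."""
    if not points:
        return np.empty((0, 4))
    return np.asarray(points, dtype=np.float64)
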