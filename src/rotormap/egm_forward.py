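"""Virtual electrograms from the Vm field: extracellular-potential forward model.

The extracellular potential at an electrode located at r' above the sheet
is the current-source integral

    phi_e(r') = -(sigma_i / sigma_e) * (1 / 4 pi) *
                integral  grad Vm . grad_s (1 / |r' - r_s|)  dv,

i.e. each tissue cell contributes a current dipole proportional to the
local transmembrane-potential gradient, weighted by the gradient of the
inverse distance to the electrode.  The integral is discretized with
central-difference gradients on cell centers and a differential volume
dv = dx^2 * thickness (one 0.25 mm cell layer: the 2D reduction of the
volume integral).  Unipolar electrograms are this potential at a single
electrode held ``h`` mm above the sheet; bipolar electrograms subtract two
closely spaced unipolar recordings.

Amplitude convention: sigma_i/sigma_e enters only as a global ratio
(default 0.4) and a fixed gain calibrates plane-wave unipolar deflections
to about 1 mV peak-to-peak, so ShEn amplitude bins of 0.01 mV are
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from rotormap.tissue_sim import TissueGrid, VmField

__all__ = [
    "ElectrodeArray",
    "EGMSignal",
    "unipolar_egm",
    "unipolar_egm_array",
    "bipolar_egm",
    "electrode_grid",
    "DEFAULT_RATIO_SIGMA",
    "DEFAULT_HEIGHT_MM",
    "SHEET_THICKNESS_MM",
    "AMPLITUDE_GAIN",
]

DEFAULT_RATIO_SIGMA = 0.4
DEFAULT_HEIGHT_MM = 1.0
SHEET_THICKNESS_MM = 0.25
# Global gain calibrated once so that the plane-wave fixture's unipolar
# peak-to-peak amplitude is ~1 mV at h = 1 mm (the model itself carries no
# absolute amplitude calibration).
AMPLITUDE_GAIN = 0.61


@dataclass
class ElectrodeArray:
    """A set of recording electrodes above the sheet.

    ``positions`` holds (x, y, h) triples in mm: (x, y) on the sheet plane,
    h the height above it (h > 0 so no electrode coincides with a source).
    """

    positions: NDArray[np.float64]
    ratio_sigma: float = DEFAULT_RATIO_SIGMA
    bipole_spacing: float = 1.0
    bipole_orientation: str = "horizontal"
    grid_shape: tuple[int, int] | None = None  # (ny, nx) if a regular grid

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=np.float64))
        if self.positions.shape[1] != 3:
            raise ValueError("positions must be (n, 3) [x, y, h] in mm")
        if np.any(self.positions[:, 2] <= 0):
            raise ValueError("electrode height h must be > 0 for every electrode")
        if self.ratio_sigma <= 0:
            raise ValueError("ratio_sigma must be > 0")
        if self.bipole_spacing <= 0:
            raise ValueError("bipole_spacing must be > 0")
        if self.bipole_orientation not in ("horizontal", "vertical"):
            raise ValueError("bipole_orientation must be 'horizontal' or 'vertical'")

    @property
    def n_electrodes(self) -> int:
        return len(self.positions)


@dataclass
class EGMSignal:
    """One electrode's electrogram: samples in mV at sampling rate fs."""

    samples: NDArray[np.float64]
    fs: float
    position: NDArray[np.float64]
    polarity: str = "unipolar"
    pole_positions: NDArray[np.float64] | None = None  # both poles if bipolar

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite EGM samples")

    @property
    def duration_ms(self) -> float:
        return len(self.samples) * 1000.0 / self.fs


def _gradients(vm_frames: np.ndarray, dx: float) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference spatial gradients of Vm frames (t, ny, nx), mV/mm."""
    gy, gx = np.gradient(vm_frames.astype(np.float64), dx, axis=(1, 2))
    return gx, gy


def _lead_field_weights(
    grid: TissueGrid, electrode: np.ndarray, ratio_sigma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell dipole weights (wx, wy) for one electrode at (x, y, h)."""
    ex, ey, h = electrode
    if h <= 0:
        raise ValueError("electrode height h must be > 0 (r = 0 otherwise)")
    cx, cy = grid.cell_centers_mm()
    rx = ex - cx
    ry = ey - cy
    r3 = (rx**2 + ry**2 + h**2) ** 1.5
    dv = grid.dx**2 * SHEET_THICKNESS_MM
    c = -ratio_sigma * dv * AMPLITUDE_GAIN / (4.0 * np.pi)
    return c * rx / r3, c * ry / r3


def unipolar_egm(
    vm: VmField,
    electrode: tuple[float, float, float] | np.ndarray,
    ratio_sigma: float = DEFAULT_RATIO_SIGMA,
) -> EGMSignal:
    """Unipolar electrogram at one electrode (x, y, h) in mm.

    A uniform Vm frame contributes exactly zero (no gradient, no dipoles).
    """
    electrode = np.asarray(electrode, dtype=np.float64)
    ex, ey, h = electrode
    w, l_ = vm.grid.extent_mm
    margin = 2.0
    if not (-margin <= ex <= w + margin and -margin <= ey <= l_ + margin):
        raise ValueError(
            f"electrode ({ex}, {ey}) projects outside the sheet "
            f"[0, {w}] x [0, {l_}] mm (margin {margin} mm)"
        )
    wx, wy = _lead_field_weights(vm.grid, electrode, ratio_sigma)
    gx, gy = _gradients(vm.values, vm.grid.dx)
    samples = np.einsum("tij,ij->t", gx, wx) + np.einsum("tij,ij->t", gy, wy)
    return EGMSignal(samples=samples, fs=vm.fs, position=electrode)


def unipolar_egm_array(
    vm: VmField,
    array: ElectrodeArray,
    chunk_frames: int = 512,
    noise_mv_rms: float = 0.0,
    rng: np.random.Generator | None = None,
) -> NDArray[np.float64]:
    """Unipolar EGMs for every electrode of an array, shape (n_elec, n_t).

    Identical to calling :func:`unipolar_egm` per electrode but batched:
    the per-electrode lead-field weights form a matrix applied to the
    flattened Vm gradients frame-chunk by frame-chunk (memory-bounded).
    ``noise_mv_rms`` adds seeded white Gaussian measurement noise (mV RMS)
    to every channel; a ``rng`` must be supplied when it is non-zero.
    """
    grid = vm.grid
    n_e = array.n_electrodes
    n_cells = grid.nx * grid.ny
    wmat = np.empty((2 * n_cells, n_e))
    for k, pos in enumerate(array.positions):
        wx, wy = _lead_field_weights(grid, pos, array.ratio_sigma)
        wmat[:n_cells, k] = wx.ravel()
        wmat[n_cells:, k] = wy.ravel()
    out = np.empty((n_e, vm.n_frames))
    for i0 in range(0, vm.n_frames, chunk_frames):
        frames = vm.values[i0 : i0 + chunk_frames]
        gx, gy = _gradients(frames, grid.dx)
        g = np.concatenate(
            [gx.reshape(len(frames), -1), gy.reshape(len(frames), -1)], axis=1
        )
        out[:, i0 : i0 + len(frames)] = (g @ wmat).T
    if noise_mv_rms > 0:
        if rng is None:
            raise ValueError("noise_mv_rms > 0 requires an rng for reproducibility")
        out += rng.normal(0.0, noise_mv_rms, size=out.shape)
    return out


def bipolar_egm(
    vm: VmField,
    center: tuple[float, float, float] | np.ndarray,
    spacing: float = 1.0,
    orientation: str = "horizontal",
    ratio_sigma: float = DEFAULT_RATIO_SIGMA,
) -> EGMSignal:
    """Bipolar electrogram: difference of two unipolar EGMs ``spacing`` mm
    apart, centered on ``center``, along the given orientation.

    Zero spacing gives an identically zero signal (identical poles).
    """
    center = np.asarray(center, dtype=np.float64)
    if orientation == "horizontal":
        offset = np.array([spacing / 2.0, 0.0, 0.0])
    elif orientation == "vertical":
        offset = np.array([0.0, spacing / 2.0, 0.0])
    else:
        raise ValueError("orientation must be 'horizontal' or 'vertical'")
    p1 = center + offset
    p2 = center - offset
    e1 = unipolar_egm(vm, p1, ratio_sigma)
    e2 = unipolar_egm(vm, p2, ratio_sigma)
    return EGMSignal(
        samples=e1.samples - e2.samples,
        fs=vm.fs,
        position=center,
        polarity="bipolar",
        pole_positions=np.stack([p1, p2]),
    )


def electrode_grid(
    tissue: TissueGrid,
    pitch: float = 1.0,
    h: float = DEFAULT_HEIGHT_MM,
    ratio_sigma: float = DEFAULT_RATIO_SIGMA,
) -> ElectrodeArray:
    """Regular electrode grid covering the sheet.

    Electrodes sit at (i * pitch, j * pitch, h) for
    i = 0 .. floor(extent / pitch); a 32 mm sheet at 1 mm pitch gives a
    33 x 33 array.  ``pitch`` may not resolve below the tissue grid (dx).
    """
    if pitch < tissue.dx:
        raise ValueError(f"pitch {pitch} mm < tissue dx {tissue.dx} mm")
    if h <= 0:
        raise ValueError("electrode height h must be > 0")
    w, l_ = tissue.extent_mm
    nx = int(np.floor(w / pitch)) + 1
    ny = int(np.floor(l_ / pitch)) + 1
    xs = np.arange(nx) * pitch
    ys = np.arange(ny) * pitch
    gx, gy = np.meshgrid(xs, ys)
    pos = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, h)])
    return ElectrodeArray(positions=pos, ratio_sigma=ratio_sigma, grid_shape=(ny, nx))
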