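"""Dynamic entropy maps over an electrode grid and rotor-tip comparison.

A dynamic ApEn map assigns each electrode site one ApEn value per
non-overlapping window (1000-point windows to track stable rotors,
500-point windows for meandering ones); the sequence of frames is colored
on a common scale from 0 (blue) to the map-sequence global maximum (red),
so no "high ApEn" threshold is ever pre-specified.  The rotor tip in a
frame is the amplitude-weighted centroid of the connected hot region
(sites at >= 90% of that frame's maximum) containing the frame maximum;
a frame whose maximum does not exceed a plane-wave calibration floor is
declared rotor-free.  Shannon-entropy maps use 4 s windows and 0.01 mV
amplitude bins.

Maps are evaluated over an observation area that excludes the pacing
near-field (stimulus artifacts) and a small border strip (no-flux sheet
boundary effects); both margins are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from rotormap.entropy import apen, shannon_entropy

__all__ = [
    "EntropyMapSequence",
    "RotorTrack",
    "observation_mask",
    "build_map",
    "shen_map",
    "locate_tip_apen",
    "calibration_floor",
    "compare_tips",
    "NO_ROTOR",
]

NO_ROTOR = None

HOT_FRACTION = 0.9  # hot region: sites >= 90% of the frame maximum


@dataclass
class EntropyMapSequence:
    """Per-window entropy value per electrode site.

    ``frames`` is (n_windows, ny, nx); NaN marks sites outside the
    observation area.  ``global_max`` is the color-scale maximum over the
    whole sequence (blue = 0, red = global_max).
    """

    frames: NDArray[np.float64]
    window: int
    pitch_mm: float
    estimator: str
    params: dict = field(default_factory=dict)
    origin_mm: tuple[float, float] = (0.0, 0.0)

    @property
    def global_max(self) -> float:
        finite = self.frames[np.isfinite(self.frames)]
        return float(finite.max()) if finite.size else 0.0

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def site_xy(self, ix: int, iy: int) -> tuple[float, float]:
        return (
            self.origin_mm[0] + ix * self.pitch_mm,
            self.origin_mm[1] + iy * self.pitch_mm,
        )


def observation_mask(
    grid_shape: tuple[int, int],
    pitch_mm: float = 1.0,
    pacing_margin_mm: float = 6.0,
    border_margin_mm: float = 3.0,
    pacing_edge: str = "left",
) -> NDArray[np.bool_]:
    """Electrode sites retained for map analysis.

    Excludes ``pacing_margin_mm`` from the stimulated edge (pacing
    artifact near-field) and ``border_margin_mm`` from the other sheet
    borders (no-flux boundary effects).
    """
    ny, nx = grid_shape
    x = np.arange(nx) * pitch_mm
    y = np.arange(ny) * pitch_mm
    xx, yy = np.meshgrid(x, y)
    xmax, ymax = x[-1], y[-1]
    b = border_margin_mm
    keep = (xx >= b) & (xx <= xmax - b) & (yy >= b) & (yy <= ymax - b)
    p = pacing_margin_mm
    if pacing_edge == "left":
        keep &= xx >= p
    elif pacing_edge == "right":
        keep &= xx <= xmax - p
    elif pacing_edge == "bottom":
        keep &= yy >= p
    elif pacing_edge == "top":
        keep &= yy <= ymax - p
    elif pacing_edge != "none":
        raise ValueError(f"unknown pacing_edge {pacing_edge!r}")
    return keep


def build_map(
    egms: NDArray[np.float64],
    grid_shape: tuple[int, int],
    window: int = 1000,
    *,
    m: int = 3,
    r_frac: float = 0.38,
    pitch_mm: float = 1.0,
    mask: NDArray[np.bool_] | None = None,
) -> EntropyMapSequence:
    """Dynamic ApEn map: one ApEn value per site per non-overlapping window.

    ``egms`` is (n_sites, n_t) in electrode-grid row-major order; all
    sites must share the same length (>= window).
    """
    egms = np.asarray(egms, dtype=np.float64)
    ny, nx = grid_shape
    if egms.ndim != 2 or egms.shape[0] != ny * nx:
        raise ValueError(f"egms shape {egms.shape} does not match grid {grid_shape}")
    n_t = egms.shape[1]
    if n_t < window:
        raise ValueError(f"signals of length {n_t} shorter than window {window}")
    n_win = n_t // window
    frames = np.full((n_win, ny * nx), np.nan)
    keep = np.ones(ny * nx, bool) if mask is None else mask.ravel()
    for i in np.nonzero(keep)[0]:
        for w in range(n_win):
            seg = egms[i, w * window : (w + 1) * window]
            frames[w, i] = apen(seg, m=m, r_frac=r_frac)
    return EntropyMapSequence(
        frames=frames.reshape(n_win, ny, nx),
        window=window,
        pitch_mm=pitch_mm,
        estimator="apen",
        params={"m": m, "r_frac": r_frac},
    )


def shen_map(
    egms: NDArray[np.float64],
    grid_shape: tuple[int, int],
    window: int = 4000,
    *,
    bin_width_mv: float = 0.01,
    pitch_mm: float = 1.0,
    mask: NDArray[np.bool_] | None = None,
) -> EntropyMapSequence:
    """Shannon-entropy map: 4 s windows, 0.01 mV amplitude bins."""
    egms = np.asarray(egms, dtype=np.float64)
    ny, nx = grid_shape
    if egms.ndim != 2 or egms.shape[0] != ny * nx:
        raise ValueError(f"egms shape {egms.shape} does not match grid {grid_shape}")
    n_t = egms.shape[1]
    if n_t < window:
        raise ValueError(f"signals of length {n_t} shorter than window {window}")
    n_win = n_t // window
    frames = np.full((n_win, ny * nx), np.nan)
    keep = np.ones(ny * nx, bool) if mask is None else mask.ravel()
    for i in np.nonzero(keep)[0]:
        for w in range(n_win):
            seg = egms[i, w * window : (w + 1) * window]
            frames[w, i] = shannon_entropy(seg, bin_width_mv)
    return EntropyMapSequence(
        frames=frames.reshape(n_win, ny, nx),
        window=window,
        pitch_mm=pitch_mm,
        estimator="shen",
        params={"bin_width_mv": bin_width_mv},
    )


def calibration_floor(planewave_map: EntropyMapSequence, safety: float = 1.2) -> float:
    """Rotor-detection floor from a plane-wave (passive activation)
    calibration run: ``safety`` times its global maximum."""
    return safety * planewave_map.global_max


def hot_region(frame: NDArray[np.float64]) -> NDArray[np.bool_]:
    """Connected component of sites >= 90% of the frame maximum that
    contains the frame maximum (4-connectivity)."""
    from scipy import ndimage

    finite = np.isfinite(frame)
    if not finite.any():
        return np.zeros_like(finite)
    fmax = np.nanmax(frame)
    hot = finite & (frame >= HOT_FRACTION * fmax)
    labels, _ = ndimage.label(hot)
    iy, ix = np.unravel_index(np.nanargmax(np.where(finite, frame, -np.inf)), frame.shape)
    return labels == labels[iy, ix]


def locate_tip_apen(
    frame: NDArray[np.float64],
    pitch_mm: float = 1.0,
    floor: float | None = None,
    origin_mm: tuple[float, float] = (0.0, 0.0),
) -> tuple[float, float] | None:
    """Rotor tip in one map frame, or ``NO_ROTOR``.

    The tip is the amplitude-weighted centroid of the hot region (>= 90%
    of the frame maximum, connected to it).  When a calibration ``floor``
    is given and the frame maximum does not exceed it, the frame is
    declared rotor-free.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if not np.isfinite(frame).any():
        raise ValueError("frame has no finite sites")
    fmax = float(np.nanmax(frame))
    if floor is not None and fmax <= floor:
        return NO_ROTOR
    comp = hot_region(frame)
    ys, xs = np.nonzero(comp)
    w = frame[ys, xs]
    cx = float((w * xs).sum() / w.sum()) * pitch_mm + origin_mm[0]
    cy = float((w * ys).sum() / w.sum()) * pitch_mm + origin_mm[1]
    return (cx, cy)


@dataclass
class RotorTrack:
    """Per-interval tip positions from the LAT and ApEn methods, with
    their Euclidean distances (mm)."""

    table: pd.DataFrame  # columns: interval, x_lat, y_lat, x_apen, y_apen, d_mm
    method: str = "lat-vs-apen"

    @property
    def max_distance_mm(self) -> float:
        return float(self.table["d_mm"].max())

    @property
    def mean_distance_mm(self) -> float:
        return float(self.table["d_mm"].mean())


def compare_tips(
    track_lat: list[tuple[tuple[float, float], tuple[float, float] | None]],
    track_apen: list[tuple[tuple[float, float], tuple[float, float] | None]],
) -> RotorTrack:
    """Euclidean distance between LAT and ApEn tips per matching interval.

    Each track is a list of ``((t_start, t_end), tip_or_None)``; interval
    boundaries must match exactly.  Intervals where either method reports
    no rotor get NaN distance.
    """
    if [iv for iv, _ in track_lat] != [iv for iv, _ in track_apen]:
        raise ValueError("interval mismatch between tracks")
    rows = []
    for (iv, tip_l), (_, tip_a) in zip(track_lat, track_apen):
        if tip_l is None or tip_a is None:
            d = np.nan
            xl, yl = tip_l if tip_l else (np.nan, np.nan)
            xa, ya = tip_a if tip_a else (np.nan, np.nan)
        else:
            xl, yl = tip_l
            xa, ya = tip_a
            d = float(np.hypot(xl - xa, yl - ya))
        rows.append(
            {
                "interval": f"{iv[0] / 1000:g} to {iv[1] / 1000:g}",
                "x_lat": xl,
                "y_lat": yl,
                "x_apen": xa,
                "y_apen": ya,
                "d_mm": d,
            }
        )
    return RotorTrack(table=pd.DataFrame(rows))
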