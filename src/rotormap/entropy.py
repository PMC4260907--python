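"""Approximate entropy and Shannon entropy of electrogram segments.

Approximate entropy (ApEn) is Pincus's regularity statistic: for an
N-sample segment, embedding dimension ``m`` and tolerance ``r`` it measures
the (negative log-) conditional probability that runs of ``m`` samples that
match within ``r`` (Chebyshev distance, self-matches included) still match
when extended by one sample.  Irregular, fractionated electrograms produce
high ApEn; organized periodic activations produce low ApEn.

The tolerance is expressed as a fraction of the standard deviation of the
segment under analysis, which makes ApEn invariant to affine rescaling of
the signal (amplifier gain, electrode contact) and lets a single parameter
pair (m, r) be applied across heterogeneous recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "ApEnParams",
    "EntropySeries",
    "apen",
    "apen_profile",
    "shannon_entropy",
    "windowed_entropy",
]


@dataclass(frozen=True)
class ApEnParams:
    """ApEn parameter triple: embedding dimension, tolerance fraction, length.

    Attributes
    ----------
    m : int
        Embedding (pattern) dimension, 1..5.
    r_frac : float
        Tolerance as a fraction of the analyzed segment's standard
        deviation, in (0, 1].
    n : int
        Segment length in samples; must exceed ``m + 1``.
    """

    m: int = 2
    r_frac: float = 0.2
    n: int = 1000

    def __post_init__(self) -> None:
        if not 1 <= self.m <= 5:
            raise ValueError(f"embedding dimension m must be in 1..5, got {self.m}")
        if not 0.0 < self.r_frac <= 1.0:
            raise ValueError(f"r_frac must be in (0, 1], got {self.r_frac}")
        if self.n <= self.m + 1:
            raise ValueError(f"segment length n={self.n} must exceed m+1={self.m + 1}")


@dataclass
class EntropySeries:
    """Entropy evaluated on consecutive non-overlapping windows of a signal."""

    values: NDArray[np.float64]
    window: int
    hop: int
    t_start_ms: NDArray[np.float64]
    estimator: str = "apen"
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)


def _check_segment(x: np.ndarray, m: int) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size <= m + 1:
        raise ValueError(f"segment length {x.size} must exceed m+1={m + 1}")
    if not np.all(np.isfinite(x)):
        raise ValueError("segment contains non-finite samples")
    return x


def _chebyshev_template_matrix(x: np.ndarray, m: int) -> np.ndarray:
    """Pairwise Chebyshev distances between all length-``m`` templates of x.

    Built incrementally: D_m[i, j] = max_{k < m} |x[i+k] - x[j+k]|.
    """
    a = np.abs(x[:, None] - x[None, :])
    n = x.size
    d = a[: n - m + 1, : n - m + 1].copy()
    for k in range(1, m):
        np.maximum(d, a[k : k + n - m + 1, k : k + n - m + 1], out=d)
    return d


def _phi(d: np.ndarray, r: float) -> float:
    """Phi^m = mean_i ln(C_i^m(r)) with C_i the fraction of templates within r."""
    counts = np.count_nonzero(d <= r, axis=1)
    return float(np.mean(np.log(counts / d.shape[0])))


def apen(x: ArrayLike, m: int = 2, r_frac: float = 0.2) -> float:
    """Approximate entropy of a 1-D segment (Pincus convention).

    Self-matches are included, distances are Chebyshev, logarithms natural,
    and the tolerance is ``r = r_frac * std(x)``.  A constant segment
    returns exactly 0 (every template matches every other at r = 0).

    Parameters
    ----------
    x : array-like
        Signal segment, length > m + 1, finite.
    m : int
        Embedding dimension.
    r_frac : float
        Tolerance as a fraction of the segment standard deviation.

    Returns
    -------
    float
        ApEn(m, r, N) >= 0.
    """
    x = _check_segment(x, m)
    r = r_frac * float(np.std(x))
    a = np.abs(x[:, None] - x[None, :])
    n = x.size
    d = a[: n - m + 1, : n - m + 1].copy()
    for k in range(1, m):
        np.maximum(d, a[k : k + n - m + 1, k : k + n - m + 1], out=d)
    phi_m = _phi(d, r)
    np.maximum(d[: n - m, : n - m], a[m:, m:], out=d[: n - m, : n - m])
    phi_m1 = _phi(d[: n - m, : n - m], r)
    return phi_m - phi_m1


def apen_profile(
    x: ArrayLike,
    ms: ArrayLike,
    r_fracs: ArrayLike,
) -> NDArray[np.float64]:
    """ApEn over a whole (m, r) grid for one segment, sharing distance work.

    Computes the pairwise-distance matrices once per embedding dimension and
    thresholds them against every tolerance, which makes exhaustive grid
    searches (5 x 30 combinations) tractable on hundreds of signals.

    Returns
    -------
    ndarray, shape (len(ms), len(r_fracs))
        ``out[i, j] = apen(x, ms[i], r_fracs[j])``, bitwise-consistent with
        :func:`apen` up to floating-point summation order.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    ms = np.asarray(ms, dtype=int)
    r_fracs = np.asarray(r_fracs, dtype=np.float64)
    m_max = int(ms.max())
    x = _check_segment(x, m_max)
    rs = r_fracs * float(np.std(x))
    n = x.size
    a = np.abs(x[:, None] - x[None, :])

    # phi[m] has shape (len(rs),) for m = 1 .. m_max + 1
    phis: dict[int, np.ndarray] = {}
    d = a.copy()
    for m in range(1, m_max + 2):
        if m > 1:
            np.maximum(
                d[: n - m + 1, : n - m + 1],
                a[m - 1 :, m - 1 :],
                out=d[: n - m + 1, : n - m + 1],
            )
        dm = d[: n - m + 1, : n - m + 1]
        if m in ms or m - 1 in ms:
            phis[m] = _phi_multi_r(dm, rs)
    return np.stack([phis[int(m)] - phis[int(m) + 1] for m in ms])


def _phi_multi_r(dm: np.ndarray, rs: np.ndarray) -> np.ndarray:
    """Phi^m for every tolerance in (sorted-ascending) ``rs`` at once.

    Bins each pairwise distance into the tolerance grid with one
    searchsorted pass, then converts per-row bin histograms into
    cumulative match counts; comparisons are exactly ``d <= r``.
    """
    n_i = dm.shape[0]
    n_r = rs.size
    order = np.argsort(rs, kind="stable")
    rs_sorted = rs[order]
    pos = np.searchsorted(rs_sorted, dm.ravel(), side="left")
    row_idx = np.repeat(np.arange(n_i), n_i)
    flat = row_idx * (n_r + 1) + pos
    hist = np.bincount(flat, minlength=n_i * (n_r + 1)).reshape(n_i, n_r + 1)
    counts = hist[:, :n_r].cumsum(axis=1)
    phi_sorted = np.log(counts / n_i).mean(axis=0)
    phi = np.empty_like(phi_sorted)
    phi[order] = phi_sorted
    return phi


def shannon_entropy(x: ArrayLike, bin_width_mv: float = 0.01) -> float:
    """Shannon entropy (bits) of the amplitude histogram of a segment.

    The histogram uses fixed-width bins anchored at the segment minimum;
    ShEn = -sum p_k log2 p_k over occupied bins.  A segment confined to a
    single bin returns 0.

    Parameters
    ----------
    x : array-like
        Non-empty signal segment in mV.
    bin_width_mv : float
        Amplitude bin width in mV (> 0).
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty segment")
    if not np.all(np.isfinite(x)):
        raise ValueError("segment contains non-finite samples")
    if bin_width_mv <= 0:
        raise ValueError("bin_width_mv must be > 0")
    idx = np.floor((x - x.min()) / bin_width_mv).astype(np.int64)
    counts = np.bincount(idx)
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def windowed_entropy(
    x: ArrayLike,
    window: int,
    estimator: str = "apen",
    *,
    fs: float = 1000.0,
    t0_ms: float = 0.0,
    m: int = 2,
    r_frac: float = 0.2,
    bin_width_mv: float = 0.01,
) -> EntropySeries:
    """Entropy on consecutive non-overlapping windows ("dynamic" evaluation).

    One value per complete window; a trailing partial window is discarded.
    For ApEn, the tolerance is recomputed from each window's own standard
    deviation, so every window is an independent ApEn evaluation.

    Parameters
    ----------
    x : array-like
        Full signal.
    window : int
        Window length in samples; must not exceed the signal length.
    estimator : {"apen", "shen"}
        Which entropy to evaluate per window.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if window > x.size:
        raise ValueError(f"window {window} exceeds signal length {x.size}")
    if window <= 0:
        raise ValueError("window must be positive")
    n_win = x.size // window
    vals = np.empty(n_win)
    for w in range(n_win):
        seg = x[w * window : (w + 1) * window]
        if estimator == "apen":
            vals[w] = apen(seg, m=m, r_frac=r_frac)
        elif estimator == "shen":
            vals[w] = shannon_entropy(seg, bin_width_mv)
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
    t_start = t0_ms + np.arange(n_win) * window * 1000.0 / fs
    params = (
        {"m": m, "r_frac": r_frac}
        if estimator == "apen"
        else {"bin_width_mv": bin_width_mv}
    )
    return EntropySeries(
        values=vals,
        window=window,
        hop=window,
        t_start_ms=t_start,
        estimator=estimator,
        params=params,
    )
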