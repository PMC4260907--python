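"""ApEn parameter optimization against labeled fractionation classes.

The embedding dimension m and tolerance fraction r are selected by
exhaustive grid search (m = 1..5, r = 0.02..0.60 in steps of 0.02; 150
combinations).  For each combination, ApEn is computed on the first
``window`` samples of every signal, the values are min-max normalized to
[0, 1] across the dataset, and two separation criteria are scored on the
per-class distributions, summed over the three adjacent class pairs
(C0,C1), (C1,C2), (C2,C3):

- interclass percentile distance  D_P  = sum_k [Q1(C_{k+1}) - Q3(C_k)],
- interclass min-max distance     D_MM = sum_k [min(C_{k+1}) - max(C_k)],

with type-7 (linear-interpolation) quantiles.  Larger values mean the
interquartile boxes (respectively the full ranges) of adjacent classes
are better separated in the right order.  The objective F equally weights
both criteria after each is min-max rescaled to [0, 1] across the grid
(equal weighting is only meaningful on a common scale):

    F = 0.5 * (D_P~ + D_MM~).

Ties in argmax F break toward the smallest m, then the smallest r (prefer
the simplest estimator).  K-fold validation re-runs the search on
stratified training partitions and reports how often the fold optimum
agrees with the full-data optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy.stats import spearmanr
from sklearn.model_selection import StratifiedKFold

from rotormap.entropy import apen_profile
from rotormap.synthetic_egm import CLASSES, FractionationDataset

__all__ = [
    "GRID_M",
    "GRID_R",
    "ClassApEnDistribution",
    "GridSearchResult",
    "interclass_percentile_distance",
    "interclass_minmax_distance",
    "objective_scores",
    "grid_search",
    "kfold_validate",
    "spearman_apen_vs_class",
]

GRID_M: NDArray[np.int_] = np.arange(1, 6)
GRID_R: NDArray[np.float64] = np.round(np.arange(1, 31) * 0.02, 2)


@dataclass
class ClassApEnDistribution:
    """Normalized ApEn values per fractionation class, with box statistics."""

    values: dict[str, NDArray[np.float64]]

    def __post_init__(self) -> None:
        for c, v in self.values.items():
            self.values[c] = np.asarray(v, dtype=np.float64)

    def stat(self, name: str) -> dict[str, float]:
        f = {
            "min": np.min,
            "max": np.max,
            "q1": lambda v: np.quantile(v, 0.25),
            "median": np.median,
            "q3": lambda v: np.quantile(v, 0.75),
        }[name]
        return {c: float(f(v)) for c, v in self.values.items() if len(v)}


def _check_classes(dist: ClassApEnDistribution) -> None:
    for c in CLASSES:
        if c not in dist.values or len(dist.values[c]) == 0:
            raise ValueError(f"class {c} is empty")


def interclass_percentile_distance(dist: ClassApEnDistribution) -> float:
    """Sum over adjacent class pairs of Q1(upper) - Q3(lower).

    Positive when the interquartile boxes of adjacent classes are disjoint
    and correctly ordered; invariant to a common shift of all classes.
    """
    _check_classes(dist)
    q1 = dist.stat("q1")
    q3 = dist.stat("q3")
    return float(sum(q1[CLASSES[k + 1]] - q3[CLASSES[k]] for k in range(3)))


def interclass_minmax_distance(dist: ClassApEnDistribution) -> float:
    """Sum over adjacent class pairs of min(upper) - max(lower).

    Positive iff adjacent classes have non-overlapping, correctly ordered
    ranges; widening any class's spread never increases it.
    """
    _check_classes(dist)
    lo = dist.stat("min")
    hi = dist.stat("max")
    return float(sum(lo[CLASSES[k + 1]] - hi[CLASSES[k]] for k in range(3)))


def _minmax_rescale(a: np.ndarray) -> np.ndarray:
    lo, hi = np.min(a), np.max(a)
    if hi == lo:
        return np.full_like(a, 0.5)
    return (a - lo) / (hi - lo)


def objective_scores(dp: np.ndarray, dmm: np.ndarray) -> np.ndarray:
    """Equal-weight objective over the grid: F = 0.5 (D_P~ + D_MM~).

    Each criterion is min-max rescaled to [0, 1] across the grid before
    weighting, so the ranking is invariant to any positive affine
    transformation applied to both criteria jointly.
    """
    dp = np.asarray(dp, dtype=np.float64)
    dmm = np.asarray(dmm, dtype=np.float64)
    if not (np.all(np.isfinite(dp)) and np.all(np.isfinite(dmm))):
        raise ValueError("non-finite criterion values")
    return 0.5 * (_minmax_rescale(dp) + _minmax_rescale(dmm))


@dataclass
class GridSearchResult:
    """Scores over the full (m, r) grid and the selected optimum."""

    m_values: NDArray[np.int_]
    r_values: NDArray[np.float64]
    dp: NDArray[np.float64]  # (n_m, n_r)
    dmm: NDArray[np.float64]
    f: NDArray[np.float64]
    best_m: int
    best_r: float
    window: int
    apen_values: NDArray[np.float64] = field(repr=False, default=None)  # (n_sig, n_m, n_r), normalized
    labels: list[str] = field(repr=False, default_factory=list)

    def distribution(self, m: int, r: float) -> ClassApEnDistribution:
        i = int(np.where(self.m_values == m)[0][0])
        j = int(np.argmin(np.abs(self.r_values - r)))
        vals = {c: [] for c in CLASSES}
        for lab, v in zip(self.labels, self.apen_values[:, i, j]):
            vals[lab].append(v)
        return ClassApEnDistribution({c: np.asarray(v) for c, v in vals.items()})


def _grid_apen_matrix(
    ds: FractionationDataset, window: int
) -> tuple[np.ndarray, list[str]]:
    """Raw ApEn of the first ``window`` samples of each usable signal, for
    every grid combination; shape (n_signals, n_m, n_r)."""
    rows = []
    labels = []
    for it in ds.items:
        if len(it.samples) < window:
            warnings.warn(
                f"signal of length {len(it.samples)} < window {window}; excluded",
                stacklevel=2,
            )
            continue
        rows.append(apen_profile(it.samples[:window], GRID_M, GRID_R))
        labels.append(it.label)
    if not rows:
        raise ValueError("no signal is long enough for the requested window")
    missing = [c for c in CLASSES if c not in labels]
    if missing:
        raise ValueError(f"classes emptied by length exclusions: {missing}")
    return np.stack(rows), labels


def grid_search(ds: FractionationDataset, window: int = 1000) -> GridSearchResult:
    """Exhaustive (m, r) grid search maximizing the class-separation
    objective F on the first ``window`` samples of each signal."""
    raw, labels = _grid_apen_matrix(ds, window)
    # min-max normalize ApEn to [0, 1] per (m, r) combination
    lo = raw.min(axis=0, keepdims=True)
    hi = raw.max(axis=0, keepdims=True)
    span = np.where(hi > lo, hi - lo, 1.0)
    norm = (raw - lo) / span
    lab_arr = np.asarray(labels)
    n_m, n_r = len(GRID_M), len(GRID_R)
    dp = np.empty((n_m, n_r))
    dmm = np.empty((n_m, n_r))
    by_class = {c: norm[lab_arr == c] for c in CLASSES}  # (n_c, n_m, n_r)
    q1 = {c: np.quantile(v, 0.25, axis=0) for c, v in by_class.items()}
    q3 = {c: np.quantile(v, 0.75, axis=0) for c, v in by_class.items()}
    lo_c = {c: v.min(axis=0) for c, v in by_class.items()}
    hi_c = {c: v.max(axis=0) for c, v in by_class.items()}
    dp = sum(q1[CLASSES[k + 1]] - q3[CLASSES[k]] for k in range(3))
    dmm = sum(lo_c[CLASSES[k + 1]] - hi_c[CLASSES[k]] for k in range(3))
    f = objective_scores(dp, dmm)
    # argmax with ties toward smaller m then smaller r (row-major scan order)
    best_flat = int(np.argmax(f))
    bi, bj = np.unravel_index(best_flat, f.shape)
    return GridSearchResult(
        m_values=GRID_M.copy(),
        r_values=GRID_R.copy(),
        dp=np.asarray(dp),
        dmm=np.asarray(dmm),
        f=f,
        best_m=int(GRID_M[bi]),
        best_r=float(GRID_R[bj]),
        window=window,
        apen_values=norm,
        labels=labels,
    )


@dataclass
class KFoldResult:
    fold_best: list[tuple[int, float]]
    full_best: tuple[int, float]
    agreement_rate: float
    modal_best: tuple[int, float]


def kfold_validate(
    ds: FractionationDataset,
    window: int = 1000,
    k: int = 10,
    seed: int = 0,
) -> KFoldResult:
    """Stratified K-fold validation of the grid-search optimum.

    Each fold's training partition is re-searched; the agreement rate is
    the fraction of folds whose optimum equals the full-data optimum.
    Deterministic per seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = ds.class_counts()
    small = [c for c, n in counts.items() if n < k]
    if small:
        raise ValueError(f"classes with fewer than k={k} members: {small}")
    labels = [it.label for it in ds.items]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    full = grid_search(ds, window)
    fold_best: list[tuple[int, float]] = []
    for train_idx, _ in skf.split(np.zeros(len(ds)), labels):
        sub = FractionationDataset(
            items=[ds.items[i] for i in train_idx],
            fs=ds.fs,
            provenance=ds.provenance + " (fold)",
        )
        res = grid_search(sub, window)
        fold_best.append((res.best_m, res.best_r))
    agree = np.mean(
        [b == (full.best_m, full.best_r) for b in fold_best]
    )
    modal = max(set(fold_best), key=fold_best.count)
    return KFoldResult(
        fold_best=fold_best,
        full_best=(full.best_m, full.best_r),
        agreement_rate=float(agree),
        modal_best=modal,
    )


def spearman_apen_vs_class(
    ds: FractionationDataset,
    m: int = 3,
    r_frac: float = 0.38,
    window: int = 1000,
) -> float:
    """Spearman rank correlation between per-signal ApEn (first ``window``
    samples) and the fractionation class index 0-3 (midrank ties)."""
    from rotormap.entropy import apen

    vals, cls = [], []
    for it in ds.items:
        if len(it.samples) >= window:
            vals.append(apen(it.samples[:window], m, r_frac))
            cls.append(CLASSES.index(it.label))
    if len(set(cls)) < 2:
        raise ValueError("need at least two populated classes")
    if np.ptp(vals) == 0:
        raise ValueError("zero variance in ApEn values")
    return float(spearmanr(vals, cls).statistic)
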