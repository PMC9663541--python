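"""Non-parametric slope check: per-voxel orthogonal (total least squares) regression.

For each voxel, responses at high contrast (y) are paired with responses at
low contrast (x) matched on (run, orientation).  Multiplicative tuning
modulation predicts a line of slope > 1 through the paired points; additive
modulation predicts slope exactly 1, regardless of the shape of the weight
distribution or the neural tuning functions.  Because both x and y carry
noise, an ordinary least-squares slope is attenuated toward zero; the total
least squares (orthogonal) slope

    g = [-(Sxx - Syy) + sqrt((Sxx - Syy)^2 + 4*Sxy^2)] / (2*Sxy)

minimizes squared perpendicular distances and is free of that attenuation.
Weakly tuned voxels yield near-isotropic point clouds whose slope can be
arbitrarily large, so results are reported as the slope *angle* in degrees
on [0, 180), where 45 deg corresponds to slope 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .util import order_contrast_labels

__all__ = [
    "SlopePairs",
    "SlopeFit",
    "OrthogonalRegression",
    "build_pairs",
    "orthogonal_slope",
    "per_voxel_angles",
    "slope_to_angle",
]

_EPS = 1e-300


def slope_to_angle(slope: float) -> float:
    """Map a slope (possibly +/-inf) to an angle in degrees on [0, 180)."""
    if math.isinf(slope):
        return 90.0
    return math.degrees(math.atan(slope)) % 180.0


@dataclass(frozen=True)
class SlopePairs:
    """Matched (low-contrast x, high-contrast y) responses for one voxel."""

    x: np.ndarray
    y: np.ndarray
    voxel: object = None
    n_dropped: int = 0

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be matched 1-D arrays")

    @property
    def n(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class SlopeFit:
    """TLS fit summary: sums of squares/cross-products, slope and its angle."""

    sxx: float
    syy: float
    sxy: float
    slope: float
    angle_deg: Optional[float]
    degenerate: bool = False
    voxel: object = None
    n: int = 0


def orthogonal_slope(pairs: SlopePairs) -> SlopeFit:
    """Total least squares slope of y on x with principal-axis tie-breaks.

    When Sxy == 0 the TLS criterion is solved by the principal axis of the
    covariance: slope 0 if Sxx > Syy, vertical (angle 90) if Syy > Sxx, and a
    degenerate flag when the cloud is isotropic (Sxx == Syy) or has no
    variance at all.
    """
    if pairs.n < 2:
        return SlopeFit(np.nan, np.nan, np.nan, np.nan, None, True,
                        pairs.voxel, pairs.n)
    x, y = pairs.x, pairs.y
    sxx = float(np.sum((x - x.mean()) ** 2))
    syy = float(np.sum((y - y.mean()) ** 2))
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    if sxx + syy == 0.0:
        return SlopeFit(sxx, syy, sxy, np.nan, None, True, pairs.voxel, pairs.n)
    if sxy == 0.0:
        if sxx > syy:
            return SlopeFit(sxx, syy, sxy, 0.0, 0.0, False, pairs.voxel, pairs.n)
        if syy > sxx:
            return SlopeFit(sxx, syy, sxy, math.inf, 90.0, False,
                            pairs.voxel, pairs.n)
        return SlopeFit(sxx, syy, sxy, np.nan, None, True, pairs.voxel, pairs.n)
    disc = math.sqrt((sxx - syy) ** 2 + 4.0 * sxy ** 2)
    slope = (-(sxx - syy) + disc) / (2.0 * sxy)
    return SlopeFit(sxx, syy, sxy, slope, slope_to_angle(slope), False,
                    pairs.voxel, pairs.n)


class OrthogonalRegression(BaseEstimator):
    """Scikit-learn style estimator for the TLS slope of y on x.

    After ``fit(X, y)`` (X a 1-D array or single-column matrix) the fitted
    attributes ``slope_``, ``angle_deg_``, ``sxx_``, ``syy_``, ``sxy_`` and
    ``degenerate_`` are available; ``predict`` evaluates the fitted line
    (through the centroid).
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("OrthogonalRegression is bivariate: X must have 1 column")
            X = X[:, 0]
        fit = orthogonal_slope(SlopePairs(X, np.asarray(y, dtype=float)))
        self.sxx_, self.syy_, self.sxy_ = fit.sxx, fit.syy, fit.sxy
        self.slope_ = fit.slope
        self.angle_deg_ = fit.angle_deg
        self.degenerate_ = fit.degenerate
        self.x_mean_ = float(np.mean(X))
        self.y_mean_ = float(np.mean(y))
        self.n_ = fit.n
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        if self.degenerate_ or math.isinf(self.slope_):
            raise ValueError("cannot predict from a degenerate or vertical fit")
        return self.y_mean_ + self.slope_ * (X - self.x_mean_)


def build_pairs(data: pd.DataFrame, voxel, baseline_label=None,
                participant=None) -> SlopePairs:
    """Pair a voxel's low/high-contrast responses matched on (run, orientation).

    Repeats within a (run, orientation, contrast) cell are averaged before
    pairing; cells present in only one contrast condition are dropped (their
    count is recorded on the returned object).  ``baseline_label`` names the
    low-contrast condition; by default the first contrast label in sorted
    order is used.
    """
    sub = data[data["voxel"] == voxel]
    if participant is not None:
        sub = sub[sub["participant"] == participant]
    if sub["contrast"].nunique() < 2:
        raise ValueError(f"voxel {voxel!r} lacks both contrast conditions")
    baseline_label, modulated_label = order_contrast_labels(
        sub["contrast"].unique(), baseline_label)
    cell = (
        sub.groupby(["run", "orientation_deg", "contrast"], sort=True, observed=True)
        ["response"]
        .mean()
        .unstack("contrast")
    )
    matched = cell.dropna()
    n_dropped = len(cell) - len(matched)
    if matched.empty:
        raise ValueError(f"voxel {voxel!r} has no matched (run, orientation) pairs")
    return SlopePairs(
        matched[baseline_label].to_numpy(),
        matched[modulated_label].to_numpy(),
        voxel=voxel,
        n_dropped=n_dropped,
    )


def per_voxel_angles(data: pd.DataFrame, baseline_label=None,
                     n_boot: int = 10_000, seed: int = 0,
                     ci_level: float = 0.95):
    """TLS fits for every voxel plus a median-angle summary with bootstrap CI.

    Returns ``(fits, summary)`` where ``fits`` is a DataFrame (one row per
    voxel: n_pairs, sums, slope, angle_deg, degenerate) and ``summary`` a dict
    with the median angle across non-degenerate voxels, a percentile
    bootstrap CI for that median, and the number of degenerate voxels
    excluded.
    """
    rows = []
    for (participant, voxel), _ in data.groupby(["participant", "voxel"], sort=True):
        try:
            pairs = build_pairs(data, voxel, baseline_label, participant=participant)
            fit = orthogonal_slope(pairs)
        except ValueError:
            fit = SlopeFit(np.nan, np.nan, np.nan, np.nan, None, True, voxel, 0)
        rows.append(
            dict(participant=participant, voxel=voxel, n_pairs=fit.n,
                 sxx=fit.sxx, syy=fit.syy, sxy=fit.sxy, slope=fit.slope,
                 angle_deg=fit.angle_deg if fit.angle_deg is not None else np.nan,
                 degenerate=fit.degenerate)
        )
    fits = pd.DataFrame(rows)
    angles = fits.loc[~fits["degenerate"], "angle_deg"].to_numpy()
    n_degenerate = int(fits["degenerate"].sum())
    if angles.size == 0:
        raise ValueError("all voxels degenerate; no angle summary possible")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, angles.size, size=(n_boot, angles.size))
    boot_medians = np.median(angles[idx], axis=1)
    lo, hi = np.quantile(boot_medians, [(1 - ci_level) / 2, 1 - (1 - ci_level) / 2])
    summary = {
        "median_angle_deg": float(np.median(angles)),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "ci_level": ci_level,
        "n_voxels": int(angles.size),
        "n_degenerate_excluded": n_degenerate,
    }
    return fits, summary
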