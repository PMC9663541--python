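"""Self-organizing (Kohonen) simulation of cortical orientation-preference maps.

A square grid of "neurons" starts with random orientation preferences.  On
each iteration a random stimulus orientation is presented, the neuron whose
preference is circularly closest wins, and every neuron's preference moves
toward the stimulus by an amount that decays with its grid distance d_j from
the winner under a Gaussian kernel:

    w_{j,i+1} = w_{j,i} + [psi(d_j, sigma_i) / psi(0, sigma_i)] * delta_i

where psi(x, sigma) is the Normal(0, sigma) density, delta_i is the signed
circular difference between stimulus and preference (period 180 deg), grid
distance is Euclidean with a city-block spacing of 0.03 between adjacent
neurons, and the kernel width shrinks linearly,
sigma_i = sigma_scale * ((n_iter - i + 1) / n_iter).

The resulting map supplies per-voxel weight distributions: tallies of
preferred orientation that are mostly flat but can carry a single mode,
summarized by a maximum-likelihood von Mises fit and compared against a
Monte-Carlo band for a perfectly flat distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e
from sklearn.base import BaseEstimator

from .tuning import CircularNormal

__all__ = [
    "KohonenConfig",
    "KohonenOrientationMap",
    "simulate_map",
    "local_circular_dispersion",
    "WeightDistributionSummary",
    "extract_weight_distribution",
    "flat_distribution_band",
    "vonmises_mle",
]

KAPPA_CAP = 500.0


@dataclass(frozen=True)
class KohonenConfig:
    """Simulation constants; defaults reproduce the study's map settings."""

    grid_size: int = 67
    iterations: int = 20_000
    neighbor_spacing: float = 0.03
    sigma_scale: float = 0.06
    seed: Optional[int] = None

    def __post_init__(self):
        if (self.grid_size < 1 or self.iterations < 1
                or self.neighbor_spacing <= 0 or self.sigma_scale <= 0):
            raise ValueError("all Kohonen configuration values must be positive")

    def sigma_at(self, i: int) -> float:
        """Kernel width on (1-based) iteration i."""
        return self.sigma_scale * ((self.iterations - i + 1) / self.iterations)


def _signed_orientation_diff(a, b):
    """Signed minimal circular difference a - b on the 180-deg orientation circle,
    in (-90, +90]."""
    d = np.mod(np.asarray(a, dtype=float) - b, 180.0)
    return np.where(d > 90.0, d - 180.0, d)


def simulate_map(cfg: KohonenConfig = KohonenConfig()) -> np.ndarray:
    """Run the self-organization and return the (grid_size, grid_size) map of
    preferred orientations in degrees on [0, 180)."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.grid_size
    prefs = rng.uniform(0.0, 180.0, size=n * n)
    rows, cols = np.divmod(np.arange(n * n), n)
    xs = cols * cfg.neighbor_spacing
    ys = rows * cfg.neighbor_spacing
    for i in range(1, cfg.iterations + 1):
        stim = rng.uniform(0.0, 180.0)
        delta = _signed_orientation_diff(stim, prefs)
        winner = int(np.argmin(np.abs(delta)))  # ties -> lowest index
        sigma = cfg.sigma_at(i)
        d2 = (xs - xs[winner]) ** 2 + (ys - ys[winner]) ** 2
        # psi(d, sigma) / psi(0, sigma) = exp(-d^2 / (2 sigma^2))
        prefs = np.mod(prefs + np.exp(-d2 / (2.0 * sigma * sigma)) * delta, 180.0)
    return prefs.reshape(n, n)


def local_circular_dispersion(orientation_map: np.ndarray) -> float:
    """Mean circular dispersion (1 - resultant length on doubled angles) over
    horizontally and vertically adjacent neuron pairs; lower = smoother map."""
    m = np.asarray(orientation_map, dtype=float)
    th = np.deg2rad(m) * 2.0
    disps = []
    for a, b in (((th[:, :-1], th[:, 1:])), ((th[:-1, :], th[1:, :]))):
        r = np.hypot(np.cos(a) + np.cos(b), np.sin(a) + np.sin(b)) / 2.0
        disps.append(1.0 - r)
    return float(np.mean(np.concatenate([d.ravel() for d in disps])))


class KohonenOrientationMap(BaseEstimator):
    """Estimator wrapper around the map simulation.

    ``fit()`` runs the self-organization; the fitted attribute ``map_``
    holds preferred orientations in degrees, and ``dispersion_`` the final
    local circular dispersion.
    """

    def __init__(self, grid_size: int = 67, iterations: int = 20_000,
                 neighbor_spacing: float = 0.03, sigma_scale: float = 0.06,
                 random_state: Optional[int] = None):
        self.grid_size = grid_size
        self.iterations = iterations
        self.neighbor_spacing = neighbor_spacing
        self.sigma_scale = sigma_scale
        self.random_state = random_state

    def fit(self, X=None, y=None):
        cfg = KohonenConfig(self.grid_size, self.iterations,
                            self.neighbor_spacing, self.sigma_scale,
                            self.random_state)
        self.map_ = simulate_map(cfg)
        self.dispersion_ = local_circular_dispersion(self.map_)
        return self


def vonmises_mle(angles_doubled: np.ndarray):
    """Closed-form/1-D-root MLE of a von Mises (phi, kappa) on [0, 2*pi).

    Returns (phi_hat, kappa_hat, capped) where ``capped`` flags a resultant
    length so close to 1 that kappa was clipped at ``KAPPA_CAP``.
    """
    th = np.asarray(angles_doubled, dtype=float)
    if th.size == 0:
        raise ValueError("empty sample")
    c, s = np.cos(th).mean(), np.sin(th).mean()
    rbar = float(np.hypot(c, s))
    phi = float(np.mod(np.arctan2(s, c), 2.0 * np.pi))
    if rbar < 1e-12:
        return phi, 0.0, False

    def a1(k):
        return i1e(k) / i0e(k)

    if a1(KAPPA_CAP) <= rbar:
        return phi, KAPPA_CAP, True
    kappa = float(brentq(lambda k: a1(k) - rbar, 0.0, KAPPA_CAP))
    return phi, kappa, False


@dataclass
class WeightDistributionSummary:
    """Histogram of preferences, its MLE von Mises fit, and the flat band."""

    bin_edges_deg: np.ndarray
    counts: np.ndarray
    mle: CircularNormal
    kappa_capped: bool
    band_low: np.ndarray
    band_high: np.ndarray
    band_level: float

    def to_dict(self) -> dict:
        return {
            "bin_edges_deg": self.bin_edges_deg.tolist(),
            "counts": self.counts.tolist(),
            "mle_phi": self.mle.phi,
            "mle_kappa": self.mle.kappa,
            "kappa_capped": self.kappa_capped,
            "band_low": self.band_low.tolist(),
            "band_high": self.band_high.tolist(),
            "band_level": self.band_level,
        }


def flat_distribution_band(n_neurons: int, n_bins: int, level: float = 0.99,
                           seed: Optional[int] = None, n_sim: int = 20_000):
    """Monte-Carlo per-bin count band under a perfectly flat preference
    distribution: multinomial(n_neurons, uniform) quantiles at
    (1-level)/2 and 1-(1-level)/2.  Returns (low, high) integer arrays."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if n_neurons < n_bins:
        raise ValueError("need n_neurons >= n_bins")
    rng = np.random.default_rng(seed)
    sims = rng.multinomial(n_neurons, np.full(n_bins, 1.0 / n_bins),
                           size=n_sim)
    lo = np.quantile(sims, (1.0 - level) / 2.0, axis=0)
    hi = np.quantile(sims, 1.0 - (1.0 - level) / 2.0, axis=0)
    return lo, hi


def extract_weight_distribution(orientation_map: np.ndarray, n_bins: int = 18,
                                band_level: float = 0.99,
                                seed: Optional[int] = None
                                ) -> WeightDistributionSummary:
    """Tally preferences into equal-width circular bins, fit a von Mises by
    MLE (on doubled angles) and attach the flat-distribution band."""
    m = np.asarray(orientation_map, dtype=float).ravel()
    if m.size == 0:
        raise ValueError("empty orientation map")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges = np.linspace(0.0, 180.0, n_bins + 1)
    counts, _ = np.histogram(np.mod(m, 180.0), bins=edges)
    phi, kappa, capped = vonmises_mle(np.deg2rad(m) * 2.0)
    lo, hi = flat_distribution_band(m.size, n_bins, level=band_level, seed=seed)
    return WeightDistributionSummary(
        bin_edges_deg=edges, counts=counts,
        mle=CircularNormal(phi, kappa), kappa_capped=capped,
        band_low=lo, band_high=hi, band_level=band_level,
    )
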