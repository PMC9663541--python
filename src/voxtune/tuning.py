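"""Circular-Normal tuning functions and the neuron-to-voxel aggregation link.

Orientation is a circular feature with period 180 degrees.  User-facing
orientations live in degrees on [0, 180); all circular computation happens on
the *doubled-angle* circle, where orientations are doubled and expressed in
radians on [0, 2*pi).  On that circle the circular Normal (von Mises) density

    f(r | phi, kappa) = exp(kappa * cos(r - phi)) / (2*pi * I0(kappa))

plays two roles: as a neural tuning-curve shape and as the weight
distribution describing how strongly neurons of each preferred orientation
contribute to a voxel's signal.

A single neuron's mean activity is an affine function of the density,

    NTF(r | kappa2, gamma, alpha) = alpha + gamma * f(r | 0, kappa2),

with baseline ``alpha`` and responsiveness ``gamma``.  Aggregating a
population of such neurons under a circular-Normal weight distribution gives
a voxel tuning function of the same affine-von-Mises form,

    VTF(r | kappa_v, gamma_v, alpha_v, phi_v) = alpha_v + gamma_v * f(r | phi_v, kappa_v),

whose concentration ``kappa_v`` blends the neural and weight concentrations
and is treated as a free parameter.  A stimulus manipulation (e.g. contrast)
may modulate the voxel function multiplicatively (gain ``g_v`` on the tuned
component) or additively (shift ``a_v`` applied uniformly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional

import numpy as np
from scipy.special import i0e

__all__ = [
    "CircularNormal",
    "NeuralTuningParams",
    "VoxelTuningParams",
    "NeuralPopulation",
    "to_doubled_angle",
    "from_doubled_angle",
    "circular_normal_density",
    "ntf_response",
    "vtf_response",
    "population_vtf",
]

Condition = Literal["baseline", "modulated"]
Family = Literal["multiplicative", "additive"]


def to_doubled_angle(orientation_deg):
    """Map orientation(s) in degrees on [0, 180) to doubled-angle radians on [0, 2*pi).

    Values outside [0, 180) are reduced modulo 180 with a warning; non-finite
    input raises ``ValueError``.
    """
    arr = np.asarray(orientation_deg, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("orientation must be finite")
    if np.any((arr < 0.0) | (arr >= 180.0)):
        warnings.warn(
            "orientation outside [0, 180) reduced modulo 180", stacklevel=2
        )
        arr = np.mod(arr, 180.0)
    out = 2.0 * np.deg2rad(arr)
    return out if out.ndim else float(out)


def from_doubled_angle(r):
    """Inverse of :func:`to_doubled_angle`: doubled radians back to degrees on [0, 180)."""
    arr = np.mod(np.asarray(r, dtype=float), 2.0 * np.pi)
    out = np.rad2deg(arr) / 2.0
    # guard against 180.0 appearing through rounding of values just below 2*pi
    out = np.where(out >= 180.0, out - 180.0, out)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CircularNormal:
    """Location/concentration pair of a von Mises density on the doubled circle.

    Parameters
    ----------
    phi : float
        Peak location, doubled-angle radians; stored wrapped to [0, 2*pi).
    kappa : float
        Concentration, >= 0.  ``kappa == 0`` is the uniform density 1/(2*pi).
    """

    phi: float
    kappa: float

    def __post_init__(self):
        if not np.isfinite(self.phi) or not np.isfinite(self.kappa):
            raise ValueError("phi and kappa must be finite")
        if self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        object.__setattr__(self, "phi", float(np.mod(self.phi, 2.0 * np.pi)))

    def pdf(self, r):
        return circular_normal_density(r, self)


def circular_normal_density(r, cn: CircularNormal):
    """Von Mises density on the doubled-angle circle, in 1/rad.

    Uses the exponentially scaled Bessel function for numerical stability at
    large concentration:  exp(kappa*(cos(r-phi) - 1)) / (2*pi*i0e(kappa)).
    """
    if not isinstance(cn, CircularNormal):
        cn = CircularNormal(*cn)
    r = np.asarray(r, dtype=float)
    if cn.kappa == 0.0:
        out = np.full_like(r, 1.0 / (2.0 * np.pi))
        return out if out.ndim else float(out)
    out = np.exp(cn.kappa * (np.cos(r - cn.phi) - 1.0)) / (
        2.0 * np.pi * i0e(cn.kappa)
    )
    return out if out.ndim else float(out)


def _vm(r, phi, kappa):
    """Vectorized von Mises density without dataclass overhead (kappa >= 0)."""
    r = np.asarray(r, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    return np.exp(kappa * (np.cos(r - phi) - 1.0)) / (2.0 * np.pi * i0e(kappa))


@dataclass(frozen=True)
class NeuralTuningParams:
    """Shape of a single neural tuning curve: baseline, responsiveness, concentration."""

    alpha: float = 0.0
    gamma: float = 1.0
    kappa2: float = 2.0

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.kappa2 < 0:
            raise ValueError(f"kappa2 must be >= 0, got {self.kappa2}")


def ntf_response(r, p: NeuralTuningParams):
    """Neural tuning function: alpha + gamma * f(r | 0, kappa2)."""
    return p.alpha + p.gamma * _vm(r, 0.0, p.kappa2)


@dataclass(frozen=True)
class VoxelTuningParams:
    """Baseline voxel tuning plus exactly one modulation parameter and a noise scale.

    ``gain`` (g_v > 0) rescales the tuned component in the modulated condition
    (multiplicative family); ``shift`` (a_v) offsets the whole curve (additive
    family).  Exactly one of the two must be set.
    """

    alpha_v: float
    gamma_v: float
    kappa_v: float
    phi_v: float
    sigma_v: float
    gain: Optional[float] = None
    shift: Optional[float] = None

    def __post_init__(self):
        if self.gamma_v < 0:
            raise ValueError("gamma_v must be >= 0")
        if self.kappa_v < 0:
            raise ValueError("kappa_v must be >= 0")
        if self.sigma_v <= 0:
            raise ValueError("sigma_v must be > 0")
        if (self.gain is None) == (self.shift is None):
            raise ValueError("exactly one of gain / shift must be set")
        if self.gain is not None and self.gain <= 0:
            raise ValueError("gain must be > 0")
        object.__setattr__(self, "phi_v", float(np.mod(self.phi_v, 2.0 * np.pi)))

    @property
    def family(self) -> Family:
        return "multiplicative" if self.gain is not None else "additive"


def vtf_response(r, v: VoxelTuningParams, condition: Condition = "baseline",
                 family: Optional[Family] = None):
    """Voxel tuning function under the given condition and model family.

    baseline:   alpha_v + gamma_v * f(r | phi_v, kappa_v)
    modulated:  multiplicative  alpha_v + g_v * gamma_v * f(...)
                additive        a_v + alpha_v + gamma_v * f(...)
    """
    if family is None:
        family = v.family
    if condition not in ("baseline", "modulated"):
        raise ValueError(f"unknown condition {condition!r}")
    base_f = _vm(r, v.phi_v, v.kappa_v)
    if condition == "baseline":
        return v.alpha_v + v.gamma_v * base_f
    if family == "multiplicative":
        if v.gain is None:
            raise ValueError("multiplicative family requires a gain parameter")
        return v.alpha_v + v.gain * v.gamma_v * base_f
    if family == "additive":
        if v.shift is None:
            raise ValueError("additive family requires a shift parameter")
        return v.shift + v.alpha_v + v.gamma_v * base_f
    raise ValueError(f"unknown family {family!r}")


@dataclass
class NeuralPopulation:
    """Discrete stand-in for the continuous neuron-to-voxel convolution.

    A grid of preferred orientations on the doubled circle with nonnegative
    weights summing to one, and either shared parametric tuning ``params`` or
    an arbitrary tuning-curve callable ``ntf`` (relative orientation ->
    activity) with an explicit ``baseline`` used for multiplicative
    modulation of non-parametric shapes.
    """

    preferred: np.ndarray
    weights: np.ndarray
    params: Optional[NeuralTuningParams] = None
    ntf: Optional[Callable[[np.ndarray], np.ndarray]] = None
    baseline: float = 0.0

    def __post_init__(self):
        self.preferred = np.asarray(self.preferred, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.preferred.shape != self.weights.shape:
            raise ValueError("preferred and weights must have the same shape")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1 (tolerance 1e-12)")
        if (self.params is None) == (self.ntf is None):
            raise ValueError("provide exactly one of params / ntf")
        if self.params is not None:
            self.baseline = self.params.alpha

    @classmethod
    def from_weight_distribution(cls, cn: CircularNormal, params: NeuralTuningParams,
                                 n_grid: int = 180) -> "NeuralPopulation":
        """Population whose weights discretize a circular-Normal weight distribution."""
        grid = np.linspace(0.0, 2.0 * np.pi, n_grid, endpoint=False)
        w = circular_normal_density(grid, cn)
        w = np.asarray(w) / np.sum(w)
        return cls(preferred=grid, weights=w, params=params)


def population_vtf(pop: NeuralPopulation, r, neural_modulation=None):
    """Voxel response: weight-distribution average of neural tuning functions.

    ``neural_modulation`` is ``None``, ``("gain", g)`` or ``("shift", a)``;
    the modulation is applied to every neuron *before* aggregation (gain
    rescales activity around the neural baseline, shift offsets it), so the
    voxel-level consequences of neural-level modulation emerge from the sum.
    """
    scalar_in = np.ndim(r) == 0
    r = np.atleast_1d(np.asarray(r, dtype=float))
    rel = r[:, None] - pop.preferred[None, :]
    if pop.params is not None:
        act = ntf_response(rel, pop.params)
    else:
        act = np.asarray(pop.ntf(rel), dtype=float)
    if neural_modulation is not None:
        kind, value = neural_modulation
        if kind == "gain":
            act = pop.baseline + value * (act - pop.baseline)
        elif kind == "shift":
            act = act + value
        else:
            raise ValueError(f"unknown neural modulation {kind!r}")
    out = act @ pop.weights
    return float(out[0]) if scalar_in else out
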