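"""Voxel retention based on population receptive field (pRF) geometry.

A voxel's pRF is an isotropic 2-D Gaussian in the visual field (center in
degrees of visual angle, size = SD).  To avoid stimulus-vignetting artifacts
near the edges of an annular grating, a voxel is retained only if the circle
of radius two SDs around its pRF center lies entirely inside the annulus in
every session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = ["PrfParams", "AnnulusStimulus", "retain_voxel", "filter_table"]


@dataclass(frozen=True)
class PrfParams:
    """pRF center (x, y) and Gaussian SD ``sigma``, all in degrees of visual angle."""

    x: float
    y: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    @property
    def eccentricity(self) -> float:
        return math.hypot(self.x, self.y)


@dataclass(frozen=True)
class AnnulusStimulus:
    """Annular grating aperture; defaults are the study's 1.2-7 deg annulus."""

    inner: float = 1.2
    outer: float = 7.0

    def __post_init__(self):
        if not 0.0 <= self.inner < self.outer:
            raise ValueError("require 0 <= inner < outer")


def retain_voxel(prf_sets: Iterable[PrfParams],
                 stim: AnnulusStimulus = AnnulusStimulus()) -> bool:
    """True iff the 2-SD pRF circle is contained by the annulus in every session.

    Containment is closed (tangency retains): e - 2*sigma >= inner and
    e + 2*sigma <= outer, with e the pRF center eccentricity.
    """
    prf_sets = list(prf_sets)
    if not prf_sets:
        raise ValueError("at least one session of pRF parameters is required")
    for prf in prf_sets:
        e = prf.eccentricity
        if e - 2.0 * prf.sigma < stim.inner or e + 2.0 * prf.sigma > stim.outer:
            return False
    return True


def filter_table(prf_table: pd.DataFrame,
                 stim: AnnulusStimulus = AnnulusStimulus()) -> pd.DataFrame:
    """Apply the retention rule to a table (voxel, session, x_deg, y_deg, sigma_deg).

    Returns one row per voxel with a boolean ``retained`` column (AND across
    that voxel's sessions).
    """
    required = {"voxel", "session", "x_deg", "y_deg", "sigma_deg"}
    missing = required - set(prf_table.columns)
    if missing:
        raise ValueError(f"pRF table missing columns: {sorted(missing)}")
    out = []
    for voxel, grp in prf_table.groupby("voxel", sort=True):
        sets = [PrfParams(r.x_deg, r.y_deg, r.sigma_deg)
                for r in grp.itertuples()]
        out.append({"voxel": voxel, "retained": retain_voxel(sets, stim)})
    return pd.DataFrame(out)
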