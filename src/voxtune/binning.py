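"""Cross-validated "binning" estimator of the average voxel tuning function.

The standard display of voxel tuning aligns every voxel to its preferred
orientation and averages across voxels.  The procedure here follows the
usual recipe: z-score each voxel's responses, estimate each voxel's
preferred orientation from all runs except one held-out run, express the
held-out run's responses as a function of signed circular distance from
that preference, repeat holding out each run, and finally average across
voxels with repeated-measures (within-voxel) confidence intervals.

This estimator is faithful but can mislead: when most voxels are untuned,
a population whose tuned voxels undergo multiplicative gain still produces
an aligned high-minus-low difference curve that is nearly constant across
distances, i.e. it *looks* additive.  The per-voxel slope check does not
share this failure mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "zscore_per_voxel",
    "holdout_preferred_orientation",
    "bin_and_average",
    "AlignedTuning",
]


def zscore_per_voxel(data: pd.DataFrame) -> pd.DataFrame:
    """Z-score responses within each (participant, voxel) across all its rows.

    Voxels with zero variance are passed through unscaled with a warning.
    """
    out = data.copy()
    flagged = []

    def _z(s):
        sd = s.std(ddof=1)
        if not np.isfinite(sd) or sd == 0.0:
            flagged.append(s.name)
            return s
        return (s - s.mean()) / sd

    out["response"] = (
        out.groupby(["participant", "voxel"], sort=False)["response"]
        .transform(_z)
    )
    if flagged:
        warnings.warn(
            f"{len(flagged)} zero-variance voxel(s) passed through unscaled",
            stacklevel=2,
        )
    return out


def signed_circular_distance(orientation_deg, preferred_deg):
    """Signed orientation difference mapped to (-90, +90] degrees."""
    d = np.mod(np.asarray(orientation_deg, dtype=float) - preferred_deg, 180.0)
    return np.where(d > 90.0, d - 180.0, d)


def holdout_preferred_orientation(data: pd.DataFrame, voxel, held_out_run,
                                  participant=None) -> float:
    """Orientation with the largest mean response excluding the held-out run.

    The mean is taken across remaining runs, repeats and both contrast
    conditions; ties go to the lowest orientation value.
    """
    sub = data[data["voxel"] == voxel]
    if participant is not None:
        sub = sub[sub["participant"] == participant]
    if sub["run"].nunique() < 2:
        raise ValueError("need >= 2 runs to hold one out")
    rest = sub[sub["run"] != held_out_run]
    means = rest.groupby("orientation_deg", sort=True)["response"].mean()
    # idxmax on a sorted index returns the lowest orientation among ties
    return float(means.idxmax())


@dataclass
class AlignedTuning:
    """Aligned per-voxel responses plus the across-voxel summary table."""

    aligned: pd.DataFrame      # voxel-level rows: participant, voxel, run, contrast, distance_deg, response
    summary: pd.DataFrame      # distance_deg, contrast, mean, ci_low, ci_high
    n_excluded_voxels: int = 0


def _morey_ci(cell_matrix: np.ndarray, level: float = 0.95):
    """Repeated-measures CI half-widths per cell (within-unit centering with
    the small-sample correction sqrt(M/(M-1)) for M conditions)."""
    n_units, n_cells = cell_matrix.shape
    centered = (cell_matrix - cell_matrix.mean(axis=1, keepdims=True)
                + cell_matrix.mean())
    sem = centered.std(axis=0, ddof=1) / np.sqrt(n_units)
    correction = np.sqrt(n_cells / (n_cells - 1.0)) if n_cells > 1 else 1.0
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=n_units - 1)
    return sem * correction * tcrit


def bin_and_average(data: pd.DataFrame, ci_level: float = 0.95,
                    zscore: bool = True) -> AlignedTuning:
    """Hold-one-run-out alignment to preferred orientation, then across-voxel
    means with repeated-measures CIs per (distance, contrast).

    Voxels lacking both contrast conditions, and voxels whose orientation set
    differs from the modal set (e.g. a seven-orientation session), are
    excluded with a count.  Contrast and distance from preference are treated
    as within-voxel factors; participants are ignored in the summary.
    """
    if zscore:
        data = zscore_per_voxel(data)
    modal_oris = None
    ori_sets = data.groupby(["participant", "voxel"])["orientation_deg"].agg(
        lambda s: tuple(sorted(s.unique()))
    )
    modal_oris = ori_sets.mode().iloc[0]

    aligned_rows = []
    n_excluded = 0
    for (participant, voxel), sub in data.groupby(["participant", "voxel"],
                                                  sort=True):
        if sub["contrast"].nunique() < 2:
            n_excluded += 1
            continue
        if tuple(sorted(sub["orientation_deg"].unique())) != modal_oris:
            n_excluded += 1
            continue
        for run in sorted(sub["run"].unique()):
            pref = holdout_preferred_orientation(sub, voxel, run)
            held = sub[sub["run"] == run]
            aligned_rows.append(pd.DataFrame({
                "participant": participant,
                "voxel": voxel,
                "run": run,
                "contrast": held["contrast"].to_numpy(),
                "distance_deg": signed_circular_distance(
                    held["orientation_deg"].to_numpy(), pref),
                "response": held["response"].to_numpy(),
            }))
    if not aligned_rows:
        raise ValueError("no voxels usable for binning")
    aligned = pd.concat(aligned_rows, ignore_index=True)

    # per-voxel cell means (averaging over runs/repeats), then across voxels
    per_voxel = (
        aligned.groupby(["participant", "voxel", "distance_deg", "contrast"])
        ["response"].mean().rename("response").reset_index()
    )
    wide = per_voxel.pivot_table(
        index=["participant", "voxel"], columns=["distance_deg", "contrast"],
        values="response",
    )
    wide = wide.dropna()  # summary uses voxels with complete cells
    cells = wide.columns
    half = _morey_ci(wide.to_numpy(), level=ci_level)
    means = wide.to_numpy().mean(axis=0)
    summary = pd.DataFrame({
        "distance_deg": [c[0] for c in cells],
        "contrast": [c[1] for c in cells],
        "mean": means,
        "ci_low": means - half,
        "ci_high": means + half,
    }).sort_values(["distance_deg", "contrast"]).reset_index(drop=True)
    return AlignedTuning(aligned=aligned, summary=summary,
                         n_excluded_voxels=n_excluded)
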