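"""Synthetic voxel-response datasets with the study's structure.

Generates long-format tables — one row per (participant, voxel, run,
orientation, contrast, repeat) — emulating GLM beta weights in percent
signal change units.  Three entry points mirror the three ways generating
parameters arise:

* explicit :class:`~voxtune.tuning.VoxelTuningParams` (``simulate_dataset``),
* hierarchical prior draws (``draw_voxel_params``; data-uninformed model
  recovery),
* joint posterior draws from a fitted model (``simulate_from_posterior``;
  data-informed model recovery).

Noise is Normal per observation with a voxel-specific scale drawn
log-normally across voxels, reflecting that run-to-run variability differs
between voxels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .tuning import VoxelTuningParams, to_doubled_angle, vtf_response

__all__ = [
    "ExperimentDesign",
    "PriorSpec",
    "draw_voxel_params",
    "simulate_dataset",
    "simulate_from_posterior",
    "mixed_population_params",
    "write_dataset",
]

DATASET_COLUMNS = [
    "participant", "voxel", "run", "orientation_deg", "contrast", "repeat",
    "response",
]


def default_orientations(n: int = 8) -> tuple:
    """n equally spaced orientations on [0, 180)."""
    return tuple(np.arange(n) * (180.0 / n))


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial layout of a study: who was measured, how often, at what stimuli.

    Defaults follow the study structure: 18 runs, 8 orientations, two
    contrast conditions (baseline listed first), each combination presented
    twice per run.
    """

    participants: int = 1
    voxels_per_participant: int = 100
    runs: int = 18
    orientations_deg: tuple = field(default_factory=default_orientations)
    contrasts: tuple = ("low", "high")
    repeats_per_run: int = 2

    def __post_init__(self):
        if min(self.participants, self.voxels_per_participant, self.runs,
               self.repeats_per_run) < 1:
            raise ValueError("all design counts must be >= 1")
        if len(self.contrasts) != 2:
            raise ValueError("exactly two contrast conditions are required")
        oris = tuple(float(o) for o in self.orientations_deg)
        if len(set(np.mod(oris, 180.0))) != len(oris):
            raise ValueError("orientations must be distinct modulo 180")
        object.__setattr__(self, "orientations_deg", oris)

    @property
    def n_rows(self) -> int:
        return (self.participants * self.voxels_per_participant * self.runs
                * len(self.orientations_deg) * len(self.contrasts)
                * self.repeats_per_run)


# Hyperprior constants: each voxel-level parameter theta_v is drawn
# N(mu_theta, tau_theta) (on the log scale for positive parameters), with
# mu_theta ~ Normal(loc, scale) and tau_theta ~ HalfNormal(tau_scale).
@dataclass(frozen=True)
class HyperPrior:
    loc: float
    scale: float
    tau_scale: float

    def __post_init__(self):
        if self.scale <= 0 or self.tau_scale <= 0:
            raise ValueError("prior scales must be > 0")


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative hierarchical priors for every voxel-level parameter.

    Positive parameters (gamma_v, kappa_v, sigma_v, g_v) are normal on the
    log scale; alpha_v and a_v are normal; phi_v is uniform on the circle
    (no pooling).  Units are percent signal change for alpha/gamma/sigma/
    shift; gain and kappa are dimensionless.
    """

    alpha: HyperPrior = HyperPrior(0.5, 0.5, 0.3)
    log_gamma: HyperPrior = HyperPrior(np.log(0.5), 0.5, 0.4)
    log_kappa: HyperPrior = HyperPrior(np.log(0.5), 0.7, 0.5)
    log_sigma: HyperPrior = HyperPrior(np.log(0.4), 0.3, 0.25)
    log_gain: HyperPrior = HyperPrior(0.0, 0.3, 0.2)
    shift: HyperPrior = HyperPrior(0.0, 0.3, 0.2)

    @classmethod
    def default(cls) -> "PriorSpec":
        """Study-emulating regime: mostly weakly tuned voxels, moderate noise."""
        return cls()

    @classmethod
    def recovery_default(cls) -> "PriorSpec":
        """Regime for data-uninformed model recovery: clearly tuned voxels
        and modulation well away from the null, so that each generating
        family leaves a distinctive signature."""
        return cls(
            alpha=HyperPrior(1.0, 0.3, 0.25),
            log_gamma=HyperPrior(0.0, 0.3, 0.25),
            log_kappa=HyperPrior(np.log(2.0), 0.3, 0.3),
            log_sigma=HyperPrior(np.log(0.3), 0.2, 0.2),
            log_gain=HyperPrior(np.log(1.5), 0.2, 0.15),
            shift=HyperPrior(0.35, 0.15, 0.1),
        )

    def fields_for(self, family: str) -> dict:
        common = {"alpha": self.alpha, "log_gamma": self.log_gamma,
                  "log_kappa": self.log_kappa, "log_sigma": self.log_sigma}
        if family == "multiplicative":
            common["log_gain"] = self.log_gain
        elif family == "additive":
            common["shift"] = self.shift
        else:
            raise ValueError(f"unknown family {family!r}")
        return common

    def to_dict(self) -> dict:
        return asdict(self)


def draw_hyperparameters(prior: PriorSpec, family: str, rng) -> dict:
    """One draw of (mu_theta, tau_theta) per voxel-level parameter."""
    hypers = {}
    for name, hp in prior.fields_for(family).items():
        hypers[f"mu_{name}"] = float(rng.normal(hp.loc, hp.scale))
        hypers[f"tau_{name}"] = float(abs(rng.normal(0.0, hp.tau_scale)))
    return hypers


def draw_voxel_params(prior: PriorSpec, design: ExperimentDesign, family: str,
                      seed=None, rng=None) -> List[VoxelTuningParams]:
    """Hierarchical prior draw: population hyperparameters, then one
    parameter set per voxel (participants share the population level).

    Returns ``design.participants * design.voxels_per_participant`` parameter
    sets in participant-major order.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    hypers = draw_hyperparameters(prior, family, rng)
    n = design.participants * design.voxels_per_participant

    def vox(name):
        return rng.normal(hypers[f"mu_{name}"], hypers[f"tau_{name}"], size=n)

    alpha = vox("alpha")
    gamma = np.exp(vox("log_gamma"))
    kappa = np.exp(vox("log_kappa"))
    sigma = np.exp(vox("log_sigma"))
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    if family == "multiplicative":
        gain = np.exp(vox("log_gain"))
        return [VoxelTuningParams(alpha[i], gamma[i], kappa[i], phi[i],
                                  sigma[i], gain=gain[i]) for i in range(n)]
    shift = vox("shift")
    return [VoxelTuningParams(alpha[i], gamma[i], kappa[i], phi[i],
                              sigma[i], shift=shift[i]) for i in range(n)]


def mixed_population_params(n_voxels: int, frac_flat: float = 0.9,
                            family: str = "multiplicative",
                            tuned_kappa: float = 1.0, tuned_gamma: float = 1.0,
                            alpha: float = 1.0, sigma: float = 0.3,
                            gain: float = 1.5, shift: float = 0.25,
                            seed=None) -> List[VoxelTuningParams]:
    """Explicit population dominated by flat (untuned) voxels.

    Emulates the empirical situation in which most voxels respond almost
    equally to all orientations, with a minority of well-tuned voxels; used
    to reproduce the failure mode of across-voxel averaging.
    """
    if not 0.0 <= frac_flat <= 1.0:
        raise ValueError("frac_flat must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_flat = int(round(frac_flat * n_voxels))
    params = []
    for i in range(n_voxels):
        flat = i < n_flat
        kw = dict(
            alpha_v=alpha,
            gamma_v=tuned_gamma,
            kappa_v=0.0 if flat else tuned_kappa,
            phi_v=rng.uniform(0.0, 2.0 * np.pi),
            sigma_v=sigma,
        )
        if family == "multiplicative":
            params.append(VoxelTuningParams(**kw, gain=gain))
        else:
            params.append(VoxelTuningParams(**kw, shift=shift))
    return params


def simulate_dataset(params: Sequence[VoxelTuningParams],
                     design: ExperimentDesign, family: Optional[str] = None,
                     seed=None, rng=None) -> pd.DataFrame:
    """Simulate a long-format dataset: noiseless tuning curve + Normal noise.

    ``params`` must contain one entry per voxel in the design
    (participant-major order).  Each response is
    ``vtf_response(orientation, condition, family) + Normal(0, sigma_v)``,
    independent across rows.
    """
    n_vox_total = design.participants * design.voxels_per_participant
    if len(params) != n_vox_total:
        raise ValueError(
            f"need {n_vox_total} parameter sets for the design, got {len(params)}"
        )
    if family is None:
        family = params[0].family
    for p in params:
        if p.family != family:
            raise ValueError("parameter family inconsistent with requested family")
    if rng is None:
        rng = np.random.default_rng(seed)

    oris = np.asarray(design.orientations_deg, dtype=float)
    r = to_doubled_angle(oris)
    n_ori, n_con = oris.size, 2
    # per-voxel block layout: run-major, then contrast, repeat, orientation
    run_ix, con_ix, rep_ix, ori_ix = np.unravel_index(
        np.arange(design.runs * n_con * design.repeats_per_run * n_ori),
        (design.runs, n_con, design.repeats_per_run, n_ori),
    )
    block = run_ix.size
    frames = []
    for pi in range(design.participants):
        for vi in range(design.voxels_per_participant):
            v = params[pi * design.voxels_per_participant + vi]
            mu = np.stack([
                vtf_response(r, v, "baseline", family),
                vtf_response(r, v, "modulated", family),
            ])  # (contrast, orientation)
            resp = mu[con_ix, ori_ix] + rng.normal(0.0, v.sigma_v, size=block)
            frames.append(pd.DataFrame({
                "participant": pi,
                "voxel": vi,
                "run": run_ix,
                "orientation_deg": oris[ori_ix],
                "contrast": np.asarray(design.contrasts)[con_ix],
                "repeat": rep_ix,
                "response": resp,
            }))
    out = pd.concat(frames, ignore_index=True)
    return out[DATASET_COLUMNS]


def simulate_from_posterior(draws, design: ExperimentDesign, family: str,
                            n_datasets: int, seed=None,
                            replace: bool = True) -> List[pd.DataFrame]:
    """Data-informed generation: each dataset uses one joint posterior draw.

    ``draws`` is a :class:`~voxtune.hbayes.PosteriorDraws`; a random joint
    draw supplies all voxel-level generating parameters, and the dataset is
    then simulated exactly as from explicit parameters.
    """
    rng = np.random.default_rng(seed)
    total = draws.n_chains * draws.n_draws
    if not replace and n_datasets > total:
        raise ValueError(
            f"{n_datasets} datasets requested without replacement from {total} draws"
        )
    idx = rng.choice(total, size=n_datasets, replace=replace)
    datasets = []
    for i in idx:
        params = draws.voxel_params_at(int(i), family=family)
        datasets.append(simulate_dataset(params, design, family=family, rng=rng))
    return datasets


def write_dataset(data: pd.DataFrame, path, seed=None, family=None,
                  prior: Optional[PriorSpec] = None) -> None:
    """Write a dataset as CSV with a JSON provenance sidecar (seed, family, priors)."""
    path = Path(path)
    data.to_csv(path, index=False)
    sidecar = {
        "seed": seed,
        "family": family,
        "priors": prior.to_dict() if prior is not None else None,
        "n_rows": int(len(data)),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2)
    )
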