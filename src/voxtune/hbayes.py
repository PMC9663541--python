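"""Hierarchical Bayesian estimation of voxel tuning-modulation models.

Both candidate models share the baseline voxel tuning function
``alpha_v + gamma_v * f(r | phi_v, kappa_v)`` and a Normal observation
model with voxel-specific noise ``sigma_v``; they differ only in how the
modulated condition changes the curve (gain ``g_v`` on the tuned component
vs. uniform shift ``a_v``).  Voxel-level parameters are pooled through
population-level location/scale pairs (normal on the log scale for positive
parameters), which lets the model down-weight noisy voxels and share
strength across the population; ``phi_v`` is uniform on the circle and not
pooled.

Posteriors are approximated with an adaptive Metropolis-within-Gibbs
sampler written for this model's structure:

* voxel blocks are conditionally independent given the hyperparameters, so
  component-wise random-walk Metropolis proposals are made for *all* voxels
  simultaneously (one vectorized accept/reject per coordinate), with
  per-voxel proposal scales adapted toward a 0.44 acceptance rate during
  warmup and frozen afterwards;
* population means are updated by conjugate Gibbs draws;
* population scales (half-Normal priors) are updated by scalar adaptive
  Metropolis steps on the log scale.

The likelihood is evaluated through per-cell sufficient statistics
(orientation x condition cell counts, means and within-cell sums of
squares), which makes each proposal O(voxels x cells) regardless of the
number of trials.  Pointwise per-observation log-likelihoods are stored for
cross-validated model comparison.

Convergence is assessed with rank-normalized split R-hat across chains
(phi_v monitored through sin/cos to avoid wrap-around artifacts).  The
random-walk sampler has no Hamiltonian trajectories, so divergences in the
HMC sense cannot occur; the per-draw divergence flags instead record
non-finite posterior-density evaluations (zero in normal operation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy.special import i0e
from sklearn.base import BaseEstimator

from .simulate import PriorSpec, ExperimentDesign
from .tuning import VoxelTuningParams, to_doubled_angle
from .util import order_contrast_labels

__all__ = [
    "HierarchicalModelSpec",
    "PosteriorDraws",
    "ConvergenceReport",
    "fit_model",
    "convergence_report",
    "posterior_predictive",
    "HierarchicalTuningModel",
]

_LOG2PI = float(np.log(2.0 * np.pi))

# sampled voxel-level coordinates, in order; "mod" is log(g_v) or a_v
_COORDS = ("alpha", "log_gamma", "log_kappa", "phi", "mod", "log_sigma")
# coordinates with a normal hierarchical prior (phi is uniform, unpooled)
_POOLED = ("alpha", "log_gamma", "log_kappa", "mod", "log_sigma")


@dataclass(frozen=True)
class HierarchicalModelSpec:
    """Model family, priors and sampler settings.

    ``draws`` is the number of *stored* post-warmup draws per chain; the
    sampler runs ``draws * thin`` post-warmup iterations and keeps every
    ``thin``-th state.  Defaults mirror the study's settings (4 chains,
    1000 adaptation iterations, 2000 posterior draws per chain).
    """

    family: str = "multiplicative"
    prior: PriorSpec = field(default_factory=PriorSpec.default)
    chains: int = 4
    warmup: int = 1000
    draws: int = 2000
    thin: int = 1

    def __post_init__(self):
        if self.family not in ("multiplicative", "additive"):
            raise ValueError(f"unknown family {self.family!r}")
        if min(self.chains, self.warmup, self.draws, self.thin) < 1:
            raise ValueError("sampler settings must be positive")


class _SuffStats:
    """Per-cell sufficient statistics of a long-format dataset."""

    def __init__(self, data: pd.DataFrame, baseline_label=None):
        required = {"participant", "voxel", "run", "orientation_deg",
                    "contrast", "response"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        if data.empty:
            raise ValueError("dataset is empty")
        baseline_label, mod_label = order_contrast_labels(
            data["contrast"].unique(), baseline_label)
        self.contrast_labels = (baseline_label, mod_label)

        key = list(zip(data["participant"], data["voxel"]))
        self.voxel_keys = sorted(set(key))
        vox_map = {k: i for i, k in enumerate(self.voxel_keys)}
        vox_ix = np.array([vox_map[k] for k in key])
        per_vox_conditions = data.groupby(["participant", "voxel"])["contrast"].nunique()
        if (per_vox_conditions < 2).any():
            bad = per_vox_conditions[per_vox_conditions < 2].index.tolist()
            raise ValueError(f"voxels lacking both contrast conditions: {bad}")

        oris = np.sort(data["orientation_deg"].unique())
        self.orientations_deg = oris
        self.r_u = np.asarray(to_doubled_angle(oris))
        ori_ix = np.searchsorted(oris, data["orientation_deg"].to_numpy())
        con_ix = (data["contrast"].to_numpy() == mod_label).astype(int)

        V, K = len(self.voxel_keys), oris.size
        self.V, self.K = V, K
        cell_flat = ori_ix * 2 + con_ix
        self.vox_ix = vox_ix
        self.cell_ix = cell_flat
        self.y = data["response"].to_numpy(dtype=float)
        if not np.all(np.isfinite(self.y)):
            raise ValueError("responses must be finite")

        lin = vox_ix * (K * 2) + cell_flat
        counts = np.bincount(lin, minlength=V * K * 2).astype(float)
        sums = np.bincount(lin, weights=self.y, minlength=V * K * 2)
        sums2 = np.bincount(lin, weights=self.y ** 2, minlength=V * K * 2)
        self.counts = counts.reshape(V, K * 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        self.means = means.reshape(V, K * 2)
        ssw = sums2 - counts * means ** 2
        self.ssw = ssw.reshape(V, K * 2).sum(axis=1)
        self.n_per_voxel = self.counts.sum(axis=1)
        self.n_obs = self.y.size


def _vm_rows(r_u, phi, kappa):
    """Von Mises density f(r_u | phi_v, kappa_v) -> (V, K)."""
    return (np.exp(kappa[:, None] * (np.cos(r_u[None, :] - phi[:, None]) - 1.0))
            / (2.0 * np.pi * i0e(kappa)[:, None]))


def _cell_means(state, stats, family):
    """Model means per (voxel, orientation x condition) cell -> (V, K*2)."""
    alpha = state["alpha"]
    gamma = np.exp(state["log_gamma"])
    kappa = np.exp(state["log_kappa"])
    f = _vm_rows(stats.r_u, state["phi"], kappa)
    mu = np.empty((stats.V, stats.K, 2))
    mu[:, :, 0] = alpha[:, None] + gamma[:, None] * f
    if family == "multiplicative":
        mu[:, :, 1] = alpha[:, None] + (np.exp(state["mod"]) * gamma)[:, None] * f
    else:
        mu[:, :, 1] = mu[:, :, 0] + state["mod"][:, None]
    return mu.reshape(stats.V, stats.K * 2)


def _voxel_loglik(state, stats, family):
    """Gaussian log-likelihood per voxel via sufficient statistics -> (V,)."""
    mu = _cell_means(state, stats, family)
    sigma = np.exp(state["log_sigma"])
    # extreme warmup states can overflow to inf; such proposals are rejected
    with np.errstate(over="ignore", invalid="ignore"):
        quad = stats.ssw + np.sum(stats.counts * (stats.means - mu) ** 2,
                                  axis=1)
        return (-stats.n_per_voxel * (state["log_sigma"] + 0.5 * _LOG2PI)
                - quad / (2.0 * sigma ** 2))


def _voxel_logprior(state, hypers, family):
    """Hierarchical normal log-prior per voxel -> (V,); phi uniform."""
    lp = np.zeros_like(state["alpha"])
    for name in _POOLED:
        mu, tau = hypers[f"mu_{name}"], hypers[f"tau_{name}"]
        lp += -np.log(tau) - 0.5 * ((state[name] - mu) / tau) ** 2
    return lp


def _prior_hp(prior: PriorSpec, family: str) -> Dict[str, "HyperPrior"]:
    m = prior.fields_for(family)
    return {"alpha": m["alpha"], "log_gamma": m["log_gamma"],
            "log_kappa": m["log_kappa"], "log_sigma": m["log_sigma"],
            "mod": m["log_gain" if family == "multiplicative" else "shift"]}


def _init_state(stats, prior, family, rng):
    """Overdispersed initialization from the hierarchical prior."""
    hp = _prior_hp(prior, family)
    hypers = {}
    for name, h in hp.items():
        hypers[f"mu_{name}"] = rng.normal(h.loc, h.scale)
        hypers[f"tau_{name}"] = max(abs(rng.normal(0.0, h.tau_scale)), 1e-3)
    state = {}
    for name in _POOLED:
        state[name] = rng.normal(hypers[f"mu_{name}"], hypers[f"tau_{name}"],
                                 size=stats.V)
    state["phi"] = rng.uniform(0.0, 2.0 * np.pi, size=stats.V)
    # keep the initial noise scale from starting absurdly small
    state["log_sigma"] = np.maximum(state["log_sigma"], np.log(1e-3))
    return state, hypers


def _state_matrix(state):
    return np.stack([state[name] for name in _COORDS], axis=1)  # (V, 6)


def _matrix_state(mat):
    return {name: mat[:, j].copy() for j, name in enumerate(_COORDS)}


def _run_chain(stats, prior, family, spec, rng):
    hp = _prior_hp(prior, family)
    state, hypers = _init_state(stats, prior, family, rng)
    loglik = _voxel_loglik(state, stats, family)
    scales = {name: np.full(stats.V, 0.2) for name in _COORDS}
    scales["phi"][:] = 0.5
    tau_scales = {name: 0.3 for name in _POOLED}
    nc_scales = {name: 0.1 for name in _POOLED}
    nc_acc = {name: 0.0 for name in _POOLED}
    nc_tau_scales = {name: 0.5 for name in _POOLED}
    nc_tau_acc = {name: 0.0 for name in _POOLED}

    n_keep = spec.draws
    n_post = n_keep * spec.thin
    n_total = spec.warmup + n_post
    acc = {name: np.zeros(stats.V) for name in _COORDS}
    tau_acc = {name: 0.0 for name in _POOLED}
    batch = 25

    # Haario-style joint proposals: per-voxel empirical covariance of the
    # 6 sampled coordinates, accumulated over the later part of warmup
    n_coord = len(_COORDS)
    cov_start = max(50, spec.warmup // 5)
    welford_n = 0
    welford_mean = np.zeros((stats.V, n_coord))
    welford_m2 = np.zeros((stats.V, n_coord, n_coord))
    chol = None
    joint_scale = np.full(stats.V, 2.38 / np.sqrt(n_coord))
    joint_acc = np.zeros(stats.V)

    out_vox = {name: np.empty((n_keep, stats.V)) for name in _COORDS}
    out_hyp = {k: np.empty(n_keep) for k in hypers}
    out_ll = np.empty((n_keep, stats.n_obs))
    divergent = np.zeros(n_keep, dtype=bool)
    kept = 0

    for it in range(1, n_total + 1):
        # --- component-wise MH on voxel blocks (vectorized over voxels) ---
        for name in _COORDS:
            prop = dict(state)
            prop[name] = state[name] + scales[name] * rng.standard_normal(stats.V)
            if name == "phi":
                prop[name] = np.mod(prop[name], 2.0 * np.pi)
            new_ll = _voxel_loglik(prop, stats, family)
            d_prior = (_voxel_logprior(prop, hypers, family)
                       - _voxel_logprior(state, hypers, family))
            log_ratio = (new_ll - loglik) + d_prior
            accept = np.log(rng.uniform(size=stats.V)) < log_ratio
            accept &= np.isfinite(new_ll)
            state[name] = np.where(accept, prop[name], state[name])
            loglik = np.where(accept, new_ll, loglik)
            acc[name] += accept

        # --- joint per-voxel MH along the adapted covariance ---
        mat = _state_matrix(state)
        if it >= cov_start:
            welford_n += 1
            delta = mat - welford_mean
            welford_mean += delta / welford_n
            welford_m2 += delta[:, :, None] * (mat - welford_mean)[:, None, :]
        if chol is not None:
            z = rng.standard_normal((stats.V, n_coord))
            step_vec = joint_scale[:, None] * np.einsum("vij,vj->vi", chol, z)
            prop_mat = mat + step_vec
            prop_mat[:, 3] = np.mod(prop_mat[:, 3], 2.0 * np.pi)  # phi wraps
            prop = _matrix_state(prop_mat)
            new_ll = _voxel_loglik(prop, stats, family)
            d_prior = (_voxel_logprior(prop, hypers, family)
                       - _voxel_logprior(state, hypers, family))
            accept = np.log(rng.uniform(size=stats.V)) < (new_ll - loglik + d_prior)
            accept &= np.isfinite(new_ll)
            for j, name in enumerate(_COORDS):
                state[name] = np.where(accept, prop_mat[:, j], state[name])
            loglik = np.where(accept, new_ll, loglik)
            joint_acc += accept

        # --- hyperparameters ---
        for name in _POOLED:
            h = hp[name]
            theta = state[name]
            tau = hypers[f"tau_{name}"]
            # conjugate Gibbs for the population mean
            prec = 1.0 / h.scale ** 2 + stats.V / tau ** 2
            mean = (h.loc / h.scale ** 2 + theta.sum() / tau ** 2) / prec
            mu = rng.normal(mean, 1.0 / np.sqrt(prec))
            hypers[f"mu_{name}"] = mu
            # scalar MH on log(tau), half-Normal(tau_scale) prior
            s = np.sum((theta - mu) ** 2)

            def _lp(u):
                t2 = np.exp(2.0 * u)
                return (-stats.V * u - s / (2.0 * t2)
                        - t2 / (2.0 * h.tau_scale ** 2) + u)

            u0 = np.log(tau)
            u1 = u0 + tau_scales[name] * rng.standard_normal()
            if np.log(rng.uniform()) < _lp(u1) - _lp(u0):
                hypers[f"tau_{name}"] = float(np.exp(u1))
                tau_acc[name] += 1.0

        # --- interweaved non-centered update of (mu, tau) per pooled coord ---
        # Holding the standardized effects eta_v = (theta_v - mu)/tau fixed,
        # (mu, log tau) are moved jointly through the likelihood; this breaks
        # the funnel coupling that slows the centered Gibbs updates when a
        # coordinate is weakly identified at the voxel level.
        for j, name in enumerate(_COORDS):
            if name not in _POOLED:
                continue
            h = hp[name]
            mu0, tau0 = hypers[f"mu_{name}"], hypers[f"tau_{name}"]
            eta = (state[name] - mu0) / tau0
            s = nc_scales[name]
            mu1 = mu0 + s * rng.standard_normal()
            u1 = np.log(tau0) + s * rng.standard_normal()
            tau1 = float(np.exp(u1))
            prop = dict(state)
            prop[name] = mu1 + tau1 * eta
            new_ll = _voxel_loglik(prop, stats, family)
            d_hyper = (
                -0.5 * ((mu1 - h.loc) / h.scale) ** 2
                + 0.5 * ((mu0 - h.loc) / h.scale) ** 2
                - (tau1 ** 2 - tau0 ** 2) / (2.0 * h.tau_scale ** 2)
                + (u1 - np.log(tau0))  # log-scale Jacobian for tau
            )
            log_ratio = float(np.sum(new_ll - loglik)) + d_hyper
            if np.isfinite(log_ratio) and np.log(rng.uniform()) < log_ratio:
                hypers[f"mu_{name}"] = float(mu1)
                hypers[f"tau_{name}"] = tau1
                state[name] = prop[name]
                loglik = new_ll
                nc_acc[name] += 1.0

            # tau-only non-centered step: larger multiplicative jumps in the
            # population scale, traversing the funnel neck directly
            mu0, tau0 = hypers[f"mu_{name}"], hypers[f"tau_{name}"]
            eta = (state[name] - mu0) / tau0
            u0 = np.log(tau0)
            u1 = u0 + nc_tau_scales[name] * rng.standard_normal()
            tau1 = float(np.exp(u1))
            prop = dict(state)
            prop[name] = mu0 + tau1 * eta
            new_ll = _voxel_loglik(prop, stats, family)
            d_hyper = (-(tau1 ** 2 - tau0 ** 2) / (2.0 * h.tau_scale ** 2)
                       + (u1 - u0))
            log_ratio = float(np.sum(new_ll - loglik)) + d_hyper
            if np.isfinite(log_ratio) and np.log(rng.uniform()) < log_ratio:
                hypers[f"tau_{name}"] = tau1
                state[name] = prop[name]
                loglik = new_ll
                nc_tau_acc[name] += 1.0

        # --- proposal-scale adaptation during warmup only ---
        if it <= spec.warmup and it % batch == 0:
            step = min(0.5, 2.0 / np.sqrt(it / batch))
            for name in _COORDS:
                rate = acc[name] / batch
                scales[name] = np.exp(np.log(scales[name])
                                      + step * (rate - 0.44))
                acc[name][:] = 0.0
            scales["phi"] = np.minimum(scales["phi"], np.pi)
            for name in _POOLED:
                tau_scales[name] = float(np.exp(
                    np.log(tau_scales[name]) + step * (tau_acc[name] / batch - 0.44)))
                tau_acc[name] = 0.0
                nc_scales[name] = float(np.exp(
                    np.log(nc_scales[name]) + step * (nc_acc[name] / batch - 0.28)))
                nc_acc[name] = 0.0
                nc_tau_scales[name] = float(max(0.1, np.exp(
                    np.log(nc_tau_scales[name])
                    + step * (nc_tau_acc[name] / batch - 0.35))))
                nc_tau_acc[name] = 0.0
            if welford_n >= 2 * n_coord:
                cov = welford_m2 / (welford_n - 1)
                cov += 1e-6 * np.eye(n_coord)[None, :, :]
                try:
                    new_chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    new_chol = chol
                if chol is not None:
                    joint_scale = np.exp(np.log(joint_scale)
                                         + step * (joint_acc / batch - 0.28))
                chol = new_chol
                joint_acc[:] = 0.0

        # --- storage ---
        if it > spec.warmup and (it - spec.warmup) % spec.thin == 0:
            for name in _COORDS:
                out_vox[name][kept] = state[name]
            for k, v in hypers.items():
                out_hyp[k][kept] = v
            mu_cells = _cell_means(state, stats, family)
            sig = np.exp(state["log_sigma"])
            resid = stats.y - mu_cells[stats.vox_ix, stats.cell_ix]
            out_ll[kept] = (-state["log_sigma"][stats.vox_ix] - 0.5 * _LOG2PI
                            - 0.5 * (resid / sig[stats.vox_ix]) ** 2)
            divergent[kept] = not np.all(np.isfinite(loglik))
            kept += 1

    return out_vox, out_hyp, out_ll, divergent


@dataclass
class PosteriorDraws:
    """Per-chain posterior draws, pointwise log-likelihoods and metadata."""

    voxel: Dict[str, np.ndarray]        # name -> (chains, draws, V)
    hyper: Dict[str, np.ndarray]        # name -> (chains, draws)
    log_lik: np.ndarray                 # (chains, draws, n_obs)
    divergent: np.ndarray               # (chains, draws) bool
    family: str
    voxel_keys: list
    orientations_deg: np.ndarray
    contrast_labels: tuple
    spec: HierarchicalModelSpec

    @property
    def n_chains(self) -> int:
        return self.log_lik.shape[0]

    @property
    def n_draws(self) -> int:
        return self.log_lik.shape[1]

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_keys)

    def natural_arrays(self) -> Dict[str, np.ndarray]:
        """Draws on the natural scale: alpha, gamma, kappa, phi, sigma and
        gain (multiplicative) or shift (additive)."""
        out = {
            "alpha": self.voxel["alpha"],
            "gamma": np.exp(self.voxel["log_gamma"]),
            "kappa": np.exp(self.voxel["log_kappa"]),
            "phi": self.voxel["phi"],
            "sigma": np.exp(self.voxel["log_sigma"]),
        }
        if self.family == "multiplicative":
            out["gain"] = np.exp(self.voxel["mod"])
        else:
            out["shift"] = self.voxel["mod"]
        return out

    def voxel_params_at(self, flat_index: int, family: Optional[str] = None
                        ) -> List[VoxelTuningParams]:
        """Generating parameters from one joint draw (chain-major flat index)."""
        family = family or self.family
        if family != self.family:
            raise ValueError("draws were fitted under a different family")
        c, d = divmod(int(flat_index), self.n_draws)
        nat = self.natural_arrays()
        params = []
        for v in range(self.n_voxels):
            kw = dict(alpha_v=nat["alpha"][c, d, v], gamma_v=nat["gamma"][c, d, v],
                      kappa_v=nat["kappa"][c, d, v], phi_v=nat["phi"][c, d, v],
                      sigma_v=nat["sigma"][c, d, v])
            if family == "multiplicative":
                params.append(VoxelTuningParams(**kw, gain=nat["gain"][c, d, v]))
            else:
                params.append(VoxelTuningParams(**kw, shift=nat["shift"][c, d, v]))
        return params

    def to_inference_data(self):
        """Pack draws and pointwise log-likelihood into an arviz InferenceData."""
        import arviz as az

        posterior = {k: v for k, v in self.natural_arrays().items()}
        posterior.update(self.hyper)
        return az.from_dict(
            posterior=posterior,
            log_likelihood={"y": self.log_lik},
            sample_stats={"diverging": self.divergent},
        )

    def to_frame(self) -> pd.DataFrame:
        """Flat tabular export of all draws (chain, draw, parameter, voxel, value)."""
        rows = []
        nat = self.natural_arrays()
        for name, arr in nat.items():
            c, d, v = np.meshgrid(np.arange(self.n_chains),
                                  np.arange(self.n_draws),
                                  np.arange(self.n_voxels), indexing="ij")
            rows.append(pd.DataFrame({
                "chain": c.ravel(), "draw": d.ravel(), "parameter": name,
                "voxel_index": v.ravel(), "value": arr.ravel()}))
        for name, arr in self.hyper.items():
            c, d = np.meshgrid(np.arange(self.n_chains),
                               np.arange(self.n_draws), indexing="ij")
            rows.append(pd.DataFrame({
                "chain": c.ravel(), "draw": d.ravel(), "parameter": name,
                "voxel_index": -1, "value": arr.ravel()}))
        return pd.concat(rows, ignore_index=True)


def fit_model(data: pd.DataFrame, spec: HierarchicalModelSpec,
              seed: Optional[int] = None,
              baseline_label=None) -> PosteriorDraws:
    """Fit the hierarchical model of the requested family to a long dataset.

    Chains are run independently with seeds derived from ``seed`` via
    ``numpy`` seed spawning; the result is reproducible given the same data,
    spec and seed.
    """
    stats = _SuffStats(data, baseline_label=baseline_label)
    seq = np.random.SeedSequence(seed)
    chain_rngs = [np.random.default_rng(s) for s in seq.spawn(spec.chains)]
    vox_draws, hyp_draws, lls, divs = [], [], [], []
    for rng in chain_rngs:
        ov, oh, ll, dv = _run_chain(stats, spec.prior, spec.family, spec, rng)
        vox_draws.append(ov)
        hyp_draws.append(oh)
        lls.append(ll)
        divs.append(dv)
    voxel = {name: np.stack([d[name] for d in vox_draws]) for name in _COORDS}
    hyper = {k: np.stack([d[k] for d in hyp_draws]) for k in hyp_draws[0]}
    return PosteriorDraws(
        voxel=voxel, hyper=hyper, log_lik=np.stack(lls),
        divergent=np.stack(divs), family=spec.family,
        voxel_keys=stats.voxel_keys, orientations_deg=stats.orientations_deg,
        contrast_labels=stats.contrast_labels, spec=spec,
    )


@dataclass
class ConvergenceReport:
    """Split R-hat per parameter, divergence count and a pass/fail verdict."""

    rhat: Dict[str, float]
    max_rhat: float
    n_divergent: int
    threshold: float
    passed: bool

    def to_dict(self) -> dict:
        return {"rhat": self.rhat, "max_rhat": self.max_rhat,
                "n_divergent": self.n_divergent,
                "threshold": self.threshold, "passed": self.passed}


def convergence_report(draws: PosteriorDraws,
                       rhat_threshold: float = 1.1) -> ConvergenceReport:
    """Rank-normalized split R-hat for every parameter plus divergence count.

    The circular phi_v is monitored through sin/cos components.  Parameters
    with zero variance in all chains yield NaN R-hat (reported with a
    warning); the verdict passes only when every R-hat is finite and below
    the threshold and no draw is divergent.
    """
    import arviz as az

    if draws.n_chains < 2:
        raise ValueError("split R-hat requires >= 2 chains")
    monitored = {k: v for k, v in draws.natural_arrays().items() if k != "phi"}
    monitored["sin_phi"] = np.sin(draws.voxel["phi"])
    monitored["cos_phi"] = np.cos(draws.voxel["phi"])
    monitored.update(draws.hyper)

    rhats = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ds = az.rhat(az.from_dict(posterior=monitored))
    for name in ds.data_vars:
        vals = np.asarray(ds[name]).ravel()
        rhats[str(name)] = float(np.nanmax(vals)) if np.isfinite(vals).any() else float("nan")
        if np.isnan(vals).any():
            warnings.warn(f"R-hat undefined (zero variance) for {name}",
                          stacklevel=2)
    finite = [v for v in rhats.values() if np.isfinite(v)]
    max_rhat = max(finite) if finite else float("nan")
    any_nan = any(np.isnan(v) for v in rhats.values())
    n_div = int(draws.divergent.sum())
    passed = bool(np.isfinite(max_rhat) and not any_nan
                  and max_rhat < rhat_threshold and n_div == 0)
    return ConvergenceReport(rhat=rhats, max_rhat=max_rhat,
                             n_divergent=n_div, threshold=rhat_threshold,
                             passed=passed)


def posterior_predictive(draws: PosteriorDraws, credibility: float = 0.95,
                         seed: Optional[int] = None) -> pd.DataFrame:
    """Central predictive interval of replicated responses per
    (voxel, orientation, contrast) cell.

    One replicated response is simulated per posterior draw and cell; the
    returned table has columns voxel_index, orientation_deg, contrast,
    predictive_mean, lo, hi.
    """
    if not 0.0 < credibility < 1.0:
        raise ValueError("credibility must be in (0, 1)")
    rng = np.random.default_rng(seed)
    nat = draws.natural_arrays()
    r_u = np.asarray(to_doubled_angle(draws.orientations_deg))
    C, D, V = draws.n_chains, draws.n_draws, draws.n_voxels
    K = r_u.size
    alpha = nat["alpha"].reshape(C * D, V)
    gamma = nat["gamma"].reshape(C * D, V)
    kappa = nat["kappa"].reshape(C * D, V)
    phi = nat["phi"].reshape(C * D, V)
    sigma = nat["sigma"].reshape(C * D, V)
    f = (np.exp(kappa[..., None] * (np.cos(r_u[None, None, :] - phi[..., None]) - 1.0))
         / (2.0 * np.pi * i0e(kappa)[..., None]))       # (S, V, K)
    mu0 = alpha[..., None] + gamma[..., None] * f
    if draws.family == "multiplicative":
        mu1 = alpha[..., None] + (nat["gain"].reshape(C * D, V) * gamma)[..., None] * f
    else:
        mu1 = mu0 + nat["shift"].reshape(C * D, V)[..., None]
    lo_q, hi_q = (1 - credibility) / 2.0, 1 - (1 - credibility) / 2.0
    rows = []
    for ci, mu in zip(draws.contrast_labels, (mu0, mu1)):
        rep = mu + sigma[..., None] * rng.standard_normal(mu.shape)
        lo = np.quantile(rep, lo_q, axis=0)
        hi = np.quantile(rep, hi_q, axis=0)
        mean = rep.mean(axis=0)
        v_ix, k_ix = np.meshgrid(np.arange(V), np.arange(K), indexing="ij")
        rows.append(pd.DataFrame({
            "voxel_index": v_ix.ravel(),
            "orientation_deg": draws.orientations_deg[k_ix.ravel()],
            "contrast": ci,
            "predictive_mean": mean.ravel(),
            "lo": lo.ravel(),
            "hi": hi.ravel(),
        }))
    return pd.concat(rows, ignore_index=True)


class HierarchicalTuningModel(BaseEstimator):
    """Scikit-learn style front end for the hierarchical Bayesian fit.

    ``fit(data)`` expects a long-format dataset (participant, voxel, run,
    orientation_deg, contrast, response) and exposes ``draws_``
    (:class:`PosteriorDraws`) and ``convergence_`` (:class:`ConvergenceReport`).
    """

    def __init__(self, family: str = "multiplicative",
                 prior: Optional[PriorSpec] = None, chains: int = 4,
                 warmup: int = 1000, draws: int = 2000, thin: int = 1,
                 rhat_threshold: float = 1.1,
                 random_state: Optional[int] = None):
        self.family = family
        self.prior = prior
        self.chains = chains
        self.warmup = warmup
        self.draws = draws
        self.thin = thin
        self.rhat_threshold = rhat_threshold
        self.random_state = random_state

    def _spec(self) -> HierarchicalModelSpec:
        return HierarchicalModelSpec(
            family=self.family,
            prior=self.prior if self.prior is not None else PriorSpec.default(),
            chains=self.chains, warmup=self.warmup, draws=self.draws,
            thin=self.thin,
        )

    def fit(self, X: pd.DataFrame, y=None):
        self.draws_ = fit_model(X, self._spec(), seed=self.random_state)
        self.convergence_ = convergence_report(self.draws_,
                                               self.rhat_threshold)
        return self

    def posterior_predictive(self, credibility: float = 0.95,
                             seed: Optional[int] = None) -> pd.DataFrame:
        return posterior_predictive(self.draws_, credibility=credibility,
                                    seed=seed)
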