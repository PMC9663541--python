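"""Orthogonal-regression slope: closed form, tie-breaks, voxel summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from sklearn.base import clone

from voxtune.simulate import ExperimentDesign, simulate_dataset
from voxtune.slope import (OrthogonalRegression, SlopePairs, build_pairs,
                           orthogonal_slope, per_voxel_angles, slope_to_angle)
from voxtune.tuning import VoxelTuningParams


def tls_oracle(x, y):
    """Numerical oracle: minimize summed squared perpendicular distances
    over (slope, intercept)."""

    def perp_ss(p):
        m, b = p
        return np.sum((y - m * x - b) ** 2) / (1.0 + m * m)

    best = None
    for m0 in (-2.0, -0.5, 0.5, 2.0):
        res = minimize(perp_ss, [m0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14,
                                "maxiter": 20000})
        if best is None or res.fun < best.fun:
            best = res
    return best.x[0]


class TestClosedForm:
    def test_exact_additive_line_slope_one(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        fit = orthogonal_slope(SlopePairs(x, x + 2.0))
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.angle_deg == pytest.approx(45.0, abs=1e-9)

    def test_exact_double_line_slope_two(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        fit = orthogonal_slope(SlopePairs(x, 2.0 * x))
        assert fit.slope == pytest.approx(2.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_numerical_tls_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 30)
        x = rng.normal(0.0, 1.0, n)
        y = rng.uniform(0.5, 2.0) * x + rng.normal(0.0, 0.5, n)
        fit = orthogonal_slope(SlopePairs(x, y))
        oracle = tls_oracle(x, y)
        assert fit.slope == pytest.approx(oracle, rel=1e-6)

    @pytest.mark.parametrize("seed", range(20))
    def test_swap_symmetry(self, seed):
        rng = np.random.default_rng(1000 + seed)
        x = rng.normal(size=30)
        y = 1.7 * x + rng.normal(0.0, 0.4, 30)
        g = orthogonal_slope(SlopePairs(x, y)).slope
        g_swapped = orthogonal_slope(SlopePairs(y, x)).slope
        assert g_swapped == pytest.approx(1.0 / g, rel=1e-9)
        # angles reflect about 45 degrees
        assert slope_to_angle(g) + slope_to_angle(g_swapped) == pytest.approx(
            90.0, abs=1e-7)

    def test_bracketed_by_ols_slopes(self):
        # TLS lies between y-on-x OLS and the reciprocal of x-on-y OLS
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        y = 1.5 * x + rng.normal(0.0, 1.0, 200)
        sxx = np.sum((x - x.mean()) ** 2)
        syy = np.sum((y - y.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        ols_yx = sxy / sxx
        inv_ols_xy = syy / sxy
        tls = orthogonal_slope(SlopePairs(x, y)).slope
        lo, hi = sorted([ols_yx, inv_ols_xy])
        assert lo - 1e-12 <= tls <= hi + 1e-12

    def test_scale_equivariance(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=40)
        y = 1.3 * x + rng.normal(0.0, 0.3, 40)
        g = orthogonal_slope(SlopePairs(x, y)).slope
        g_scaled = orthogonal_slope(SlopePairs(3.7 * x, 3.7 * y)).slope
        assert g_scaled == pytest.approx(g, rel=1e-12)


class TestDegenerateCases:
    def test_zero_sxy_principal_axis_horizontal(self):
        x = np.array([-1.0, 0.0, 1.0])
        y = np.zeros(3)
        fit = orthogonal_slope(SlopePairs(x, y))
        assert fit.slope == 0.0 and fit.angle_deg == 0.0

    def test_zero_sxy_principal_axis_vertical(self):
        fit = orthogonal_slope(SlopePairs(np.zeros(3),
                                          np.array([-1.0, 0.0, 1.0])))
        assert math.isinf(fit.slope) and fit.angle_deg == 90.0

    def test_isotropic_cloud_flagged(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, -1.0, -1.0, 1.0])  # Sxy=0, Sxx=Syy
        fit = orthogonal_slope(SlopePairs(x, y))
        assert fit.degenerate and fit.angle_deg is None

    def test_no_variance_flagged(self):
        fit = orthogonal_slope(SlopePairs(np.ones(4), np.ones(4)))
        assert fit.degenerate

    def test_negative_slope_angle_above_90(self):
        x = np.array([0.0, 1.0, 2.0])
        fit = orthogonal_slope(SlopePairs(x, -x))
        assert 90.0 < fit.angle_deg < 180.0
        assert fit.angle_deg == pytest.approx(135.0, abs=1e-9)


class TestEstimatorInterface:
    def test_fit_predict_and_clone(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        y = 2.0 * x + 1.0
        est = OrthogonalRegression().fit(x, y)
        assert est.slope_ == pytest.approx(2.0, abs=1e-9)
        np.testing.assert_allclose(est.predict(np.array([0.0])),
                                   [1.0], atol=1e-9)
        clone(est)  # sklearn-compatible params


class TestPairBuilding:
    def _dataset(self, runs=18, n_ori=8, repeats=2):
        design = ExperimentDesign(participants=1, voxels_per_participant=1,
                                  runs=runs, repeats_per_run=repeats,
                                  orientations_deg=tuple(
                                      np.arange(n_ori) * 180.0 / n_ori))
        v = VoxelTuningParams(1.0, 2.0, 2.0, 0.3, 0.2, gain=1.4)
        return simulate_dataset([v], design, "multiplicative", seed=0)

    def test_full_crossing_pair_count(self):
        pairs = build_pairs(self._dataset(), 0)
        assert pairs.n == 18 * 8

    def test_pair_count_matches_brute_force_join(self):
        data = self._dataset()
        # independent oracle: explicit merge of per-cell means
        low = (data[data.contrast == "low"]
               .groupby(["run", "orientation_deg"])["response"].mean()
               .reset_index())
        high = (data[data.contrast == "high"]
                .groupby(["run", "orientation_deg"])["response"].mean()
                .reset_index())
        merged = low.merge(high, on=["run", "orientation_deg"])
        pairs = build_pairs(data, 0)
        assert pairs.n == len(merged)
        np.testing.assert_allclose(np.sort(pairs.x),
                                   np.sort(merged["response_x"].to_numpy()))

    def test_missing_condition_rows_dropped(self):
        data = self._dataset()
        mask = (data["run"] == 3) & (data["contrast"] == "high")
        pairs = build_pairs(data[~mask], 0)
        assert pairs.n == 17 * 8
        assert pairs.n_dropped == 8

    def test_voxel_without_both_conditions_errors(self):
        data = self._dataset()
        with pytest.raises(ValueError):
            build_pairs(data[data.contrast == "low"], 0)


class TestPerVoxelSummary:
    def _population_dataset(self, family, noiseless=True, n_vox=12, seed=21):
        rng = np.random.default_rng(seed)
        design = ExperimentDesign(participants=1,
                                  voxels_per_participant=n_vox, runs=4,
                                  repeats_per_run=1)
        params = []
        for _ in range(n_vox):
            kw = dict(alpha_v=1.0, gamma_v=float(rng.uniform(0.5, 2.0)),
                      kappa_v=float(rng.uniform(1.0, 3.0)),
                      phi_v=float(rng.uniform(0, 2 * np.pi)),
                      sigma_v=1e-9 if noiseless else 0.3)
            if family == "multiplicative":
                params.append(VoxelTuningParams(**kw, gain=1.5))
            else:
                params.append(VoxelTuningParams(**kw, shift=0.4))
        return simulate_dataset(params, design, family, seed=seed)

    def test_noiseless_additive_all_angles_45(self):
        data = self._population_dataset("additive")
        fits, summary = per_voxel_angles(data, n_boot=200, seed=0)
        np.testing.assert_allclose(fits["angle_deg"], 45.0, atol=1e-6)
        assert summary["median_angle_deg"] == pytest.approx(45.0, abs=1e-6)

    def test_noiseless_multiplicative_all_angles_above_45(self):
        data = self._population_dataset("multiplicative")
        fits, _ = per_voxel_angles(data, n_boot=200, seed=0)
        assert (fits["angle_deg"] > 45.0).all()

    def test_bootstrap_ci_brackets_median(self):
        data = self._population_dataset("multiplicative", noiseless=False)
        _, summary = per_voxel_angles(data, n_boot=500, seed=0)
        assert summary["ci_low"] <= summary["median_angle_deg"] <= summary["ci_high"]

    def test_median_above_45_under_noisy_multiplicative_replicates(self):
        # simulation oracle, scaled down: clear in >= 95% of replicates
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            data = self._population_dataset("multiplicative",
                                            noiseless=False, seed=300 + seed)
            _, summary = per_voxel_angles(data, n_boot=50, seed=0)
            hits += summary["median_angle_deg"] > 45.0
        assert hits >= int(0.95 * n_rep)
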