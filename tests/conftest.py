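import numpy as np
import pytest

from voxtune.simulate import (ExperimentDesign, PriorSpec, draw_voxel_params,
                              simulate_dataset)
from voxtune.tuning import VoxelTuningParams


@pytest.fixture(scope="session")
def small_design():
    """Compact factorial design used by fast unit tests."""
    return ExperimentDesign(participants=1, voxels_per_participant=6, runs=4,
                            repeats_per_run=1)


@pytest.fixture(scope="session")
def tuned_mult_params():
    """Six clearly tuned multiplicative voxels with known gains, low noise."""
    rng = np.random.default_rng(1234)
    return [
        VoxelTuningParams(
            alpha_v=1.0,
            gamma_v=float(rng.lognormal(0.0, 0.2)),
            kappa_v=float(rng.lognormal(np.log(2.0), 0.2)),
            phi_v=float(rng.uniform(0.0, 2.0 * np.pi)),
            sigma_v=0.1,
            gain=float(rng.lognormal(np.log(1.5), 0.15)),
        )
        for _ in range(6)
    ]


@pytest.fixture(scope="session")
def tuned_mult_dataset(small_design, tuned_mult_params):
    return simulate_dataset(tuned_mult_params, small_design,
                            "multiplicative", seed=99)


@pytest.fixture(scope="session")
def small_mult_fit(tuned_mult_dataset):
    """One small hierarchical fit shared by several unit tests."""
    from voxtune.hbayes import HierarchicalModelSpec, fit_model

    spec = HierarchicalModelSpec(
        family="multiplicative", prior=PriorSpec.recovery_default(),
        chains=2, warmup=400, draws=200, thin=2,
    )
    return fit_model(tuned_mult_dataset, spec, seed=77)
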