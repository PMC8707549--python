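import numpy as np
import pytest

from kernelharm.pipeline import ExperimentConfig, run_experiment
from kernelharm.simcohort import PhantomSpec, generate_cohort


@pytest.fixture(scope="session")
def experiment_report():
    """One full default-scale experiment (dev n=16, val n=60), shared by the
    end-to-end reproducibility-gain, shape-invariance and AUC-gain checks."""
    return run_experiment(ExperimentConfig(seed=1))


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small paired-kernel cohort on a reduced grid for structural tests."""
    # z extent 22 still admits the default LoG sigma-2.5 kernel (21 voxels)
    spec = PhantomSpec(grid_shape=(24, 24, 22), lesion_radius=4.0)
    return generate_cohort(6, 0.5, spec, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_small_roi(rng, max_side=5, n_levels=4):
    """Random quantized ROI of at most max_side^3 voxels with a random mask."""
    from kernelharm.radfeat.quantize import QuantizedROI

    shape = tuple(int(rng.integers(2, max_side + 1)) for _ in range(3))
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask[0, 0, 0] = True
    levels = np.zeros(shape, dtype=np.int32)
    levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    return QuantizedROI(levels=levels, n_levels=n_levels,
                        bin_edges=np.arange(n_levels + 1, dtype=float))
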