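import numpy as np
import pytest

from gnawfe import MandibleParams, generate_mandible
from gnawfe.postprocess import ExperimentConfig, run_experiment
from gnawfe.voxel_model import MaterialTable


@pytest.fixture(scope="session")
def materials():
    return MaterialTable.default()


@pytest.fixture(scope="session")
def coarse_params():
    # 0.5 mm voxels: fast unit-test resolution, still >2 voxels across the root
    return MandibleParams(spacing=0.5)


@pytest.fixture(scope="session")
def coarse_mandible(coarse_params):
    return generate_mandible(coarse_params)


@pytest.fixture(scope="session")
def coarse_pipeline(tmp_path_factory):
    """Full five-variant experiment at unit-test resolution (0.5 mm)."""
    outdir = tmp_path_factory.mktemp("coarse_run")
    cfg = ExperimentConfig(
        params=MandibleParams(spacing=0.5), write_fields=False, make_plots=False
    )
    return run_experiment(cfg, outdir=outdir), outdir


@pytest.fixture(scope="session")
def default_pipeline(tmp_path_factory):
    """The study-condition experiment: default mandible at 0.25 mm spacing."""
    outdir = tmp_path_factory.mktemp("default_run")
    cfg = ExperimentConfig(write_fields=False, make_plots=False)
    return run_experiment(cfg, outdir=outdir), outdir


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
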