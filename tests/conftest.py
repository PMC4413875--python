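import warnings
from pathlib import Path

import numpy as np
import pytest

FIXTURES = Path(__file__).resolve().parent.parent / "fixtures"


@pytest.fixture(scope="session")
def default_config():
    from crystomo.pipeline import load_config

    return load_config(FIXTURES / "default_pipeline.json")


@pytest.fixture(scope="session")
def crystal_volume(default_config):
    """Noiseless default crystal volume and ground-truth table."""
    from crystomo.synthetic import build_crystal_volume

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vol, table = build_crystal_volume(
            default_config.crystal, default_config.phantom,
            box=tuple(default_config.tomogram["box"]),
            voxel_size=default_config.tomogram["voxel_size"],
        )
    return vol, table


@pytest.fixture(scope="session")
def phantom_volume(default_config):
    from crystomo.synthetic import build_phantom

    return build_phantom(default_config.phantom, 6.66, box=48)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory, default_config):
    """One full pipeline run at the packaged study conditions (seed 7).

    Session-scoped: the acceptance-style checks all read from this run.
    """
    from crystomo.pipeline import run_pipeline

    outdir = tmp_path_factory.mktemp("default_run")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = run_pipeline(default_config, outdir, seed=7)
    return results, outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
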