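import numpy as np
import pytest

from mscurate.pipeline import run_curation
from mscurate.synth import (
    AcquisitionGrid,
    SynthCompound,
    SynthParams,
    compound_metadata,
    generate_run,
)


@pytest.fixture(scope="session")
def default_run():
    """The default synthetic benchmark: full 36-type grid, three compounds
    with chimeric interference and chemical background."""
    params = SynthParams(seed=1)
    scans, truth = generate_run(params)
    return params, scans, truth


@pytest.fixture(scope="session")
def default_curation(default_run):
    """The default benchmark processed end-to-end once per session."""
    params, scans, truth = default_run
    result = run_curation(scans, compound_metadata(params))
    return params, scans, truth, result


def small_params(seed: int = 5, **kwargs) -> SynthParams:
    """A reduced acquisition (3 NCEs, 12 types) for fast unit tests."""
    defaults = dict(
        seed=seed,
        compounds=[
            SynthCompound("SML-001", "smallphycin", "C38H54O8", rt=3.0,
                          interference_formula="C21H17BrCl2N2O12"),
        ],
        grid=AcquisitionGrid(nce_list=(20.0, 40.0, 60.0), n_replicates=6),
    )
    defaults.update(kwargs)
    return SynthParams(**defaults)


@pytest.fixture(scope="session")
def small_run():
    params = small_params()
    scans, truth = generate_run(params)
    return params, scans, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
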