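import numpy as np
import pytest

from cladelink.occurrences import DetectionMatrix
from cladelink.stages import StageTable


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_stages():
    """Four contiguous 2-Myr stages, 8-0 Ma."""
    return StageTable(
        names=("s1", "s2", "s3", "s4"),
        older=(8.0, 6.0, 4.0, 2.0),
        younger=(6.0, 4.0, 2.0, 0.0),
    )


def make_matrix(data, clade="cheilostome", stage_names=None):
    data = np.asarray(data)
    if stage_names is None:
        stage_names = tuple(f"s{i + 1}" for i in range(data.shape[1]))
    return DetectionMatrix(
        genera=tuple(f"g{i}" for i in range(data.shape[0])),
        data=data,
        clade=clade,
        stage_names=stage_names,
    )


@pytest.fixture
def matrix_factory():
    return make_matrix
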