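import numpy as np
import pandas as pd
import pytest

from bovarch.core import MISSING, GenotypeMatrix, marker_map


def make_panel(dosages, positions=None, chroms=None, breeds=None):
    """Build a GenotypeMatrix from a plain dosage array."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100_000
    if chroms is None:
        chroms = ["1"] * m
    mk = marker_map([f"m{j}" for j in range(m)], chroms, positions, sort=False)
    if breeds is None:
        breeds = ["POP"] * n
    samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)], "breed": breeds})
    return GenotypeMatrix(samples=samples, markers=mk, dosages=d)


@pytest.fixture
def toy_panel():
    # 4 samples x 3 markers with one missing call and one monomorphic marker
    return make_panel(
        [
            [0, 0, 2],
            [1, 0, 2],
            [2, 0, MISSING],
            [1, 0, 0],
        ]
    )
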