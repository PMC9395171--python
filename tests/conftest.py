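import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from regcascade.dge import CONTROL, TREATED, CountMatrix
from regcascade.synthdata import SimulationConfig, simulate_bundle

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_count_matrix(arr, n_control=None) -> CountMatrix:
    """Wrap an array (genes x samples) into a CountMatrix, first half control."""
    arr = np.asarray(arr)
    n = arr.shape[1]
    n_control = n // 2 if n_control is None else n_control
    samples = [f"c{i}" for i in range(n_control)] + [
        f"t{i}" for i in range(n - n_control)
    ]
    counts = pd.DataFrame(arr, columns=samples, index=[f"g{i:04d}" for i in range(arr.shape[0])])
    groups = pd.Series(
        [CONTROL] * n_control + [TREATED] * (n - n_control), index=samples
    )
    return CountMatrix(counts=counts, groups=groups)


@pytest.fixture(scope="session")
def small_bundle():
    """A modest default-condition bundle reused by read-only tests."""
    cfg = SimulationConfig(
        n_genes=800, n_tfs=60, n_causal_tfs=3, n_silenced_genes=10, seed=11
    )
    return simulate_bundle(cfg)
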