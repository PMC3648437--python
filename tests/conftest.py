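import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from seroarray import gen_array_dataset, gen_elisa

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

TINY_GPR = """Type=seroarray GPR subset 1.0
SampleID=demo
Wavelength=635
Block\tColumn\tRow\tName\tID\tF635 Median\tB635 Median
1\t1\t1\tGENE1\tF1\t100\t10
1\t2\t1\tGENE2\tF2\t200\t20
1\t3\t1\tGENE3\tF3\t300\t30
"""


@pytest.fixture
def tiny_gpr(tmp_path):
    path = tmp_path / "demo.gpr"
    path.write_text(TINY_GPR)
    return path


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced-size array experiment with known injected reactivities."""
    return gen_array_dataset(
        n_features=600, n_elevated=30, n_control_spots=60, seed=7
    )


@pytest.fixture(scope="session")
def default_dataset():
    """Full-size (8268-feature, 10 vs 10) experiment at default conditions."""
    return gen_array_dataset(seed=1)


@pytest.fixture(scope="session")
def elisa_panel():
    return gen_elisa(seed=3)


@pytest.fixture
def toy_experiment():
    """3 control spots + 3 features on 2 arrays; the second array is 4x the first."""
    from seroarray import ExperimentSet

    features = pd.DataFrame(
        {
            "gene_symbol": ["CTRL", "CTRL", "CTRL", "A", "B", "C"],
            "is_control": [True, True, True, False, False, False],
        },
        index=pd.Index(
            ["CTRL_1", "CTRL_2", "CTRL_3", "F1", "F2", "F3"], name="feature_id"
        ),
    )
    samples = pd.DataFrame(
        {"group": ["case", "control"], "timepoint": "na"},
        index=pd.Index(["s1", "s2"], name="sample_id"),
    )
    col1 = np.array([100.0, 200.0, 400.0, 150.0, 300.0, 50.0])
    matrix = pd.DataFrame(
        {"s1": col1, "s2": 4.0 * col1}, index=features.index
    )
    return ExperimentSet(features=features, samples=samples, net_signal=matrix)
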