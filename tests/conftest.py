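import numpy as np
import pandas as pd
import pytest

from lfqde import AnalysisConfig, IntensityMatrix


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def design6():
    return {
        "c1": "control", "c2": "control", "c3": "control",
        "t1": "treated", "t2": "treated", "t3": "treated",
    }


@pytest.fixture
def small_matrix(design6):
    """3 proteins x 6 samples, complete."""
    data = pd.DataFrame(
        np.arange(18, dtype=float).reshape(3, 6) + 10.0,
        index=["P1", "P2", "P3"],
        columns=list(design6),
    )
    return IntensityMatrix(data=data, design=design6)


@pytest.fixture
def random_matrix(design6):
    """50 proteins x 6 samples with scattered missing cells, seeded."""
    rng = np.random.default_rng(42)
    values = rng.normal(20.0, 2.0, (50, 6))
    mask = rng.random((50, 6)) < 0.15
    values[mask] = np.nan
    data = pd.DataFrame(values, index=[f"P{i}" for i in range(50)], columns=list(design6))
    return IntensityMatrix(data=data, design=design6)


def write_tsv(path, text):
    path.write_text(text)
    return str(path)
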