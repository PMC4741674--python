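import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from glycotype import ProfileMatrix, SignalModel, simulate_profiles


@pytest.fixture
def tiny_profiles() -> ProfileMatrix:
    """Three hand-written samples over two components, both isotypes."""
    columns = pd.MultiIndex.from_product(
        [["BG-A3-Oct-14", "BG-B3-Oct-17"], ["IgG", "IgM"]],
        names=["component", "isotype"],
    )
    data = pd.DataFrame(
        [
            [7.0, 7.5, 12.0, 11.0],  # type A: anti-B only
            [12.5, 11.5, 6.5, 7.2],  # type B: anti-A only
            [12.0, 11.8, 12.3, 10.9],  # type O: both
        ],
        index=["s1", "s2", "s3"],
        columns=columns,
    )
    metadata = pd.DataFrame(
        {"recorded_blood_type": ["A", "B", "O"]}, index=data.index
    )
    return ProfileMatrix(data, metadata)


@pytest.fixture
def clean_training_set():
    """A low-noise n=60 synthetic training set with truth labels."""
    model = SignalModel(sigma=0.3)
    return simulate_profiles(60, model=model, seed=42)
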