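import numpy as np
import pandas as pd
import pytest

from spatialqg.pedigree import PedigreeTable


@pytest.fixture
def trio_frame() -> pd.DataFrame:
    """Two founders and one offspring."""
    return pd.DataFrame(
        {
            "individual": ["O", "F1", "F2"],
            "dam": ["F1", "", ""],
            "sire": ["F2", "", ""],
        }
    )


@pytest.fixture
def nuclear_family() -> PedigreeTable:
    """Two founders, two full-sib offspring, one inbred grandchild."""
    return PedigreeTable.from_frame(
        pd.DataFrame(
            {
                "individual": ["F1", "F2", "S1", "S2", "I1"],
                "dam": [None, None, "F1", "F1", "S1"],
                "sire": [None, None, "F2", "F2", "S2"],
            }
        )
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
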