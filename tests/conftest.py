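import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from mirmet.qpcr import CqMatrix


@pytest.fixture
def small_cq() -> CqMatrix:
    """3 miRNAs + U6 across 4 samples, one undetected well."""
    values = pd.DataFrame(
        {
            "s1": [25.0, 30.0, np.nan, 20.0],
            "s2": [26.0, 31.0, 35.0, 20.5],
            "s3": [24.0, 29.0, 34.0, 19.5],
            "s4": [25.5, 30.5, 36.0, 20.0],
        },
        index=["miR-a", "miR-b", "miR-c", "U6"],
    )
    return CqMatrix(values, values.notna(), "U6")


@pytest.fixture
def small_metadata() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "group": ["BM", "BM", "primary", "primary"],
            "set": ["discovery"] * 4,
            "pair_id": [""] * 4,
            "mycn": ["amplified", "not_amplified", "amplified", "not_amplified"],
        }
    ).set_index("sample_id")
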