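import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from rvbayes.io import SampleFrame


@pytest.fixture
def schema_sample() -> SampleFrame:
    """The case:control composition of the schizophrenia exome cohort."""
    return SampleFrame(24248, 97322)


@pytest.fixture
def toy_variants() -> pd.DataFrame:
    """Small well-formed variant table spanning both classes."""
    return pd.DataFrame(
        {
            "gene": ["GENEA", "GENEA", "GENEB", "GENEC", "GENEC"],
            "variant": ["v1", "v2", "v3", "v4", "v5"],
            "annotation": ["PTV", "missense", "missense", "PTV", "missense"],
            "mpc": [float("nan"), 3.4, 2.5, float("nan"), 1.2],
            "ac_case": [2, 1, 0, 3, 1],
            "ac_control": [1, 2, 3, 0, 1],
        }
    )


@pytest.fixture
def write_tsv(tmp_path):
    def _write(df: pd.DataFrame, name: str = "table.tsv") -> Path:
        p = tmp_path / name
        df.to_csv(p, sep="\t", index=False, na_rep="NA")
        return p

    return _write
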