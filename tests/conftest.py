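import numpy as np
import pandas as pd
import pytest

from lncprog.simulate import SyntheticConfig, generate_dataset


@pytest.fixture
def tiny_matrix():
    """2 genes × 4 samples with easily checked arithmetic."""
    return pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [5.0, 7.0, 1.0, 3.0]],
        index=["g1", "g2"],
        columns=["sA", "sB", "sC", "sD"],
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Scaled-down synthetic bundle shared by slower tests."""
    config = SyntheticConfig(
        seed=20240901,
        n_coding=150,
        n_lnc=30,
        n_decoy_terms=10,
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def default_dataset():
    """Full default-condition synthetic bundle (170 tumor samples)."""
    return generate_dataset(SyntheticConfig(seed=20240902))


def make_sheet(groups: dict[str, int], prefix: str = "S") -> pd.DataFrame:
    rows = []
    i = 0
    for group, count in groups.items():
        for _ in range(count):
            i += 1
            rows.append({"sample_id": f"{prefix}{i:03d}", "group": group})
    sheet = pd.DataFrame(rows)
    for col in ("subtype", "endpoint"):
        sheet[col] = "unknown"
    for col in ("time", "event", "age", "ipi", "gender"):
        sheet[col] = np.nan
    return sheet.set_index("sample_id", drop=False)
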