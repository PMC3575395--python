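from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from autocmap import MARKERS, PHENOTYPES


def make_marker_table(
    n_per_group: int = 3, seed: int = 0, groups=PHENOTYPES
) -> pd.DataFrame:
    """A small random but valid raw marker table."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in groups:
        for k in range(n_per_group):
            row = {"subject_id": f"{g}-{k:02d}", "phenotype": g}
            for m in MARKERS:
                row[m] = float(rng.uniform(0.1, 60.0))
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def marker_table() -> pd.DataFrame:
    return make_marker_table()
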