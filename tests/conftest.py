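import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from promid import fixture_small

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from promid.instruments import BASELINE, InstrumentSpec, ItemResponseMatrix


@pytest.fixture(scope="session")
def small_cohort():
    return fixture_small()


def make_matrix(rows, spec=None, timepoint=BASELINE, ids=None):
    """Build an ItemResponseMatrix from a list of row lists (None = missing)."""
    rows = [[np.nan if v is None else v for v in r] for r in rows]
    if spec is None:
        n_items = len(rows[0])
        spec = InstrumentSpec("adhoc", "ad hoc", n_items, 0, 5)
    if ids is None:
        ids = [f"P{i:02d}" for i in range(1, len(rows) + 1)]
    data = pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"),
                        columns=spec.item_columns())
    return ItemResponseMatrix(spec, timepoint, data)
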