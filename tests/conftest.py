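import pandas as pd
import pytest

from hedkit.core import HealthTable, MISSING


def make_table(columns: dict, ids: list | None = None) -> HealthTable:
    """Build a HealthTable from {variable: values}; use hedkit MISSING for NA."""
    n = len(next(iter(columns.values())))
    ids = ids or [f"p{i + 1}" for i in range(n)]
    frame = pd.DataFrame(columns, index=pd.Index(ids, name="id"), dtype=object)
    return HealthTable(frame, id_name="id")


@pytest.fixture
def simple_table():
    return make_table({
        "age": ["64", "71", MISSING, "58"],
        "stage": ["N0", "N1", "N2", "N1"],
        "smoker": ["yes", "no", "no", MISSING],
    })
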