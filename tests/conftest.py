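import numpy as np
import pandas as pd
import pytest

from immunohub.events import EventTable


def make_event_table(
    marker_values: dict,
    donor: str = "D1",
    arm: str = "CAR",
    timepoint: str = "day11",
    transformed: bool = True,
    extra: dict | None = None,
) -> EventTable:
    """Build a small in-memory event table from {marker: values} arrays."""
    n = len(next(iter(marker_values.values())))
    data = pd.DataFrame(
        {"donor": donor, "arm": arm, "timepoint": timepoint, "panel": "p1"},
        index=range(n),
    )
    for marker, values in marker_values.items():
        data[marker] = np.asarray(values, dtype=float)
    for col, values in (extra or {}).items():
        data[col] = values
    return EventTable(data, tuple(marker_values), transformed=transformed)


@pytest.fixture(scope="session")
def hub_fixture():
    """Packaged synthetic hub-gene study (counts, sample sheet, PPI, sets, truth)."""
    from immunohub.pipelines import fixture_hub_inputs

    return fixture_hub_inputs(seed=11)


@pytest.fixture(scope="session")
def immuno_fixture():
    """Small synthetic cytometry cohort for pipeline-level tests."""
    from immunohub.pipelines import fixture_immuno_inputs

    return fixture_immuno_inputs(seed=11, cells_per_sample=1500)
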