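import math

import numpy as np
import pandas as pd
import pytest

from iqrray import ArrayIntensities, ChipLayout, ControlPair


def build_layout(rows, control_pairs=(), platform_id="toy", n_rows=0, n_cols=0):
    """Build a ChipLayout from (probe_id, x, y, probe_set_id, is_pm,
    partner_probe_id, position_index) tuples."""
    probes = pd.DataFrame(
        rows,
        columns=[
            "probe_id",
            "x",
            "y",
            "probe_set_id",
            "is_pm",
            "partner_probe_id",
            "position_index",
        ],
    )
    probes["position_index"] = probes["position_index"].astype(float)
    return ChipLayout(
        platform_id=platform_id,
        probes=probes,
        control_pairs=list(control_pairs),
        n_rows=n_rows,
        n_cols=n_cols,
    )


@pytest.fixture
def toy_layout():
    """Four PM probes in two probe sets A = {p1, p2}, B = {p3, p4}."""
    return build_layout(
        [
            ("p1", 0, 0, "A", True, None, math.nan),
            ("p2", 1, 0, "A", True, None, math.nan),
            ("p3", 0, 1, "B", True, None, math.nan),
            ("p4", 1, 1, "B", True, None, math.nan),
        ]
    )


def toy_array(layout, values, array_id="arr1"):
    return ArrayIntensities(
        array_id, layout.platform_id, layout.probe_ids, np.asarray(values, float)
    )


@pytest.fixture
def paired_layout():
    """Three PM/MM pairs in one probe set."""
    rows = []
    for j in range(3):
        rows.append((f"pm{j}", j, 0, "S", True, f"mm{j}", float(j)))
        rows.append((f"mm{j}", j, 1, "S", False, f"pm{j}", float(j)))
    return build_layout(rows)


TOY_LAYOUT_TSV = (
    "probe_id\tx\ty\tprobe_set_id\tis_pm\tpartner_probe_id\tposition_index\n"
    "p1\t0\t0\tA\t1\t\t\n"
    "p2\t1\t0\tA\t1\t\t\n"
    "p3\t0\t1\tB\t1\t\t\n"
    "p4\t1\t1\tB\t1\t\t\n"
)
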