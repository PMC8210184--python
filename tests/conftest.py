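import numpy as np
import pandas as pd
import pytest

from prcdeconv import (
    IntensityMatrix,
    default_config,
    simulate_interactome,
)


@pytest.fixture(scope="session")
def default_sim():
    """Default 500-protein synthetic screen at a fixed seed."""
    cfg = default_config(seed=1)
    matrix, truth = simulate_interactome(cfg)
    return cfg, matrix, truth


def make_matrix(values: dict, meta_rows: list) -> IntensityMatrix:
    """Build a small IntensityMatrix from a {protein: {sample: value}} dict.

    ``meta_rows`` is a list of (sample_id, cell_line, bait, condition,
    culture, tech_rep, is_mock) tuples; absent values become NaN.
    """
    meta = pd.DataFrame(
        meta_rows,
        columns=[
            "sample_id",
            "cell_line",
            "bait",
            "condition",
            "culture",
            "tech_rep",
            "is_mock",
        ],
    ).set_index("sample_id")
    frame = pd.DataFrame(
        {
            sid: {p: values.get(p, {}).get(sid, np.nan) for p in values}
            for sid in meta.index
        },
        dtype=float,
    )
    frame.index.name = "protein_id"
    return IntensityMatrix(values=frame, samples=meta)


@pytest.fixture
def four_run_matrix():
    """One bait, one line, 4 IP runs + 2 mock runs; hand-set detections."""
    meta = []
    for c in (1, 2):
        for r in (1, 2):
            meta.append((f"ip.c{c}.r{r}", "L1", "BMI1", "control", c, r, 0))
    meta.append(("mock.c1.r1", "L1", "mock", "control", 1, 1, 1))
    meta.append(("mock.c2.r1", "L1", "mock", "control", 2, 1, 1))
    ip = [m[0] for m in meta[:4]]
    values = {
        "P_ALL": {s: 100.0 for s in ip},           # 4/4 runs
        "P_ONE": {ip[0]: 100.0},                   # 1/4 runs
        "P_TWO": {ip[0]: 100.0, ip[3]: 50.0},      # 2/4 runs
        "P_MOCKY": {**{s: 80.0 for s in ip}, "mock.c1.r1": 10.0},
        "P_NONE": {},
    }
    return make_matrix(values, meta)
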