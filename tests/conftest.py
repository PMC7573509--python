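import io

import numpy as np
import pandas as pd
import pytest

from cuspshift import PanelDataset, SimConfig, VariableRoles


@pytest.fixture
def toy_csv():
    return io.StringIO(
        "subject_id,distress_t1,distress_t2,distress_t3,cse_t1,loss_t1,gender,time_since\n"
        "a,0.5,0.7,0.9,5.0,1.0,1,60\n"
        "b,1.5,1.2,,4.0,0.5,0,55\n"
        "c,2.5,2.0,2.2,3.0,2.0,1,70\n"
    )


@pytest.fixture
def toy_roles():
    return VariableRoles(
        state="distress",
        bifurcation="cse_t1",
        asymmetry=("loss_t1",),
        wave_pair=("T1", "T3"),
    )


def random_panel(rng: np.random.Generator, n: int = 40) -> PanelDataset:
    """Small in-range panel with a few missing cells, for round-trip tests."""
    data = pd.DataFrame(
        {
            "distress_t1": rng.uniform(0, 4, n),
            "distress_t2": rng.uniform(0, 4, n),
            "distress_t3": rng.uniform(0, 4, n),
            "cse_t1": rng.uniform(1, 7, n),
            "loss_t1": rng.uniform(0, 4, n),
            "gender": rng.integers(0, 2, n).astype(float),
            "time_since": rng.uniform(40, 90, n),
        },
        index=pd.Index([f"s{i}" for i in range(n)], name="subject_id"),
    )
    holes = rng.random(data.shape) < 0.05
    data = data.mask(holes)
    return PanelDataset(data, ("T1", "T2", "T3"))


@pytest.fixture
def study1_small():
    """Clean (no missingness/attrition) study1 config at modest n."""
    return SimConfig.from_profile(
        "study1", n_subjects=400, missing_rates=(0, 0, 0), attrition_rates=(0, 0)
    )
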