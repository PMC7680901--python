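import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import sigrev

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def toy_study():
    """Three genes, 3 vs 3 samples; gene g1 is the hand-computed worked case."""
    values = pd.DataFrame(
        {
            "c1": [1.0, 5.0, 2.0], "c2": [2.0, 5.0, 2.0], "c3": [3.0, 5.0, 2.0],
            "t1": [3.0, 5.0, 2.0], "t2": [4.0, 5.0, 2.0], "t3": [5.0, 5.0, 2.0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene"),
    )
    groups = pd.Series(
        ["control"] * 3 + ["case"] * 3,
        index=["c1", "c2", "c3", "t1", "t2", "t3"],
    )
    return sigrev.ExpressionStudy(values=values, groups=groups, species="human")


def make_deg_list(entries, alpha=0.05):
    """entries: iterable of (gene, logfc) or (gene, logfc, p)."""
    rows = [(e[0], e[1], e[2] if len(e) > 2 else 0.01) for e in entries]
    table = pd.DataFrame(
        {"logfc": [r[1] for r in rows], "p": [r[2] for r in rows],
         "direction": ["up" if r[1] > 0 else "down" for r in rows]},
        index=pd.Index([r[0] for r in rows], name="gene"),
    )
    return sigrev.DEGList(table=table, alpha=alpha)


@pytest.fixture
def small_sim_config():
    return sigrev.SimulationConfig(
        n_genes=400, n_case=8, n_control=8, n_perturbagens=12,
        instances_per_perturbagen=3, n_reversers=2, n_mimickers=1, seed=7,
    )
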