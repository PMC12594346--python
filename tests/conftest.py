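import numpy as np
import pandas as pd
import pytest

from coremir.engines_io import (
    CandidatePool,
    EngineTable,
    ExpressionDataset,
    build_candidate_pool,
)
from coremir import synthetic


@pytest.fixture
def toy_panel():
    """Four small engines over a shared universe with varied overlaps."""
    def pairs(*idx):
        return frozenset((f"hsa-miR-{i:03d}", f"G{j}") for i, j in idx)

    return [
        EngineTable("targetscan", pairs((1, 1), (1, 2), (2, 1), (2, 3), (3, 2))),
        EngineTable("diana", pairs((1, 1), (1, 2), (2, 1), (3, 3))),
        EngineTable("mirtarbase", pairs((1, 1), (2, 1), (2, 3), (3, 2))),
        EngineTable("tarbase", pairs((1, 1), (1, 2), (2, 3), (3, 3))),
    ]


@pytest.fixture
def toy_dataset():
    """Expression matrix covering all molecules of the toy panel."""
    rng = np.random.default_rng(11)
    mirnas = [f"hsa-miR-{i:03d}" for i in (1, 2, 3)]
    genes = [f"G{j}" for j in (1, 2, 3)]
    cols = mirnas + genes
    matrix = pd.DataFrame(
        rng.normal(5, 1, size=(40, 6)), columns=cols,
        index=[f"S{i}" for i in range(40)],
    )
    roles = pd.Series(["mirna"] * 3 + ["mrna"] * 3, index=cols)
    classes = np.tile([0, 1], 20)
    return ExpressionDataset(matrix=matrix, feature_roles=roles, class_vector=classes)


@pytest.fixture
def toy_pool(toy_dataset, toy_panel) -> CandidatePool:
    return build_candidate_pool(toy_dataset, toy_panel)


@pytest.fixture(scope="session")
def informative_study():
    """One synthetic study with planted signal, shared across tests."""
    spec = synthetic.make_spec(n_per_class=150, seed=42)
    panel, annotation = synthetic.make_panel(spec)
    data = synthetic.sample_expression(spec)
    return spec, panel, annotation, data
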