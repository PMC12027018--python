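import numpy as np
import pandas as pd
import pytest

from solatlas import ExpressionMatrix, OrganProfile
from solatlas.synthetic import SimulationConfig, simulate_atlas


def make_expression(values: dict[str, list[float]], genes: list[str],
                    organs: dict[str, str], stages: dict[str, str] | None = None,
                    ) -> ExpressionMatrix:
    """Small-matrix helper: values maps sample id -> per-gene column."""
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                         dtype=float)
    stages = stages or {}
    meta = pd.DataFrame(
        {
            "organ": {s: organs[s] for s in frame.columns},
            "stage": {s: stages.get(s, "") for s in frame.columns},
            "replicate": {s: 1 for s in frame.columns},
        }
    )
    meta.index.name = "sample_id"
    return ExpressionMatrix(frame, meta)


def make_profile(rows: dict[str, list[float]],
                 organs=("root", "stem", "leaf", "flower/fruit")) -> OrganProfile:
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(organs))
    frame.index.name = "gene_id"
    return OrganProfile(frame.astype(float))


@pytest.fixture(scope="session")
def default_atlas():
    """Reference two-species atlas under the default study conditions."""
    return simulate_atlas(SimulationConfig(seed=20240915))


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)
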