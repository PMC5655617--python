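import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from critfact.detection import make_regulatory_network
from critfact.synthetic import SimulationConfig
from critfact.transcriptome import FoldChangeVector

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def five_gene_fc() -> FoldChangeVector:
    """The hand-checkable five-gene universe with fold changes 1..5."""
    return FoldChangeVector(
        "b_vs_a",
        pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=["g1", "g2", "g3", "g4", "g5"]),
    )


@pytest.fixture
def five_gene_network():
    return make_regulatory_network({"TF_hi": ["g4", "g5"], "TF_lo": ["g1", "g2"]})


@pytest.fixture
def small_config() -> SimulationConfig:
    """A fast, fully planted study: 50 TFs, 600 genes, 4 + 4 planted."""
    return SimulationConfig(
        n_tfs=50,
        n_genes=600,
        targets_per_tf=(10, 15),
        n_activators=4,
        n_repressors=4,
        n_final_tfs=3,
        n_coactivators=8,
        n_compounds=5,
        seed=11,
    )
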