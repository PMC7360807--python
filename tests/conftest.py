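import numpy as np
import pandas as pd
import pytest

from triadshift import ExpressionMatrix, GeneratorConfig, TriadMap


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """Six genes, two conditions x three replicates, hand-set values."""
    values = pd.DataFrame(
        {
            "hex_1": [10.0, 0.0, 12.0, 30.0, 0.0, 5.0],
            "hex_2": [10.0, 0.0, 12.0, 30.0, 0.1, 6.0],
            "hex_3": [10.0, 0.0, 12.0, 30.0, 0.2, 7.0],
            "non_1": [40.0, 5.0, 12.0, 10.0, 0.0, 5.0],
            "non_2": [40.0, 6.0, 12.0, 10.0, 0.0, 6.0],
            "non_3": [40.0, 7.0, 12.0, 10.0, 0.3, 7.0],
        },
        index=pd.Index(["g1", "g2", "g3", "g4", "g5", "g6"], name="gene_id"),
    )
    design = pd.DataFrame(
        {
            "condition": ["hexaploid"] * 3 + ["nonaploid"] * 3,
            "replicate": [1, 2, 3, 1, 2, 3],
        },
        index=pd.Index(values.columns, name="sample_id"),
    )
    return ExpressionMatrix(values=values, design=design)


@pytest.fixture
def toy_triads() -> TriadMap:
    return TriadMap(
        pd.DataFrame(
            {
                "triad_id": ["tr1", "tr2"],
                "gene_A": ["g1", "g4"],
                "gene_B": ["g2", "g5"],
                "gene_D": ["g3", "g6"],
                "syntenic": [True, True],
            }
        )
    )


@pytest.fixture
def small_config():
    """Factory for quick generator configs; override any field per test."""

    def make(**overrides) -> GeneratorConfig:
        base = dict(
            n_triads=200,
            n_singletons=400,
            n_activated=8,
            n_silenced=4,
            deg_fraction=0.05,
            n_go_terms=30,
            seed=0,
        )
        base.update(overrides)
        return GeneratorConfig(**base)

    return make
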