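import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from redcmicro.synthetic_data import (  # noqa: E402
    SimulationConfig,
    simulate_annotation,
    simulate_contacts,
    simulate_expression,
)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small, fast replicon for pipeline round-trip tests."""
    return SimulationConfig(
        seed=7, L=300_000, n_operons=40, n_contacts=5_000,
        error_rate=0.0, artifact_fraction=0.0,
    )


@pytest.fixture(scope="session")
def tiny_sim(tiny_cfg):
    genome, genes, operons = simulate_annotation(tiny_cfg)
    expression = simulate_expression(tiny_cfg, operons, genes)
    truth = simulate_contacts(tiny_cfg, genome, genes, operons, expression)
    return genome, genes, operons, expression, truth


@pytest.fixture(scope="session")
def study_cfg():
    """Study-scale conditions: 2.4 Mb circle, 300 operons, 1e5 contacts."""
    return SimulationConfig(seed=3, L=2_400_000, n_operons=300, n_contacts=100_000)


@pytest.fixture(scope="session")
def study_sim(study_cfg):
    genome, genes, operons = simulate_annotation(study_cfg)
    expression = simulate_expression(study_cfg, operons, genes)
    truth = simulate_contacts(study_cfg, genome, genes, operons, expression)
    return genome, genes, operons, expression, truth


def make_contacts(rna3_pos, dna_pos, rna3_strand="-", gene_id=None, rna_class=None,
                  dna_strand="+"):
    """Hand-built contact table with broadcastable columns."""
    n = len(np.atleast_1d(rna3_pos))

    def col(v):
        a = np.atleast_1d(v)
        return np.repeat(a, n) if a.size == 1 else a

    df = pd.DataFrame(
        {
            "rna3_pos": col(rna3_pos),
            "rna3_strand": col(rna3_strand),
            "dna_pos": col(dna_pos),
            "dna_strand": col(dna_strand),
        }
    )
    if gene_id is not None:
        df["gene_id"] = col(gene_id)
    if rna_class is not None:
        df["rna_class"] = col(rna_class)
    return df
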