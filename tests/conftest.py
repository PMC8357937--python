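import numpy as np
import pytest

from marinerscan import (
    CopyPlan,
    GenomePlan,
    PipelineParams,
    PlantConfig,
    build_panel,
    plant_copies,
)
from marinerscan.synthetic_data import build_consensi


def small_config(seed: int = 7) -> PlantConfig:
    """A desk-size two-genome benchmark exercising every copy class."""
    copies_a = [
        CopyPlan(subfamily="Mauritiana", activity="intact", divergence=0.02),
        CopyPlan(subfamily="Drosophila", activity="decayed", n_premature_stops=1),
        CopyPlan(subfamily="Vertumana", activity="decayed", n_premature_stops=2,
                 triad_mutation=True),
        CopyPlan(subfamily="Irritans", activity="decayed", n_premature_stops=1,
                 tsd="3p_only"),
        CopyPlan(subfamily="Drosophila", completeness="truncated_5p",
                 activity="intact", divergence=0.02, at_contig_end=True),
    ]
    copies_b = [
        CopyPlan(subfamily="Mauritiana", activity="decayed", n_premature_stops=1),
        CopyPlan(subfamily="Vertumana", completeness="truncated_3p",
                 activity="decayed", n_premature_stops=1, at_contig_end=True),
        CopyPlan(subfamily="Drosophila", activity="intact", divergence=0.02),
    ]
    genomes = [
        GenomePlan(species="genomeA", prefix="gA", copies=copies_a,
                   n_large_contigs=1, large_contig_len=60_000,
                   n_small_contigs=8),
        GenomePlan(species="genomeB", prefix="gB", copies=copies_b,
                   n_large_contigs=1, large_contig_len=40_000,
                   n_small_contigs=8),
    ]
    return PlantConfig(genomes=genomes, seed=seed)


@pytest.fixture(scope="session")
def small_sim():
    cfg = small_config()
    genomes, truth = plant_copies(cfg)
    panel = build_panel(cfg)
    return cfg, genomes, truth, panel


@pytest.fixture(scope="session")
def small_params():
    p = PipelineParams()
    p.classify.n_bootstrap = 50
    return p


@pytest.fixture(scope="session")
def consensi():
    return build_consensi(PlantConfig(genomes=[], seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
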