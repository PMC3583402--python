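import pandas as pd
import pytest

from mitotx import SimulationParams, make_toy_genome


@pytest.fixture(scope="session")
def toy_convergent():
    """3-kb circle: one promoter per strand, a polarized terminator between
    them, genes on both strands upstream and downstream of the terminator."""
    return make_toy_genome(
        3000,
        promoter_specs=[("PH", 100, "heavy"), ("PL", 2900, "light")],
        gene_specs=[("GH1", 200, 800, "heavy"), ("GH2", 1600, 2200, "heavy"),
                    ("GL1", 2300, 2800, "light"), ("GL2", 600, 1100, "light")],
        factor_specs=[("TERM", 1500, 28, 0.3, 0.05, 0.5)])


@pytest.fixture(scope="session")
def toy_params():
    return SimulationParams(
        promoter_intensities={"PH": 0.02, "PL": 0.01},
        factor_intensities={"TERM": 0.5},
        p=0.3, q=0.05, elongation_rate=200.0, t_end=1800.0)


@pytest.fixture(scope="session")
def single_promoter_genome():
    """2-kb circle, one heavy promoter, one downstream gene, no obstacles."""
    return make_toy_genome(
        2000,
        promoter_specs=[("P", 50, "heavy")],
        gene_specs=[("G", 70, 570, "heavy")])


@pytest.fixture
def rat_tables():
    from mitotx.compare import ExperimentTable
    from mitotx.fixtures import rat_experiment_frame
    frame = rat_experiment_frame()
    eu = ExperimentTable.from_long_frame(frame, "euthyroid", "16S")
    hy = ExperimentTable.from_long_frame(frame, "hypothyroid", "16S")
    return eu, hy
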