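import numpy as np
import pandas as pd
import pytest

from meddx.containers import LpnPISiteIndex, SiteCountMatrix
from meddx.synthetic import (
    SimulationDesign,
    choose_planted_dmrs,
    generate_genome,
    simulate_site_counts,
)


@pytest.fixture(scope="session")
def toy_genome():
    """One 200 kb chromosome with genes, islands and LpnPI sites."""
    return generate_genome(
        n_chroms=1, chrom_length=200_000, gene_density=30, island_density=8, seed=11
    )


@pytest.fixture(scope="session")
def planted_sim(toy_genome):
    """Tumor/control tissue simulation with 6 planted fold-4 hyper DMRs."""
    annotation, index = toy_genome
    planted = choose_planted_dmrs(index, n_dmrs=6, sites_per_dmr=8, fold_change=4.0, seed=12)
    design = SimulationDesign(n_per_group=10, planted_dmrs=planted, seed=13)
    matrices = simulate_site_counts(annotation, index, design)
    return annotation, index, planted, matrices


def single_site_matrices(x1, n1, x2, n2):
    """Two one-sample matrices realizing a 2x2 pooled count table."""
    idx = LpnPISiteIndex({"chr1": np.array([100])})
    case = SiteCountMatrix(
        idx, pd.DataFrame({"a": [x1]}, index=idx.labels()), pd.Series({"a": float(n1)})
    )
    control = SiteCountMatrix(
        idx, pd.DataFrame({"b": [x2]}, index=idx.labels()), pd.Series({"b": float(n2)})
    )
    return case, control
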