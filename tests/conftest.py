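import numpy as np
import pandas as pd
import pytest

from pitanga.io_formats import PipelineConfig
from pitanga.synthetic_data import SimParams


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def small_sim_params():
    """Desk-scale simulation: one small genome, few genes."""
    return SimParams(genome_length=60_000, n_chromosomes=2,
                     ssr_rate=30 / 60_000, n_genes=24,
                     n_ssr_adjacent_genes=8, n_blocks=3, block_size=8)


@pytest.fixture
def toy_counts():
    """2 populations x 2 conditions x 3 replicates, 30 genes, fixed seed."""
    rng = np.random.default_rng(42)
    samples = [f"{pop}_{cond}_{rep}" for pop in ("RE", "RF")
               for cond in ("control", "drought") for rep in (1, 2, 3)]
    sheet = pd.DataFrame(
        [{"population": s.split("_")[0], "condition": s.split("_")[1],
          "replicate": int(s.split("_")[2])} for s in samples],
        index=pd.Index(samples, name="sample"))
    mu = rng.lognormal(np.log(200), 0.5, size=30)
    counts = pd.DataFrame(
        rng.poisson(mu[:, None], size=(30, 12)),
        index=pd.Index([f"g{i:03d}" for i in range(30)], name="gene_id"),
        columns=samples)
    return counts, sheet
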