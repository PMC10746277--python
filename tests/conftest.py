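import numpy as np
import pandas as pd
import pytest

from aeroscreen.simulate import SimConfig, build_library, simulate_genome


@pytest.fixture(scope="session")
def small_genome():
    """A 10-gene genome with TU structure, plus its designed library."""
    cfg = SimConfig(
        n_genes=10,
        genes_per_tu_dist={1: 0.5, 2: 0.5},
        n_controls=100,
        seed=7,
    )
    rng = np.random.default_rng(cfg.seed)
    annotation, tu_table, genome = simulate_genome(cfg, rng)
    library = build_library(genome, annotation, cfg, rng)
    return dict(
        config=cfg,
        annotation=annotation,
        tu_table=tu_table,
        genome=genome,
        library=library,
    )


@pytest.fixture
def toy_library():
    """Four targeting spacers over two genes plus two controls."""
    rng = np.random.default_rng(11)
    bases = np.array(list("ACGT"))
    seqs = ["".join(rng.choice(bases, size=20)) for _ in range(6)]
    return pd.DataFrame(
        dict(
            spacer_id=["g1_a", "g1_b", "g2_a", "g2_b", "c1", "c2"],
            sequence=seqs,
            gene_id=["g1", "g1", "g2", "g2", "CONTROL", "CONTROL"],
            offset_frac=[0.1, 0.6, 0.2, 0.8, np.nan, np.nan],
            efficiency=[0.9, 0.8, 0.95, 0.7, 0.0, 0.0],
        )
    )
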