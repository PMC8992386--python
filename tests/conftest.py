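import numpy as np
import pandas as pd
import pytest

from ilqtl.io_core import GenomeSpec, MarkerMap
from ilqtl.simulate import SimConfig, build_marker_map, default_test_genome, library_tables, run_breeding_scheme


@pytest.fixture
def small_genome() -> GenomeSpec:
    """Two chromosomes; chr1 carries the worked 6 Mb / 3-marker example."""
    return GenomeSpec({"chr1": 6_000_000, "chr2": 4_000_000})


@pytest.fixture
def three_marker_map(small_genome) -> MarkerMap:
    return MarkerMap(
        pd.DataFrame(
            {
                "marker_id": ["RM1", "RM2", "RM3"],
                "chromosome": ["chr1"] * 3,
                "position_bp": [1_000_000, 3_000_000, 5_000_000],
            }
        ),
        small_genome,
    )


@pytest.fixture(scope="session")
def sim_library():
    """A small deterministic BC2F2 library shared across tests."""
    cfg = SimConfig(genome=default_test_genome(), n_backcrosses=2, n_selfs=2, n_lines=20, seed=11)
    mm = build_marker_map(cfg)
    ils = run_breeding_scheme(cfg, mm)
    genotypes, phenotypes, truth = library_tables(ils, cfg, mm)
    return {
        "config": cfg,
        "marker_map": mm,
        "ils": ils,
        "genotypes": genotypes,
        "phenotypes": phenotypes,
        "truth": truth,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
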