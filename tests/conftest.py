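import numpy as np
import pandas as pd
import pytest

from rohscan import GenotypeMatrix, MarkerMap, SimConfig, simulate_populations


def make_marker_map(
    n_markers: int,
    chromosome: str = "1",
    spacing_bp: int = 17_000,
    start_bp: int = 1,
) -> MarkerMap:
    """Evenly spaced single-chromosome map for hand-built fixtures."""
    pos = start_bp + spacing_bp * np.arange(n_markers)
    return MarkerMap(
        pd.DataFrame(
            {
                "marker_id": [f"m{chromosome}_{i}" for i in range(n_markers)],
                "chromosome": chromosome,
                "position_bp": pos,
                "allele1": "A",
                "allele2": "G",
            }
        )
    )


def make_genotypes(calls, populations=None) -> GenotypeMatrix:
    calls = np.asarray(calls, dtype=np.int8)
    n = calls.shape[0]
    return GenotypeMatrix(
        calls,
        [f"s{i}" for i in range(n)],
        populations if populations is not None else ["pop1"] * n,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """3 populations x 12 individuals on 4 dense chromosomes, light missingness."""
    cfg = SimConfig(
        seed=101,
        n_per_population=(12, 12, 12),
        n_chromosomes=4,
        markers_per_chromosome=400,
        missing_rate=0.01,
    )
    return simulate_populations(cfg)
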