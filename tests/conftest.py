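import numpy as np
import pytest

from iwgtrace import synthetic_data as sd
from iwgtrace.genotypes import DosageMatrix


@pytest.fixture(scope="session")
def small_config() -> sd.SimConfig:
    """A small, fast cohort: 8 accessions x 4 genets at 300 loci."""
    return sd.SimConfig(
        n_accessions=8,
        n_genets_per_accession=4,
        n_loci=300,
        fst=0.2,
        mean_depth=10,
        missing_rate=0.1,
        n_cycles=1,
        n_progeny_per_cycle=40,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """(dosages, membership, pedigree) for the small cohort."""
    return sd.simulate_founder_cohort(small_config)


def random_dosage_matrix(
    rng: np.random.Generator, n_genets: int, n_loci: int, missing_rate: float = 0.2
) -> DosageMatrix:
    d = rng.integers(0, 3, size=(n_genets, n_loci)).astype(float)
    d[rng.random(d.shape) < missing_rate] = np.nan
    return DosageMatrix(
        [f"g{i}" for i in range(n_genets)],
        [f"L{j}" for j in range(n_loci)],
        d,
    )
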