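import numpy as np
import pytest

import telandscape as tl


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@pytest.fixture(scope="session")
def two_species_sim() -> tl.SimResult:
    """A small two-species simulation shared across tests: two LINE and one
    DNA superfamily, bursts at two ages, tandem arrays planted in L2 copies."""
    config = tl.SimConfig(
        seed=42,
        n_species=2,
        genome_length=400_000,
        n_genes=15,
        superfamilies=[
            tl.Superfamily("L2", "LINE", 1400),
            tl.Superfamily("Rex-Babar", "LINE", 1200),
            tl.Superfamily("TcMar-Tc1", "DNA", 1100),
        ],
        bursts=[
            tl.Burst("sp1", "L2", 40, 0.05),
            tl.Burst("sp1", "Rex-Babar", 25, 0.30),
            tl.Burst("sp1", "TcMar-Tc1", 20, 0.10),
            tl.Burst("sp2", "L2", 15, 0.05),
            tl.Burst("sp2", "TcMar-Tc1", 10, 0.10),
        ],
        tandem_plants=[tl.TandemPlant("L2", 10, 25, 4, noise=0.03)],
        fraction_te_in_genes=0.4,
    )
    return tl.simulate_genome(config)


@pytest.fixture(scope="session")
def sim_files(two_species_sim, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("simdata")
    paths = two_species_sim.write(outdir)
    return outdir, paths
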