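import numpy as np
import pytest

from chiprx.genome import GenomeInterval, GenomeTable
from chiprx.pipeline import RunConfig, run_pipeline
from chiprx.simulate import SimConfig, simulate_all, write_simdata

# small but fully featured study used by pipeline-level tests
SMALL_SIM_KW = dict(seed=11, n_genes=80, chrom_length=1_500_000)


@pytest.fixture(scope="session")
def toy_genome() -> GenomeTable:
    return GenomeTable({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture(scope="session")
def small_sim():
    return simulate_all(SimConfig(**SMALL_SIM_KW))


@pytest.fixture(scope="session")
def study_dir(small_sim, tmp_path_factory):
    out = tmp_path_factory.mktemp("study")
    write_simdata(small_sim, out)
    return out


@pytest.fixture(scope="session")
def run_dir(study_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    return run_pipeline(RunConfig(input_dir=str(study_dir),
                                  output_dir=str(out)))


def random_intervals(rng: np.random.Generator, genome: GenomeTable,
                     n: int, max_len: int = 2000) -> list[GenomeInterval]:
    out = []
    chroms = list(genome)
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, genome[chrom] - length))
        out.append(GenomeInterval(chrom, start, start + length))
    return out
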