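import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

import aneupore.align_count as ac
import aneupore.simulate as sim
from aneupore.karyotype import Karyotype


@pytest.fixture(scope="session")
def small_genome() -> sim.ToyGenome:
    return sim.make_toy_genome({"chrA": 50_000, "chrB": 50_000}, seed=1)


@pytest.fixture(scope="session")
def small_index(small_genome) -> ac.GenomeIndex:
    return ac.GenomeIndex(small_genome)


@pytest.fixture(scope="session")
def default_genome() -> sim.ToyGenome:
    return sim.default_toy_genome(seed=7)


@pytest.fixture(scope="session")
def default_index(default_genome) -> ac.GenomeIndex:
    return ac.GenomeIndex(default_genome)


@pytest.fixture(scope="session")
def barcodes() -> sim.BarcodeSet:
    return sim.make_barcode_set(5, seed=11)


@pytest.fixture(scope="session")
def diploid() -> Karyotype:
    # both-autosome diploid state for genomes without sex chromosomes
    return Karyotype()
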