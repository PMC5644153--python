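import numpy as np
import pytest

from gdti.experiment import table1_design
from gdti.pedigree import Individual, MarkerGenotype, Pedigree, PedigreeSet
from gdti.simulate import simulate_replicate


@pytest.fixture
def trio() -> Pedigree:
    """Two heterozygous unaffected founders with an affected M1M1 child."""
    return Pedigree(
        "1",
        [
            Individual("F", sex=1, affection=0, genotype=MarkerGenotype(1, 2)),
            Individual("M", sex=2, affection=0, genotype=MarkerGenotype(1, 2)),
            Individual(
                "C", "F", "M", sex=1, affection=1, genotype=MarkerGenotype(1, 1)
            ),
        ],
    )


@pytest.fixture
def trio_set(trio) -> PedigreeSet:
    return PedigreeSet([trio])


def simulated_set(
    seed: int, per_template: int = 4, incomplete: bool = False, setting: int = 7
) -> PedigreeSet:
    """A small gene-dropped study replicate (complete genotypes by default)."""
    design = table1_design(
        setting, per_template=per_template, incomplete=incomplete
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return simulate_replicate(design, rng)
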