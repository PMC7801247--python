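import numpy as np
import pytest

from wgdscan import (
    Gene,
    GenomeAnnotation,
    SequenceStore,
    SimConfig,
    WGDSpec,
    simulate_genome,
)
from wgdscan._codon import SENSE_CODONS


def make_annotation(sizes: dict[str, int], prefix: str = "g") -> GenomeAnnotation:
    """Annotation with ``sizes[scaffold]`` genes per scaffold, rank order."""
    genes = {}
    i = 0
    for sc, n in sizes.items():
        genes[sc] = [
            Gene(id=f"{prefix}{i + k}", scaffold=sc, rank=k + 1) for k in range(n)
        ]
        i += n
    return GenomeAnnotation(name="toy", genes=genes)


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    return "".join(SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def tetraploid_lossfree():
    """One WGD at Ks 0.3, full retention: every gene has an identical-history twin."""
    config = SimConfig(
        n_ancestral_genes=120, n_scaffolds=2,
        events=(WGDSpec(target_ks=0.3, retention=1.0),), seed=11,
    )
    return simulate_genome(config)


@pytest.fixture(scope="session")
def two_wgd_genome():
    """Small two-event history used across pipeline tests."""
    config = SimConfig(
        n_ancestral_genes=250, n_scaffolds=3,
        events=(WGDSpec(1.2, 0.4), WGDSpec(0.12, 0.7)),
        n_inversions=3, n_translocations=2, seed=5,
    )
    return simulate_genome(config)


@pytest.fixture()
def tiny_store():
    return SequenceStore({
        "a": "ATGGCTGCTGCAACTGGTCATCTTCCTGCAGGAGATCTAAGCGCTTGGACT" + "GCT" * 20,
        "b": "ATGGCTGCAGCAACTGGCCATCTGCCTGCAGGAGATCTAAGCGCATGGACT" + "GCT" * 20,
    })
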