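import numpy as np
import pytest

from lohsim.genomes import CloneGenome, MarkerMap, SyntheticReference


@pytest.fixture(scope="session")
def marker_map() -> MarkerMap:
    return MarkerMap()


@pytest.fixture(scope="session")
def chrv_reference() -> SyntheticReference:
    """Small reference (chrV plus one short chromosome) for fast tests."""
    return SyntheticReference.yeast_like(
        seed=11, chrom_lengths={"chrV": 576_874, "chrII": 120_000}
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def empty_clone(chrv_reference, marker_map) -> CloneGenome:
    return CloneGenome(
        clone_id="test_clone",
        ploidy=2,
        marker_alleles=marker_map.heterozygous_alleles(),
        chrom_lengths=dict(chrv_reference.chrom_lengths),
    )
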