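import numpy as np
import pytest

from mtauth import fixtures
from mtauth.refhap import CircularReference, Haplotype
from mtauth.simulate import SimParams, simulate_reads


@pytest.fixture(scope="session")
def ref():
    return fixtures.reference()


@pytest.fixture(scope="session")
def tree():
    return fixtures.haplogroup_tree()


@pytest.fixture(scope="session")
def sample_hap():
    return fixtures.sample_haplotype()


@pytest.fixture(scope="session")
def empty_hap():
    return Haplotype("reference", ())


@pytest.fixture(scope="session")
def toy_ref():
    rng = np.random.default_rng(42)
    return CircularReference("toy", "".join(rng.choice(list("ACGT"), size=500)))


@pytest.fixture(scope="session")
def clean_sim(ref, sample_hap, empty_hap):
    """Noise-free 20k-fragment simulation from the packaged haplotype."""
    params = SimParams(n_fragments=20000, contamination=0.0, seed=11)
    return simulate_reads(ref, sample_hap, empty_hap, params)
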