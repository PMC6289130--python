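import numpy as np
import pytest

from hostsieve import simulate


@pytest.fixture(scope="session")
def artifact_community(tmp_path_factory):
    """Community with every artifact type planted, shared across tests."""
    spec = simulate.CommunitySpec(
        n_reads=2000,
        host_fraction=0.5,
        per_base_error_rate=0.01,
        duplicate_rate=0.2,
        adapter_contamination_rate=0.05,
        low_complexity_insert_rate=0.05,
        novel_organism_fraction=0.02,
        seed=11,
    )
    return simulate.generate_community(
        spec, str(tmp_path_factory.mktemp("artifact_community"))
    )


@pytest.fixture(scope="session")
def clean_community(tmp_path_factory):
    """Error- and artifact-free half-host community."""
    spec = simulate.CommunitySpec(n_reads=1000, host_fraction=0.5, seed=5)
    return simulate.generate_community(
        spec, str(tmp_path_factory.mktemp("clean_community"))
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
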