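import pytest
from hypothesis import settings

from nsltpkit import synth

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def sdp_fixture():
    """Noise-free planted-SDP alignment: 2 clades of 4, 60 columns."""
    return synth.make_sdp_alignment(
        n_clades=2, seqs_per_clade=4, n_columns=60, n_sdp=5, n_conserved=10,
        noise_rate=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def bundle_fixture():
    """Two planted structural clusters of four helical traces each."""
    return synth.make_helix_bundle(
        n_clusters=2, members_per_cluster=4, n_residues=40,
        within_sigma=0.3, between_shift=5.0, seed=7,
    )


@pytest.fixture(scope="session")
def trace_benchmark():
    """43-sequence, 90-residue alignment with the controlled tie structure."""
    return synth.make_trace_benchmark()
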