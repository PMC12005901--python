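import pytest

from cnvbench.fixtures import make_reference


@pytest.fixture(scope="session")
def reference():
    """A small random reference with two planted tandem-repeat sites."""
    return make_reference(
        seed=11,
        contigs={"c1": 30_000, "c2": 20_000},
        tandem_sites_per_contig=1,
        tandem_length=500,
    )
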