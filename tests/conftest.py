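import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def diamond_model():
    """A mutually-exclusive-exon gene model shared across tests."""
    from isocore import make_mutually_exclusive_gene

    return make_mutually_exclusive_gene(seed=1, k=47)


@pytest.fixture(scope="session")
def diamond_reads(diamond_model):
    """Error-free 2x125 bp pairs at 20x from all four long isoforms."""
    from isocore import ReadSimParams, simulate_read_pairs

    txs = diamond_model.transcribed_isoforms()
    pairs, truth = simulate_read_pairs(
        txs, {n: 1.0 for n in txs}, ReadSimParams(coverage=20.0, seed=1)
    )
    return pairs, truth
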