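import pytest

from topofill.fixtures import benchmark_model, fig1_instance, fig2_network


@pytest.fixture(scope="session")
def fig1():
    return fig1_instance()


@pytest.fixture(scope="session")
def fig2():
    net, seeds = fig2_network()
    return net, seeds


@pytest.fixture(scope="session")
def bench_model():
    return benchmark_model()
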