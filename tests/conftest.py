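import pytest

from canalith import make_canal


@pytest.fixture(scope="session")
def right_true():
    return make_canal("right", "true_posteromedial")


@pytest.fixture(scope="session")
def left_true():
    return make_canal("left", "true_posteromedial")


@pytest.fixture(scope="session")
def right_hyp():
    return make_canal("right", "hypothetical_anteromedial")


@pytest.fixture(scope="session")
def left_hyp():
    return make_canal("left", "hypothetical_anteromedial")


@pytest.fixture(scope="session")
def default_canals(right_true, left_true, right_hyp, left_hyp):
    return [
        right_true,
        left_true,
        right_hyp,
        left_hyp,
        make_canal("right", "arc180"),
        make_canal("left", "arc180"),
    ]
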