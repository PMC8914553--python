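import pytest

from matscale import default_vocabulary, load_lexicon, synthetic


@pytest.fixture(scope="session")
def vocab():
    return default_vocabulary()


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture(scope="session")
def small_design():
    """8 images, 24 participants, moderate asymmetry."""
    return synthetic.default_design(n_images=8, lam=0.6, seed=11)


@pytest.fixture(scope="session")
def exp1_records(small_design):
    records, ledger = synthetic.simulate_exp1(small_design)
    return records, ledger


@pytest.fixture(scope="session")
def exp2a_records(small_design):
    records, ledger = synthetic.simulate_exp2(small_design, "instructions")
    return records, ledger
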