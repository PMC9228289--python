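import pytest

from qsarval import fit_ols, load_glyt1, split


@pytest.fixture(scope="session")
def glyt1():
    return load_glyt1()


@pytest.fixture(scope="session")
def train_test(glyt1):
    return split(glyt1, drop_outliers=True)


@pytest.fixture(scope="session")
def train(train_test):
    return train_test[0]


@pytest.fixture(scope="session")
def test_set(train_test):
    return train_test[1]


@pytest.fixture(scope="session")
def mlr_model(train):
    return fit_ols(train.X, train.y)
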