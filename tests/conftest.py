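import numpy as np
import pytest

from fusionbreak.catalog import Catalog, load_packaged_catalog


@pytest.fixture(scope="session")
def catalog() -> Catalog:
    return load_packaged_catalog()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230913)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
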