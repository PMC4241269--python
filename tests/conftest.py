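import numpy as np
import pytest

from csmotif import load_default_table
from csmotif.msa_io import Alignment


@pytest.fixture(scope="session")
def table():
    return load_default_table()


@pytest.fixture()
def tiny_alignment():
    """Four sequences, ten columns, a fully conserved block at columns 1-6."""
    return Alignment((
        ("s1", "AKWDEFGHIA"),
        ("s2", "CKWDEFGYLC"),
        ("s3", "DKWDEFGHMD"),
        ("s4", "EKWDEFGYNE"),
    ))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20110830)
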