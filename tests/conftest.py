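import pytest

from tagarmt import call_series, default_motif_table, load_bundled_series


@pytest.fixture(scope="session")
def motifs():
    return default_motif_table()


@pytest.fixture(scope="session")
def series():
    return load_bundled_series()


@pytest.fixture(scope="session")
def called(series, motifs):
    table, report = call_series(series, motifs)
    return table
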