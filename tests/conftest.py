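import pytest
from hypothesis import settings

from emtscore import builtin_emt_signature, fixture_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cohort():
    """Deterministic fixture cohort: (matrix, metadata, ihc records)."""
    return fixture_cohort()


@pytest.fixture(scope="session")
def emt_sig():
    return builtin_emt_signature()


@pytest.fixture
def matrix_file(tmp_path):
    """Write a small genes x samples TSV and return its path."""

    def _write(lines, name="expr.tsv"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
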