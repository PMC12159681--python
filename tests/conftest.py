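import pytest

from cmrnorms import StudySummary, load_default_registry


@pytest.fixture(scope="session")
def registry():
    return load_default_registry()


@pytest.fixture(scope="session")
def five_studies():
    """Heterogeneous five-study aggregate fixture for pooling oracles."""
    rows = [("s1", 50, 100.0, 15.0), ("s2", 120, 104.0, 12.0),
            ("s3", 80, 97.0, 18.0), ("s4", 200, 101.0, 14.0),
            ("s5", 60, 95.0, 20.0)]
    return [StudySummary(study_id=i, parameter_id="lvedv", n=n, mean=m, sd=s)
            for i, n, m, s in rows]
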