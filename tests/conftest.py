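import pytest


@pytest.fixture(scope="session")
def study17():
    """The full synthetic study (discovery + design + in-silico PCR), seed 17."""
    from pseudoquant.study import build_study

    return build_study(17)


@pytest.fixture(scope="session")
def locus_set17(study17):
    return study17.locus_set
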