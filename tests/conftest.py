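import pytest

from lepitran import synthetic_data as sd


@pytest.fixture(scope="session")
def small_world():
    """A balanced 40-transcript world shared by read-level tests."""
    return sd.make_world(
        n_proteins=12,
        n_transcripts=40,
        tier_mix={"gold": 0.25, "silver": 0.25, "bronze": 0.25, "none": 0.25},
        seed=101,
    )


@pytest.fixture(scope="session")
def toy_ontology():
    return sd.make_toy_ontology(depth=3, branching=3, seed=7)
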