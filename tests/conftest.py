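import pytest

from temodeler import (
    SimConfig,
    TELibrary,
    TEReference,
    simulate_genome,
    simulate_library,
)


@pytest.fixture
def toy_library() -> TELibrary:
    """A hand-built two-element library: one LTR-RT (annotated LTRs) and
    one CACTA-like element, both flagged complete."""
    rlg = TEReference(
        id="RLG_famc1_cons",
        family_id="RLG_famc1",
        superfamily="RLG",
        length=8300,
        is_complete=True,
        ltr5=(1, 300),
        ltr3=(8001, 8300),
    )
    dtc = TEReference(
        id="DTC_famc1_cons",
        family_id="DTC_famc1",
        superfamily="DTC",
        length=5000,
        is_complete=True,
    )
    return TELibrary({rlg.id: rlg, dtc.id: dtc})


@pytest.fixture
def sim_bundle():
    """Factory for (config, library, truth) simulation bundles."""

    def make(seed: int = 0, **kwargs):
        defaults = dict(
            seed=seed,
            n_insertions=60,
            background_len=80_000,
            nesting_prob=0.4,
        )
        defaults.update(kwargs)
        config = SimConfig(**defaults)
        library = simulate_library(config)
        truth = simulate_genome(library, config)
        return config, library, truth

    return make
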