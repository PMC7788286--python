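import pytest

from dubscreen import (
    EffectModel,
    HairpinRecord,
    ScreenSimParams,
    ShrnaLibrary,
    make_dub_library,
    simulate_screen,
)


@pytest.fixture(scope="session")
def lib508():
    """The packaged 508-hairpin DUB-like library."""
    return make_dub_library()


@pytest.fixture(scope="session")
def neutral_screen(lib508):
    """One neutral full-scale simulated screen (seed 1)."""
    return simulate_screen(lib508, ScreenSimParams(seed=1))


@pytest.fixture
def tiny_lib():
    """Hand-built 11-hairpin library: 3 test genes + controls."""
    import numpy as np

    from dubscreen.library import _random_kmers

    seqs = iter(_random_kmers(11, 21, np.random.default_rng(1234)))
    records = [
        HairpinRecord(f"sh{g}_{j}", g, next(seqs))
        for g in ("GeneA", "GeneB", "GeneC")
        for j in range(1, 4)
    ] + [
        HairpinRecord("shBmi1_1", "Bmi1", next(seqs), role="positive_control"),
        HairpinRecord("shScr_1", "Scramble", next(seqs), role="neutral_control"),
    ]
    return ShrnaLibrary(records, name="tiny")


@pytest.fixture
def neutral_effects(lib508):
    return EffectModel.neutral(lib508)
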