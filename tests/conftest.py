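import pytest

from panscreen import synthetic


@pytest.fixture(scope="session")
def small_design():
    return synthetic.default_library_design(seed=2)


@pytest.fixture(scope="session")
def small_campaign():
    """A 300-clone, 3000-reads-per-round campaign used across tests."""
    cfg = synthetic.PanningConfig(reads_per_round=3000, seed=11)
    return synthetic.simulate_campaign(n_clones=300, seed=11, config=cfg)


@pytest.fixture(scope="session")
def singleton_design(small_design):
    """A design whose pools hold exactly one variant each."""
    d = small_design
    return synthetic.LibraryDesign(
        framework_regions=d.framework_regions,
        cdr_pools=([d.cdr_pools[0][0]], [d.cdr_pools[1][0]],
                   [d.cdr_pools[2][0]]),
        anchor=d.anchor,
        seed=0,
    )
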