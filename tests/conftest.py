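import pytest

from camelscan import admixscan, simpop

#: the study-style quartet: (ingroup Y, ingroup Z; outgroup W, donor X)
CAMEL_QUARTET = admixscan.QuartetConfig(
    "east_asian", "central_asian", "wild_bactrian", "dromedary"
)


@pytest.fixture(scope="session")
def pulse_sim():
    """Camel scenario with strong (f = 0.2) dromedary pulses into the three
    Central Asian populations, confined to 20 of 100 scan windows."""
    cfg = simpop.make_camel_scenario(
        seed=7, pulse_proportions={"IRAN": 0.2, "KAZA": 0.2, "RUS": 0.2}
    )
    matrix, popmap, truth, freqs = simpop.simulate(cfg)
    return cfg, matrix, popmap, truth, freqs


@pytest.fixture(scope="session")
def null_sim(pulse_sim):
    """Matched no-pulse control: same seed, pulses removed."""
    cfg = pulse_sim[0].without_pulses()
    matrix, popmap, truth, freqs = simpop.simulate(cfg)
    return cfg, matrix, popmap, truth, freqs


@pytest.fixture(scope="session")
def default_sim():
    """The default camel scenario (1-10% pulses)."""
    cfg = simpop.make_camel_scenario(seed=3)
    matrix, popmap, truth, freqs = simpop.simulate(cfg)
    return cfg, matrix, popmap, truth, freqs


@pytest.fixture(scope="session")
def pulse_scan(pulse_sim):
    _, matrix, popmap, _, _ = pulse_sim
    return admixscan.introgression_scan(matrix, popmap, CAMEL_QUARTET)


@pytest.fixture(scope="session")
def null_scan(null_sim):
    _, matrix, popmap, _, _ = null_sim
    return admixscan.introgression_scan(matrix, popmap, CAMEL_QUARTET)
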