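import math

import numpy as np
import pytest

from poretrace.transport import CargoSpecies, PoreGeometry, Vesicle


@pytest.fixture
def open_pore():
    return PoreGeometry(lumen_radius=4.8, channel_length=32.0)


@pytest.fixture
def vesicle_200nm():
    return Vesicle(id=0, diameter=200.0, content={"dye": 1000.0})


@pytest.fixture
def small_dye():
    return CargoSpecies("dye", hydrodynamic_radius=0.5, flexibility=1.0,
                        brightness=10.0)


def make_exp_trace(times, plateau, onset, k, noise_sd=0.0, rng=None,
                   baseline=0.0):
    """Plateau followed by exponential decay toward baseline."""
    times = np.asarray(times, dtype=float)
    clean = np.where(times < onset, plateau,
                     baseline + (plateau - baseline)
                     * np.exp(-k * np.clip(times - onset, 0, None)))
    if noise_sd > 0:
        clean = clean + rng.normal(0, noise_sd, size=times.size)
    return clean
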