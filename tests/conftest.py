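"""Shared fixtures: small synthetic recordings reused across detector tests."""

import numpy as np
import pytest

from cohfo import detect, sim
from cohfo.types import BurstSpec


@pytest.fixture(scope="session")
def small_bank():
    """Filter bank at a desk-scale sampling rate (fs = 2000 Hz still covers
    the full 60-800 Hz layout)."""
    return detect.FilterBank(fs=2000.0)


@pytest.fixture(scope="session")
def small_noise():
    """25 s of pink noise on one channel at fs = 2000 Hz."""
    cfg = sim.SimConfig(n_channels=1, duration=95.0, n_lists=1, fs=2000.0,
                        seed=11)
    sig = sim.generate_pink_noise(cfg)
    sig.data = sig.data[:, : int(25.0 * 2000)]
    return sig


@pytest.fixture(scope="session")
def injected_recording(small_bank):
    """One channel, 25 s, ten 120-Hz bursts at 6x the 60-800 Hz noise RMS.

    Returns (signal, burst_specs, band_rms).
    """
    cfg = sim.SimConfig(n_channels=1, duration=95.0, n_lists=1, fs=2000.0,
                        seed=21)
    sig = sim.generate_pink_noise(cfg)
    sig.data = sig.data[:, : int(25.0 * 2000)]
    band_rms = detect.band_rms(sig.data[0], 2000.0, 60.0, 800.0)
    rng = np.random.default_rng(5)
    centers = np.linspace(2.0, 23.0, 10)
    specs = [BurstSpec(channel=0, center_time=float(c), frequency=120.0,
                       n_cycles=6, amplitude=6.0 * band_rms,
                       phase=float(rng.uniform(0, 2 * np.pi)))
             for c in centers]
    return sim.inject_bursts(sig, specs), specs, band_rms
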