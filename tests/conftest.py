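import numpy as np
import pytest

from drinkometer import DetectionConfig, SimConfig
from drinkometer.detection import SpeedTrace


@pytest.fixture
def det_cfg():
    return DetectionConfig()


@pytest.fixture
def sim_cfg():
    return SimConfig(seed=7)


def make_speed(values, fs=1000.0):
    """SpeedTrace from raw values, for direct detection-stage tests."""
    return SpeedTrace(fs=fs, speed=np.asarray(values, dtype=float))


def raised_cosine_speed(
    peaks_s, amplitude, width_s, fs=1000.0, total_s=None
):
    """Speed signal made of raised-cosine pulses centred at given times.

    Pulse area is amplitude * width / 2 (the mean of 1 - cos is 1).
    """
    peaks_s = np.asarray(peaks_s, dtype=float)
    total_s = total_s or peaks_s.max() + width_s
    n = int(round(total_s * fs))
    speed = np.zeros(n)
    for p in peaks_s:
        i0 = int(round((p - width_s / 2) * fs))
        m = int(round(width_s * fs))
        t = np.arange(m) / m
        pulse = amplitude / 2 * (1 - np.cos(2 * np.pi * t))
        lo = max(i0, 0)
        speed[lo : i0 + m] += pulse[lo - i0 : n - i0]
    return SpeedTrace(fs=fs, speed=speed)
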