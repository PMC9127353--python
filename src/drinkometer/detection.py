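"""Suck detection and inter-suck interval extraction from volume traces.

The conditioning chain is fixed:

    lowpass_filter -> differentiate -> remove_artifacts -> floor_speed
    -> detect_sucks -> extract_intervals

A suck is a pulse in the drinking speed (the derivative of cumulative
volume): a local maximum at least ``min_amplitude`` ml/s high, at least
``min_peak_distance_s`` away from its neighbours, whose integrated volume
between the flanking zero-speed samples is at least ``min_suck_size_ml``.
An inter-suck interval is the pause between one suck's offset and the next
suck's onset (not peak-to-peak: the population's modal pause of ~0.97 s
would be impossible peak-to-peak under the 1 s minimum peak spacing).

The detection low-pass defaults to 10 Hz. The device protocol suggests a
0.5 Hz cutoff, but that smooths cumulative volume for visual quality
control: a 0.5 Hz zero-phase filter has a ~1.3 s rise time and merges
pulses separated by second-scale pauses, so it cannot precede
derivative-based event detection. ``VIZ_CUTOFF_HZ`` keeps the 0.5 Hz value
for the QC plot path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import trapezoid
from scipy.signal import butter, filtfilt, find_peaks

from .errors import ConfigError, SignalTooShortError
from .signal_io import MeasurementMeta, QCStatus, VolumeTrace, make_interval_table

#: Suggested cutoff (Hz) for smoothing cumulative volume in QC plots.
VIZ_CUTOFF_HZ = 0.5


@dataclass
class DetectionConfig:
    """Thresholds of the suck-detection chain.

    Parameters
    ----------
    fs : float
        Sampling frequency in Hz (suggested 1000).
    cutoff_hz : float
        Low-pass cutoff for signal conditioning, Hz. Default 10 Hz
        (see module docstring; 0.5 Hz is the visualization cutoff).
    artifact_speed : float
        Absolute speed above which samples are artifacts, ml/s (suggested 20).
    min_amplitude : float
        Minimal suck amplitude, ml/s; speed below it is set to 0
        (suggested 0.5).
    min_peak_distance_s : float
        Minimal spacing between suck peaks, s (suggested 1).
    min_suck_size_ml : float
        Minimal suck size, ml; smaller pulses are noise (suggested 1).
    qc_artifact_fraction : float
        Fraction of artifact-masked samples above which a measurement is
        flagged as interference.
    qc_volume_drop_ml : float
        Tolerated decrease of cumulative volume before flagging.
    """

    fs: float = 1000.0
    cutoff_hz: float = 10.0
    artifact_speed: float = 20.0
    min_amplitude: float = 0.5
    min_peak_distance_s: float = 1.0
    min_suck_size_ml: float = 1.0
    qc_artifact_fraction: float = 0.01
    qc_volume_drop_ml: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "fs",
            "cutoff_hz",
            "artifact_speed",
            "min_amplitude",
            "min_peak_distance_s",
            "min_suck_size_ml",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.cutoff_hz >= self.fs / 2:
            raise ConfigError(
                f"cutoff_hz={self.cutoff_hz} must be below the Nyquist "
                f"frequency {self.fs / 2}"
            )


@dataclass
class SpeedTrace:
    """Drinking speed (ml/s) aligned to a parent :class:`VolumeTrace`."""

    fs: float
    speed: np.ndarray
    artifact_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.speed = np.asarray(self.speed, dtype=float)
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.speed.size, dtype=bool)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.artifact_mask.size != self.speed.size:
            raise ConfigError("artifact_mask must match speed length")

    @property
    def n(self) -> int:
        return int(self.speed.size)


@dataclass(frozen=True)
class SuckEvent:
    """One detected suck."""

    onset_s: float
    peak_s: float
    offset_s: float
    size_ml: float
    peak_speed: float

    def __post_init__(self) -> None:
        if not (self.onset_s <= self.peak_s <= self.offset_s):
            raise ConfigError("suck times must satisfy onset <= peak <= offset")


def _butter_lowpass(cutoff_hz: float, fs: float):
    return butter(4, cutoff_hz / (fs / 2), btype="low")


def lowpass_filter(trace: VolumeTrace, cfg: DetectionConfig) -> VolumeTrace:
    """Zero-phase 4th-order Butterworth low-pass of the volume signal.

    Zero-phase (forward-backward) filtering avoids shifting suck times.
    """
    b, a = _butter_lowpass(cfg.cutoff_hz, trace.fs)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if trace.n <= padlen:
        raise SignalTooShortError(
            f"trace has {trace.n} samples; need more than {padlen} to filter"
        )
    filtered = filtfilt(b, a, trace.volume)
    return VolumeTrace(
        measurement_id=trace.measurement_id,
        fs=trace.fs,
        volume=filtered,
        t0=trace.t0,
    )


def differentiate(trace: VolumeTrace) -> SpeedTrace:
    """Central-difference derivative of volume, in ml/s (one-sided at edges)."""
    if trace.n < 2:
        raise SignalTooShortError("need at least 2 samples to differentiate")
    speed = np.gradient(trace.volume) * trace.fs
    return SpeedTrace(fs=trace.fs, speed=speed, t0=trace.t0)


def remove_artifacts(speed: SpeedTrace, cfg: DetectionConfig) -> SpeedTrace:
    """Delete super-threshold speed excursions and bridge them linearly.

    Every maximal run with ``|speed| > artifact_speed`` is extended to the
    flanking zero crossings of the speed signal and replaced by linear
    interpolation between the flanking retained samples (nearest retained
    value when a run touches a signal edge). Replaced samples are marked in
    ``artifact_mask``.
    """
    s = speed.speed.copy()
    n = s.size
    bad = np.abs(s) > cfg.artifact_speed
    if not bad.any():
        return SpeedTrace(
            fs=speed.fs,
            speed=s,
            artifact_mask=np.zeros(n, dtype=bool),
            t0=speed.t0,
        )

    # sign changes (treat 0 as a crossing anchor)
    mask = np.zeros(n, dtype=bool)
    idx = np.flatnonzero(bad)
    # group contiguous runs
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    for run in np.split(idx, splits):
        lo, hi = run[0], run[-1]
        sign = np.sign(s[lo]) or 1.0
        # extend left to the nearest sample where the excursion's sign ends
        while lo > 0 and np.sign(s[lo - 1]) == sign and s[lo - 1] != 0:
            lo -= 1
        while hi < n - 1 and np.sign(s[hi + 1]) == sign and s[hi + 1] != 0:
            hi += 1
        mask[lo : hi + 1] = True

    good = ~mask
    if not good.any():
        # extension swallowed the whole signal (one same-sign lobe):
        # fall back to bridging only the super-threshold runs themselves
        mask = bad
        good = ~mask
    repaired = s.copy()
    if good.any():
        repaired[mask] = np.interp(
            np.flatnonzero(mask), np.flatnonzero(good), s[good]
        )
    else:
        repaired[:] = 0.0
    return SpeedTrace(fs=speed.fs, speed=repaired, artifact_mask=mask, t0=speed.t0)


def floor_speed(speed: SpeedTrace, cfg: DetectionConfig) -> SpeedTrace:
    """Zero out speed samples below the minimal suck amplitude."""
    s = speed.speed.copy()
    s[s < cfg.min_amplitude] = 0.0
    return SpeedTrace(
        fs=speed.fs, speed=s, artifact_mask=speed.artifact_mask.copy(), t0=speed.t0
    )


def detect_sucks(speed: SpeedTrace, cfg: DetectionConfig) -> list[SuckEvent]:
    """Detect sucks in an artifact-repaired, floored speed signal.

    Peaks at least ``min_amplitude`` high and ``min_peak_distance_s`` apart
    (the higher peak wins a conflict); onset/offset at the nearest
    surrounding zero-speed samples; size is the trapezoidal integral of the
    speed between them; pulses smaller than ``min_suck_size_ml`` are
    discarded.
    """
    s = speed.speed
    distance = max(1, int(round(cfg.min_peak_distance_s * speed.fs)))
    peaks, _ = find_peaks(s, height=cfg.min_amplitude, distance=distance)
    if peaks.size == 0:
        return []

    zero = s == 0.0
    zero_idx = np.flatnonzero(zero)
    events: list[SuckEvent] = []
    for p in peaks:
        if zero_idx.size:
            pos = np.searchsorted(zero_idx, p)
            onset = zero_idx[pos - 1] if pos > 0 else 0
            offset = zero_idx[pos] if pos < zero_idx.size else s.size - 1
        else:
            onset, offset = 0, s.size - 1
        size_ml = trapezoid(s[onset : offset + 1]) / speed.fs
        if size_ml < cfg.min_suck_size_ml:
            continue
        events.append(
            SuckEvent(
                onset_s=speed.t0 + onset / speed.fs,
                peak_s=speed.t0 + p / speed.fs,
                offset_s=speed.t0 + offset / speed.fs,
                size_ml=float(size_ml),
                peak_speed=float(s[p]),
            )
        )
    # two peaks between the same pair of zeros would duplicate the pulse;
    # keep the higher one
    deduped: list[SuckEvent] = []
    for ev in events:
        if deduped and ev.onset_s == deduped[-1].onset_s:
            if ev.peak_speed > deduped[-1].peak_speed:
                deduped[-1] = ev
            continue
        deduped.append(ev)
    return deduped


def extract_intervals(sucks, meta: MeasurementMeta):
    """Pause durations between consecutive sucks, as an interval table.

    The interval is offset-to-onset (the silent pause), one row per
    consecutive suck pair; fewer than two sucks yield an empty table.
    """
    intervals = [
        b.onset_s - a.offset_s for a, b in zip(sucks, sucks[1:])
    ]
    return make_interval_table(meta.participant, meta.visit, intervals)


def qc_flag_interference(trace: VolumeTrace, cfg: DetectionConfig) -> MeasurementMeta:
    """Flag measurements whose signal shows interference.

    A measurement is excluded when more than ``qc_artifact_fraction`` of
    samples are artifact-repaired, or when cumulative volume decreases by
    more than ``qc_volume_drop_ml`` anywhere in the record.
    """
    filtered = lowpass_filter(trace, cfg)
    speed = differentiate(filtered)
    repaired = remove_artifacts(speed, cfg)
    artifact_fraction = repaired.artifact_mask.mean()
    running_max = np.maximum.accumulate(filtered.volume)
    max_drop = float(np.max(running_max - filtered.volume))
    status = QCStatus.INCLUDED
    if artifact_fraction > cfg.qc_artifact_fraction or max_drop > cfg.qc_volume_drop_ml:
        status = QCStatus.EXCLUDED_INTERFERENCE
    return MeasurementMeta(
        participant=trace.measurement_id,
        visit=1,
        source_files=[],
        qc_status=status,
    )


def run_detection(
    trace: VolumeTrace, cfg: DetectionConfig, meta: MeasurementMeta | None = None
):
    """Full chain: filter, differentiate, repair, floor, detect, extract.

    Returns ``(sucks, interval_table, floored_speed)``.
    """
    if meta is None:
        meta = MeasurementMeta(participant=trace.measurement_id)
    cfg = replace(cfg, fs=trace.fs)
    filtered = lowpass_filter(trace, cfg)
    speed = differentiate(filtered)
    repaired = remove_artifacts(speed, cfg)
    floored = floor_speed(repaired, cfg)
    sucks = detect_sucks(floored, cfg)
    table = extract_intervals(sucks, meta)
    return sucks, table, floored
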