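"""Synthetic drinkometer traces and interval samples with known ground truth.

Pauses are drawn from a two-component lognormal mixture whose log-domain
means sit at the modal values observed in pooled human drinking data
(log_e ISI mode ~ -0.0325, i.e. ~0.97 s; log_e IBI mode ~ 1.1460, i.e.
~3.15 s). Sucks are rendered as raised-cosine speed pulses whose area is
the drawn suck size; cumulative volume is the integral of the speed plus
optional white measurement noise and optional biphasic artifact spikes.

Physiological realism choices baked into the defaults: sucks last 0.8 s,
move 3.8 +/- 0.5 ml (clipped to [2.0, 5.5] ml so every rendered suck is
detectable and no clean suck crosses the 20 ml/s artifact threshold), and
pauses are floored at 0.25 s (a refractory period: a new suck cannot start
mid-swallow). The floor resamples only ~0.1% of the ISI draws — kept this
far into the tail deliberately, because a harder floor truncates the ISI
component's left tail and visibly distorts the fitted mixture
decomposition. It also guarantees peak-to-peak spacings above the 1 s
minimum peak distance, so clean pulses are never merged by detection.
``true_intersection`` always refers to the untruncated generating
components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bpcd import component_intersection
from .errors import ConfigError, NoIntersectionError
from .signal_io import VolumeTrace, make_interval_table


@dataclass
class SimConfig:
    """Generator settings; defaults reproduce the pooled-data calibration."""

    seed: int = 0
    fs: float = 1000.0
    n_bursts: int = 20
    #: geometric mean; 1/(1 - mix_weight_isi) makes the realized fraction of
    #: within-burst pauses match mix_weight_isi in expectation
    sucks_per_burst_mean: float = 10.0 / 3.0
    isi_logmean: float = -0.0325
    isi_logsd: float = 0.45
    ibi_logmean: float = 1.1460
    ibi_logsd: float = 0.55
    mix_weight_isi: float = 0.70
    suck_size_mean_ml: float = 3.8
    suck_size_sd_ml: float = 0.5
    suck_duration_s: float = 0.8
    noise_sd_ml: float = 0.0
    artifact_rate_per_min: float = 0.0
    #: refractory floor on rendered pauses (s); draws below it are resampled
    min_pause_s: float = 0.25

    def __post_init__(self) -> None:
        for name in (
            "fs",
            "sucks_per_burst_mean",
            "isi_logsd",
            "ibi_logsd",
            "suck_size_mean_ml",
            "suck_size_sd_ml",
            "suck_duration_s",
            "min_pause_s",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.mix_weight_isi < 1:
            raise ConfigError("mix_weight_isi must be in (0, 1)")
        if self.isi_logmean >= self.ibi_logmean:
            raise ConfigError("isi_logmean must be below ibi_logmean")
        if np.exp(self.isi_logmean) <= self.suck_duration_s:
            raise ConfigError(
                "modal pause exp(isi_logmean) must exceed suck_duration_s; "
                "pulses would overlap with peak spacing below the pause scale"
            )
        if self.noise_sd_ml < 0 or self.artifact_rate_per_min < 0:
            raise ConfigError("noise_sd_ml and artifact_rate_per_min must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually drew."""

    suck_onsets_s: np.ndarray
    suck_sizes_ml: np.ndarray
    pauses_s: np.ndarray
    pause_labels: np.ndarray  # "ISI" / "IBI"
    n_bursts: int
    true_pc_log: float | None
    suck_duration_s: float = 0.8
    artifact_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_sucks(self) -> int:
        return int(self.suck_onsets_s.size)

    @property
    def total_volume_ml(self) -> float:
        return float(self.suck_sizes_ml.sum())


def true_intersection(cfg: SimConfig) -> float:
    """Analytic intersection of the weighted generating log-domain components."""
    return component_intersection(
        cfg.mix_weight_isi, cfg.isi_logmean, cfg.isi_logsd,
        1.0 - cfg.mix_weight_isi, cfg.ibi_logmean, cfg.ibi_logsd,
    )


def _maybe_true_pc(cfg: SimConfig) -> float | None:
    try:
        return true_intersection(cfg)
    except NoIntersectionError:
        return None


def simulate_intervals(
    cfg: SimConfig, n: int, participant: str = "SIM", visit: int = 1
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw n labelled intervals from the two-component lognormal mixture."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    is_isi = rng.random(n) < cfg.mix_weight_isi
    logs = np.where(
        is_isi,
        rng.normal(cfg.isi_logmean, cfg.isi_logsd, size=n),
        rng.normal(cfg.ibi_logmean, cfg.ibi_logsd, size=n),
    )
    intervals = np.exp(logs)
    table = make_interval_table(participant, visit, intervals)
    truth = GroundTruth(
        suck_onsets_s=np.empty(0),
        suck_sizes_ml=np.empty(0),
        pauses_s=intervals,
        pause_labels=np.where(is_isi, "ISI", "IBI"),
        n_bursts=int(np.sum(~is_isi)) + 1,
        true_pc_log=_maybe_true_pc(cfg),
        suck_duration_s=cfg.suck_duration_s,
    )
    return table, truth


def _draw_pause(rng: np.random.Generator, logmean: float, logsd: float,
                floor: float) -> float:
    """Lognormal pause, resampled above the refractory floor."""
    for _ in range(1000):
        p = float(np.exp(rng.normal(logmean, logsd)))
        if p >= floor:
            return p
    raise ConfigError(
        "pause distribution is almost entirely below min_pause_s"
    )


def _raised_cosine(duration_s: float, area_ml: float, fs: float) -> np.ndarray:
    n = max(2, int(round(duration_s * fs)))
    t = np.arange(n) / n
    pulse = 1.0 - np.cos(2 * np.pi * t)
    return pulse * (area_ml * fs / pulse.sum())


def simulate_trace(cfg: SimConfig) -> tuple[VolumeTrace, GroundTruth]:
    """Render a full volume trace with burst structure and known ground truth.

    Sucks per burst are geometric (memoryless bout model) with the
    configured mean; within-burst pauses are ISI draws and between-burst
    pauses IBI draws, both floored at ``min_pause_s``. Noise is additive
    white Gaussian on the volume; artifacts are biphasic +/-50 ml/s speed
    spikes at Poisson times.
    """
    rng = np.random.default_rng(cfg.seed)
    p_geom = min(1.0, 1.0 / cfg.sucks_per_burst_mean)

    onsets: list[float] = []
    sizes: list[float] = []
    pauses: list[float] = []
    labels: list[str] = []

    t = 3.0  # lead-in
    for b in range(cfg.n_bursts):
        n_sucks = int(rng.geometric(p_geom))
        for s in range(n_sucks):
            if onsets:  # pause preceding this suck
                kind = "ISI" if s > 0 else "IBI"
                lm, ls = (
                    (cfg.isi_logmean, cfg.isi_logsd)
                    if kind == "ISI"
                    else (cfg.ibi_logmean, cfg.ibi_logsd)
                )
                pause = _draw_pause(rng, lm, ls, cfg.min_pause_s)
                pauses.append(pause)
                labels.append(kind)
                t += pause
            onsets.append(t)
            sizes.append(
                float(
                    np.clip(
                        rng.normal(cfg.suck_size_mean_ml, cfg.suck_size_sd_ml),
                        2.0,
                        5.5,
                    )
                )
            )
            t += cfg.suck_duration_s

    total_s = t + 3.0  # lead-out
    n_samples = int(round(total_s * cfg.fs))
    speed = np.zeros(n_samples)
    pulse_cache: dict[float, np.ndarray] = {}
    for onset, size in zip(onsets, sizes):
        pulse = pulse_cache.get(size)
        if pulse is None:
            pulse = _raised_cosine(cfg.suck_duration_s, size, cfg.fs)
            pulse_cache[size] = pulse
        i0 = int(round(onset * cfg.fs))
        speed[i0 : i0 + pulse.size] += pulse[: n_samples - i0]

    artifact_times = np.empty(0)
    if cfg.artifact_rate_per_min > 0:
        n_art = rng.poisson(cfg.artifact_rate_per_min * total_s / 60.0)
        artifact_times = np.sort(rng.uniform(1.0, total_s - 1.0, size=n_art))
        # ~100 ms biphasic excursions: slow enough to survive the detection
        # low-pass, well above the 20 ml/s artifact threshold
        half = max(1, int(round(0.05 * cfg.fs)))
        for at in artifact_times:
            i = int(round(at * cfg.fs))
            speed[i : i + half] += 60.0
            speed[i + half : i + 2 * half] -= 60.0

    volume = np.cumsum(speed) / cfg.fs
    if cfg.noise_sd_ml > 0:
        volume = volume + rng.normal(0.0, cfg.noise_sd_ml, size=n_samples)

    trace = VolumeTrace(
        measurement_id=f"sim-seed{cfg.seed}", fs=cfg.fs, volume=volume
    )
    truth = GroundTruth(
        suck_onsets_s=np.asarray(onsets),
        suck_sizes_ml=np.asarray(sizes),
        pauses_s=np.asarray(pauses),
        pause_labels=np.asarray(labels),
        n_bursts=cfg.n_bursts,
        true_pc_log=_maybe_true_pc(cfg),
        suck_duration_s=cfg.suck_duration_s,
        artifact_times_s=artifact_times,
    )
    return trace, truth
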