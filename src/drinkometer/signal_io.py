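"""Reading, validating and writing drinkometer volume traces and interval tables.

The canonical portable trace format is a UTF-8 CSV with header
``time_s,volume_ml`` (or ``volume_ml`` alone with an explicit sampling rate).
The device's native National Instruments TDMS triplet
(``.info``/``.tdms``/``.tdms_index``) is supported through an optional
adapter that reads a single mapped volume channel; the ``.info`` and
``.tdms_index`` companions carry undocumented calibration/condition payloads
and are treated as opaque.

Interval tables — the unit of analysis for burst-pause criterion
derivation — are plain :class:`pandas.DataFrame` objects with columns
``participant`` (str), ``visit`` (int) and ``interval_s`` (float, seconds).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    ChannelError,
    DataError,
    FormatError,
    SamplingError,
)

INTERVAL_COLUMNS = ("participant", "visit", "interval_s")

#: Relative tolerance for declaring a time grid uniform (1 part in 10^3).
_UNIFORMITY_RTOL = 1e-3


class QCStatus(str, Enum):
    """Inclusion status of a measurement after quality control."""

    INCLUDED = "included"
    EXCLUDED_INTERFERENCE = "excluded_interference"
    EXCLUDED_OTHER = "excluded_other"


@dataclass
class VolumeTrace:
    """Uniformly sampled cumulative consumed-volume signal.

    Parameters
    ----------
    measurement_id : str
        Label identifying the measurement (typically participant + visit).
    fs : float
        Sampling frequency in Hz.
    volume : numpy.ndarray
        Cumulative consumed volume in ml, one value per sample.
    t0 : float
        Time of the first sample in seconds (default 0); the trace covers
        the closed interval ``[t0, t0 + (n - 1) / fs]``.
    """

    measurement_id: str
    fs: float
    volume: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        if self.fs <= 0:
            raise SamplingError(f"fs must be positive, got {self.fs}")
        if self.volume.ndim != 1 or self.volume.size == 0:
            raise DataError("volume must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.volume)):
            raise DataError("volume contains NaN or infinite values")

    @property
    def n(self) -> int:
        return int(self.volume.size)

    @property
    def duration_s(self) -> float:
        return (self.n - 1) / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n) / self.fs


@dataclass
class MeasurementMeta:
    """Identity and QC status of one measurement."""

    participant: str
    visit: int = 1
    source_files: list[str] = field(default_factory=list)
    qc_status: QCStatus = QCStatus.INCLUDED

    def __post_init__(self) -> None:
        self.qc_status = QCStatus(self.qc_status)
        if self.visit < 1:
            raise FormatError(f"visit must be >= 1, got {self.visit}")


@dataclass
class ChannelMap:
    """Where the volume lives inside a TDMS file.

    ``volume_channel`` is a ``"group/channel"`` path; ``unit_scale`` converts
    the stored unit to ml (e.g. 1000 for litres).
    """

    volume_channel: str
    time_channel: str | None = None
    unit_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.unit_scale <= 0:
            raise FormatError(f"unit_scale must be positive, got {self.unit_scale}")


def infer_fs(time_s: np.ndarray) -> float:
    """Infer the sampling frequency from a time axis.

    The axis must be strictly increasing and uniform within one part in
    10^3 of the median spacing; otherwise a :class:`SamplingError` is raised.
    """
    time_s = np.asarray(time_s, dtype=float)
    if time_s.size < 2:
        raise SamplingError("need at least 2 time samples to infer fs")
    dt = np.diff(time_s)
    if np.any(dt <= 0):
        raise SamplingError("time axis is not strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > _UNIFORMITY_RTOL * med:
        raise SamplingError(
            "time axis is not uniform within 0.1% of the median spacing"
        )
    return 1.0 / med


def read_trace_csv(
    path: str | os.PathLike,
    fs: float | None = None,
    measurement_id: str | None = None,
) -> VolumeTrace:
    """Read a volume trace from the canonical CSV dialect.

    The file must contain a ``volume_ml`` column and either a ``time_s``
    column (from which ``fs`` is inferred and verified uniform) or an
    explicit ``fs`` argument.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"could not parse {path}: {exc}") from exc

    if "volume_ml" not in df.columns:
        raise FormatError(f"{path}: missing required column 'volume_ml'")
    volume = df["volume_ml"].to_numpy(dtype=float)
    if np.any(~np.isfinite(volume)):
        raise DataError(f"{path}: volume_ml contains NaN or non-finite values")

    t0 = 0.0
    if "time_s" in df.columns:
        time_s = df["time_s"].to_numpy(dtype=float)
        inferred = infer_fs(time_s)
        if fs is not None and abs(inferred - fs) > _UNIFORMITY_RTOL * fs:
            raise SamplingError(
                f"{path}: explicit fs={fs} disagrees with inferred fs={inferred:.6g}"
            )
        fs = inferred
        t0 = float(time_s[0])
    elif fs is None:
        raise FormatError(
            f"{path}: no time_s column; an explicit fs is required"
        )

    return VolumeTrace(
        measurement_id=measurement_id or path.stem,
        fs=float(fs),
        volume=volume,
        t0=t0,
    )


def write_trace_csv(trace: VolumeTrace, path: str | os.PathLike) -> Path:
    """Write a trace in the canonical ``time_s,volume_ml`` dialect."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.times(), "volume_ml": trace.volume})
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_trace_tdms(
    tdms_path: str | os.PathLike,
    channel_map: ChannelMap,
    fs: float | None = None,
    measurement_id: str | None = None,
) -> VolumeTrace:
    """Read a volume trace from a National Instruments TDMS file.

    Only the mapped volume channel is read; the ``.info`` and
    ``.tdms_index`` companion files are ignored if present. Requires the
    optional ``npTDMS`` dependency.
    """
    tdms_path = Path(tdms_path)
    if not tdms_path.exists():
        raise FileNotFoundError(f"TDMS file not found: {tdms_path}")
    try:
        from nptdms import TdmsFile
    except ImportError as exc:
        raise ImportError(
            "reading TDMS files requires the optional 'npTDMS' package "
            "(pip install drinkometer[tdms])"
        ) from exc

    with TdmsFile.open(str(tdms_path)) as f:
        group_name, _, channel_name = channel_map.volume_channel.partition("/")
        try:
            channel = f[group_name][channel_name]
        except KeyError as exc:
            raise ChannelError(
                f"channel '{channel_map.volume_channel}' not found in {tdms_path}"
            ) from exc
        volume = np.asarray(channel[:], dtype=float) * channel_map.unit_scale
        if fs is None:
            try:
                fs = 1.0 / channel.properties["wf_increment"]
            except (KeyError, ZeroDivisionError):
                raise SamplingError(
                    f"{tdms_path}: channel has no wf_increment; pass fs explicitly"
                )
    return VolumeTrace(
        measurement_id=measurement_id or tdms_path.stem,
        fs=float(fs),
        volume=volume,
    )


def make_interval_table(
    participant: str | Sequence[str],
    visit: int | Sequence[int],
    intervals: Sequence[float],
) -> pd.DataFrame:
    """Assemble a validated interval table from labels and interval values."""
    intervals = np.asarray(intervals, dtype=float)
    n = intervals.size
    if np.isscalar(participant) or isinstance(participant, str):
        participant = [participant] * n
    if np.isscalar(visit):
        visit = [visit] * n
    df = pd.DataFrame(
        {
            "participant": pd.Series(participant, dtype=str),
            "visit": pd.Series(visit, dtype=int),
            "interval_s": intervals,
        }
    )
    return validate_interval_table(df)


def validate_interval_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check interval-table invariants: required columns, finite positive intervals."""
    missing = [c for c in INTERVAL_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"interval table missing columns: {missing}")
    iv = table["interval_s"].to_numpy(dtype=float)
    if iv.size and (np.any(~np.isfinite(iv)) or np.any(iv <= 0)):
        raise DataError("interval_s values must be finite and strictly positive")
    return table


def read_interval_csv(path: str | os.PathLike) -> pd.DataFrame:
    """Read an interval table (``participant,visit,interval_s``)."""
    df = pd.read_csv(path, dtype={"participant": str}, float_precision="round_trip")
    df = validate_interval_table(df)
    df["visit"] = df["visit"].astype(int)
    return df[list(INTERVAL_COLUMNS)]


def write_interval_table(table: pd.DataFrame, path: str | os.PathLike) -> Path:
    """Write an interval table to CSV at full stored precision.

    ``read_interval_csv(write_interval_table(t, p))`` reproduces ``t`` exactly.
    """
    validate_interval_table(table)
    path = Path(path)
    table[list(INTERVAL_COLUMNS)].to_csv(path, index=False, float_format="%.17g")
    return path
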