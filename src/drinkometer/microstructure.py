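"""Burst segmentation and macro-/microstructural parameter tables.

A burst is a maximal run of consecutive sucks whose internal pauses are
all shorter than the pause criterion. Parameters split into a
PC-independent set describing sucks (count, total volume, meal duration,
mean suck size, mean within-burst pause) and a PC-dependent set describing
bursts (count, mean sucks per burst, mean burst size and duration, mean
inter-burst interval). The column roster is held in
:data:`PARAMETER_COLUMNS` and is extensible; undefined means are emitted
as missing values, never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bpcd import PauseCriterion
from .detection import SuckEvent
from .signal_io import MeasurementMeta

#: Output columns of the parameter table, in order.
PARAMETER_COLUMNS = [
    "participant",
    "visit",
    "pc_s",
    # PC-independent (suck level)
    "n_sucks",
    "total_volume_ml",
    "meal_duration_s",
    "mean_suck_size_ml",
    "mean_ISI_s",
    # PC-dependent (burst level)
    "n_bursts",
    "mean_sucks_per_burst",
    "mean_burst_size_ml",
    "mean_burst_duration_s",
    "mean_IBI_s",
]


@dataclass(frozen=True)
class Burst:
    """A cluster of consecutive sucks separated by pauses below the criterion."""

    suck_indices: tuple[int, ...]
    start_s: float
    end_s: float
    size_ml: float

    @property
    def n_sucks(self) -> int:
        return len(self.suck_indices)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _pc_seconds(pc: PauseCriterion | float) -> float:
    return pc.pc_s if isinstance(pc, PauseCriterion) else float(pc)


def segment_bursts(
    sucks: list[SuckEvent], pc: PauseCriterion | float
) -> list[Burst]:
    """Greedy left-to-right burst segmentation.

    A new burst starts whenever the pause (previous offset to next onset)
    reaches the criterion; every suck belongs to exactly one burst.
    """
    pc_s = _pc_seconds(pc)
    bursts: list[Burst] = []
    current: list[int] = []
    for i, suck in enumerate(sucks):
        if current and suck.onset_s - sucks[current[-1]].offset_s >= pc_s:
            bursts.append(_make_burst(sucks, current))
            current = []
        current.append(i)
    if current:
        bursts.append(_make_burst(sucks, current))
    return bursts


def _make_burst(sucks: list[SuckEvent], indices: list[int]) -> Burst:
    return Burst(
        suck_indices=tuple(indices),
        start_s=sucks[indices[0]].onset_s,
        end_s=sucks[indices[-1]].offset_s,
        size_ml=float(sum(sucks[i].size_ml for i in indices)),
    )


def measurement_parameters(
    sucks: list[SuckEvent], meta: MeasurementMeta, pc: PauseCriterion | float
) -> dict:
    """One parameter-table row for a single measurement."""
    pc_s = _pc_seconds(pc)
    row: dict = {
        "participant": meta.participant,
        "visit": meta.visit,
        "pc_s": pc_s,
        "n_sucks": len(sucks),
        "total_volume_ml": math.nan,
        "meal_duration_s": math.nan,
        "mean_suck_size_ml": math.nan,
        "mean_ISI_s": math.nan,
        "n_bursts": 0,
        "mean_sucks_per_burst": math.nan,
        "mean_burst_size_ml": math.nan,
        "mean_burst_duration_s": math.nan,
        "mean_IBI_s": math.nan,
    }
    if not sucks:
        return row

    sizes = np.array([s.size_ml for s in sucks])
    pauses = np.array(
        [b.onset_s - a.offset_s for a, b in zip(sucks, sucks[1:])]
    )
    row["total_volume_ml"] = float(sizes.sum())
    row["meal_duration_s"] = float(sucks[-1].offset_s - sucks[0].onset_s)
    row["mean_suck_size_ml"] = float(sizes.mean())
    isis = pauses[pauses < pc_s]
    if isis.size:
        row["mean_ISI_s"] = float(isis.mean())

    bursts = segment_bursts(sucks, pc)
    row["n_bursts"] = len(bursts)
    row["mean_sucks_per_burst"] = float(np.mean([b.n_sucks for b in bursts]))
    row["mean_burst_size_ml"] = float(np.mean([b.size_ml for b in bursts]))
    row["mean_burst_duration_s"] = float(np.mean([b.duration_s for b in bursts]))
    if len(bursts) >= 2:
        ibis = [
            b.start_s - a.end_s for a, b in zip(bursts, bursts[1:])
        ]
        row["mean_IBI_s"] = float(np.mean(ibis))
    return row


def build_parameter_table(
    measurements: list[tuple[list[SuckEvent], MeasurementMeta]],
    pc: PauseCriterion | float,
) -> pd.DataFrame:
    """Parameter table with one row per measurement under a common criterion."""
    rows = [measurement_parameters(sucks, meta, pc) for sucks, meta in measurements]
    return pd.DataFrame(rows, columns=PARAMETER_COLUMNS)
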