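"""Post-hoc verification of a pause criterion with Kaplan-Meier analysis.

For each candidate criterion, the set of intervals below it (the ISIs it
would extract) is treated as a group of fully observed event times; with no
censoring the Kaplan-Meier product-limit estimate coincides with the
empirical survival function S(t) = #(intervals > t) / n. Groups obtained
under different criteria are compared with a log-rank test, each curve is
summarised by the quotient of its median event time and the criterion that
produced it, and per-group interval histograms ("residuals") are reported
in 0.25 s bins.

Censoring is deliberately out of scope: a criterion truncates the *set* of
intervals, not the observation window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .errors import ComparisonError, EmptyGroupError, UndefinedMedianError
from .signal_io import validate_interval_table


@dataclass
class KMCurve:
    """A Kaplan-Meier survival curve for one group of intervals."""

    group_label: str
    event_times: np.ndarray
    survival: np.ndarray
    n: int
    intervals: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def survival_at(self, t) -> np.ndarray:
        """Right-continuous step-function value S(t)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]


@dataclass
class LogRankResult:
    """Omnibus log-rank comparison across groups."""

    chi2: float
    df: int
    p: float


@dataclass
class MedianQuotient:
    """KM median of a curve expressed as a percentage of its criterion."""

    pc_s: float
    median_s: float
    quotient_pct: int


def km_estimate(intervals, label: str = "all") -> KMCurve:
    """Product-limit survival estimate of a fully observed interval set."""
    intervals = np.asarray(intervals, dtype=float)
    if intervals.size == 0:
        raise EmptyGroupError(f"group {label!r} has no intervals")
    kmf = KaplanMeierFitter()
    kmf.fit(intervals, event_observed=np.ones(intervals.size))
    sf = kmf.survival_function_
    # drop the t=0 anchor row; keep one step per distinct event time
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = times > 0
    return KMCurve(
        group_label=label,
        event_times=times[keep],
        survival=surv[keep],
        n=int(intervals.size),
        intervals=np.sort(intervals),
    )


def compare_pcs(
    table: pd.DataFrame, pcs: list[float]
) -> tuple[list[KMCurve], LogRankResult]:
    """KM curves of the ISI sets extracted under each criterion, plus log-rank.

    For each pc the group is ``{interval < pc}``; an infinite pc extracts
    every interval (the "all" curve). The log-rank test spans the
    finite-criterion groups only. Criteria yielding empty groups are
    dropped with a warning; fewer than two surviving finite groups is an
    error.
    """
    validate_interval_table(table)
    if len(pcs) < 2:
        raise ComparisonError("need at least 2 criteria to compare")
    iv = table["interval_s"].to_numpy(dtype=float)

    curves: list[KMCurve] = []
    finite_groups: list[tuple[float, np.ndarray]] = []
    for pc in sorted(pcs):
        group = iv if np.isinf(pc) else iv[iv < pc]
        label = "all" if np.isinf(pc) else f"PC={pc:g}s"
        if group.size == 0:
            warnings.warn(f"criterion {pc} extracts no intervals; dropped", stacklevel=2)
            continue
        curves.append(km_estimate(group, label))
        if np.isfinite(pc):
            finite_groups.append((pc, group))

    if len(finite_groups) < 2:
        raise ComparisonError(
            "fewer than 2 non-empty finite-criterion groups remain"
        )
    durations = np.concatenate([g for _, g in finite_groups])
    labels = np.concatenate(
        [np.full(g.size, i) for i, (_, g) in enumerate(finite_groups)]
    )
    res = multivariate_logrank_test(
        durations, labels, event_observed=np.ones(durations.size)
    )
    return curves, LogRankResult(
        chi2=float(res.test_statistic),
        df=len(finite_groups) - 1,
        p=float(res.p_value),
    )


def quotient_pct(median_s: float, pc_s: float) -> int:
    """Median event time as a nearest-integer percentage of the criterion."""
    return int(round(100.0 * median_s / pc_s))


def median_quotient(curve: KMCurve, pc_s: float) -> MedianQuotient:
    """Smallest event time where S(t) <= 0.5, as a percentage of the criterion."""
    below = curve.survival <= 0.5
    if not below.any():
        raise UndefinedMedianError(
            f"curve {curve.group_label!r} never reaches 50% probability"
        )
    median_s = float(curve.event_times[np.argmax(below)])
    return MedianQuotient(
        pc_s=pc_s, median_s=median_s, quotient_pct=quotient_pct(median_s, pc_s)
    )


def bin_residuals(
    curves: list[KMCurve], bin_width: float = 0.25
) -> pd.DataFrame:
    """Per-group interval histograms with fixed-width bins from 0.

    Returns a tidy frame with columns ``group``, ``bin_left``, ``bin_right``
    and ``count``; each group's counts sum to its n.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    max_iv = max(
        (float(c.intervals.max()) for c in curves if c.intervals.size), default=0.0
    )
    n_bins = max(1, int(np.ceil(max_iv / bin_width + 1e-12)))
    edges = np.arange(n_bins + 1) * bin_width
    rows = []
    for c in curves:
        counts, _ = np.histogram(c.intervals, bins=edges)
        for left, right, count in zip(edges[:-1], edges[1:], counts):
            rows.append(
                {"group": c.group_label, "bin_left": left, "bin_right": right,
                 "count": int(count)}
            )
    return pd.DataFrame(rows)
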