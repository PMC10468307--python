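"""Paleotemperature ingestion and local warming period (LWP) detection.

The input is a global surface temperature (Ts) record over the past ~66 MY:
irregularly sampled (age in MYA, Ts in °C) pairs whose density increases
toward the present.  Within the record's overall cooling trend, a *local
warming period* is a rising excursion whose net temperature gain exceeds
``min_delta_t`` (default 0.5 °C, strict) and whose duration is at least
``min_duration`` (default 0.25 MY, inclusive).

Detection operationalizes that definition as segmentation at local extrema:
scanning from the oldest sample toward the present, every maximal rising
segment — from a local minimum to the following local maximum, optionally
tolerating interior dips no deeper than ``dip_tolerance`` — is emitted iff it
clears both thresholds.  Irregular sampling is honored; nothing is resampled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureSeries",
    "LwpConfig",
    "WarmingInterval",
    "read_temperature",
    "detect_lwps",
    "in_lwp",
    "range_overlaps_lwp",
    "intervals_to_frame",
]

_DURATION_EPS = 1e-9  # float slop on the inclusive duration comparison


@dataclass
class TemperatureSeries:
    """Irregular (age, Ts) samples, stored oldest first."""

    ages: np.ndarray  # MYA, strictly decreasing
    ts: np.ndarray  # °C
    source: str = ""

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.ts = np.asarray(self.ts, dtype=float)
        if self.ages.ndim != 1 or self.ages.shape != self.ts.shape:
            raise ValueError("ages and ts must be 1-D arrays of equal length")
        if len(self.ages) < 2:
            raise ValueError("temperature series needs at least 2 points")
        if np.isnan(self.ages).any() or np.isnan(self.ts).any():
            raise ValueError("temperature series contains missing values")
        if not (np.diff(self.ages) < 0).all():
            raise ValueError("ages must be strictly decreasing (oldest first)")

    def __len__(self) -> int:
        return len(self.ages)


@dataclass(frozen=True)
class LwpConfig:
    """Thresholds and knobs of the warming-period detector."""

    min_delta_t: float = 0.5  # °C, strict >
    min_duration: float = 0.25  # MY, inclusive >=
    smoothing_window: float = 0.0  # MY of centered moving-median; 0 = none
    dip_tolerance: float = 0.0  # °C of interior dip permitted inside a rise

    def __post_init__(self) -> None:
        if self.min_delta_t <= 0:
            raise ValueError("min_delta_t must be > 0")
        if self.min_duration <= 0:
            raise ValueError("min_duration must be > 0")
        if self.dip_tolerance < 0:
            raise ValueError("dip_tolerance must be >= 0")
        if self.smoothing_window < 0:
            raise ValueError("smoothing_window must be >= 0")


@dataclass(frozen=True)
class WarmingInterval:
    """One detected rising excursion; start is the older bound."""

    start_age: float  # MYA (older)
    end_age: float  # MYA (younger)
    delta_t: float  # °C net rise over the segment
    duration: float  # MY, = start_age - end_age

    def __post_init__(self) -> None:
        if not self.start_age > self.end_age >= 0:
            raise ValueError(
                f"need start_age > end_age >= 0, got "
                f"({self.start_age}, {self.end_age})"
            )


def read_temperature(path) -> TemperatureSeries:
    """Read two-column (age_mya, ts_celsius) text, whitespace or comma split.

    Comment lines (``#``) are tolerated; rows are sorted oldest first and
    duplicate ages are collapsed by the mean of their temperatures.
    """
    ages, temps = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.replace(",", " ").split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two numeric columns, "
                    f"got {line.rstrip()!r}"
                )
            try:
                ages.append(float(parts[0]))
                temps.append(float(parts[1]))
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric row {line.rstrip()!r}"
                ) from None
    if len(ages) < 2:
        raise ValueError(f"{path}: temperature series needs at least 2 points")
    df = pd.DataFrame({"age": ages, "ts": temps})
    df = df.groupby("age", as_index=False)["ts"].mean()
    df = df.sort_values("age", ascending=False)
    return TemperatureSeries(
        ages=df["age"].to_numpy(), ts=df["ts"].to_numpy(), source=str(path)
    )


def _moving_median(series: TemperatureSeries, window: float) -> np.ndarray:
    half = window / 2.0
    out = np.empty_like(series.ts)
    for i, age in enumerate(series.ages):
        mask = np.abs(series.ages - age) <= half
        out[i] = np.median(series.ts[mask])
    return out


def _rising_runs(ts: np.ndarray) -> list[tuple[int, int]]:
    """Maximal strictly-increasing runs (start, end index), oldest first.

    A run starts at the last point of any preceding plateau, i.e. at the
    local minimum nearest the rise, so flat stretches never inflate a
    segment's duration.
    """
    runs = []
    start = 0
    for k in range(1, len(ts)):
        if ts[k] > ts[k - 1]:
            continue
        if k - 1 > start:
            runs.append((start, k - 1))
        start = k
    if len(ts) - 1 > start:
        runs.append((start, len(ts) - 1))
    return runs


def detect_lwps(
    series: TemperatureSeries, cfg: LwpConfig = LwpConfig()
) -> list[WarmingInterval]:
    """Detect local warming periods; intervals are disjoint, oldest first."""
    ts = series.ts
    if cfg.smoothing_window > 0:
        ts = _moving_median(series, cfg.smoothing_window)
    runs = _rising_runs(ts)

    # merge consecutive rising runs across dips no deeper than dip_tolerance;
    # at tolerance 0 this bridges exact plateaus interior to a rise
    if len(runs) > 1:
        merged: list[tuple[int, int]] = []
        cur_s, cur_e = runs[0]
        for s, e in runs[1:]:
            dip_depth = ts[cur_e] - ts[cur_e : s + 1].min()
            if dip_depth <= cfg.dip_tolerance:
                if ts[e] > ts[cur_e]:
                    cur_e = e
            else:
                merged.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((cur_s, cur_e))
        runs = merged

    out = []
    for s, e in runs:
        delta = ts[e] - ts[s]
        duration = series.ages[s] - series.ages[e]
        if delta > cfg.min_delta_t and duration >= cfg.min_duration - _DURATION_EPS:
            out.append(
                WarmingInterval(
                    start_age=float(series.ages[s]),
                    end_age=float(series.ages[e]),
                    delta_t=float(delta),
                    duration=float(duration),
                )
            )
    return out


def in_lwp(age: float, lwps: Sequence[WarmingInterval]) -> bool:
    """True iff the age lies inside a warming interval (boundaries inclusive)."""
    return any(iv.end_age <= age <= iv.start_age for iv in lwps)


def range_overlaps_lwp(
    age_range: tuple[float, float], lwps: Sequence[WarmingInterval]
) -> bool:
    """True iff [min, max] intersects any interval (closed intervals)."""
    lo, hi = age_range
    if lo > hi:
        raise ValueError(f"age_range min {lo} exceeds max {hi}")
    return any(lo <= iv.start_age and hi >= iv.end_age for iv in lwps)


def intervals_to_frame(lwps: Sequence[WarmingInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start_age": iv.start_age,
                "end_age": iv.end_age,
                "delta_t": iv.delta_t,
                "duration": iv.duration,
            }
            for iv in lwps
        ],
        columns=["start_age", "end_age", "delta_t", "duration"],
    )
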