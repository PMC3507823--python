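"""Looming-detector spike-train statistics.

Spike times are stored in milliseconds relative to the projected time of
collision (negative = before collision).  The central statistic is a rate
computed at each spike event by counting spikes in the preceding 25 ms
(half-wingbeat) window; peak extraction, binned PSTHs and threshold-crossing
times build on it.

Window convention: the window is half-open ``(t - w, t]`` and *includes* the
anchoring spike, so every spike event carries a nonzero rate.  For a
homogeneous train at rate ``r`` this convention biases the mean rate to
``r + 1/w``; the bias is documented here and asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "SpikeTrain",
    "RateSeries",
    "PeakResponse",
    "Psth",
    "rate_at_spikes",
    "peak_response",
    "individual_mean_peak",
    "psth",
    "threshold_crossings",
    "group_summary",
]

WINDOW_CONVENTION = "half-open (t-w, t], anchoring spike included"


@dataclass(frozen=True)
class SpikeTrain:
    """Spike event times (ms, signed re: collision) for one presentation."""

    individual_id: str
    stim_id: str
    presentation: int
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=float)
        if t.ndim != 1:
            raise ValueError("spike_times must be one-dimensional")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            bad = int(np.argmax(np.diff(t) <= 0)) + 1
            raise ValueError(
                f"spike_times must be strictly increasing (violation at index {bad})"
            )
        object.__setattr__(self, "spike_times", t)

    def __len__(self) -> int:
        return len(self.spike_times)


@dataclass(frozen=True)
class RateSeries:
    """Windowed rate evaluated at spike events: (t_ms, rate_hz) pairs."""

    t: np.ndarray
    rate: np.ndarray
    window_ms: float = 25.0
    convention: str = WINDOW_CONVENTION

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        r = np.asarray(self.rate, dtype=float)
        if len(t) != len(r):
            raise ValueError("t and rate must have equal length")
        if np.any(r < 0):
            raise ValueError("rates must be >= 0")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "rate", r)

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class PeakResponse:
    peak_rate: float
    peak_time: float


@dataclass(frozen=True)
class Psth:
    """Binned mean rate across presentations/individuals, with SEM."""

    bin_edges: np.ndarray
    mean_rate: np.ndarray
    sem: np.ndarray
    n: int
    bin_width: float = 25.0


def rate_at_spikes(train: SpikeTrain, window_ms: float = 25.0) -> RateSeries:
    """Windowed spike rate at each spike event.

    At each spike time ``t`` the rate is the number of spikes in the
    half-open window ``(t - window_ms, t]`` divided by the window duration,
    so a single isolated spike yields ``1000/window_ms`` Hz.
    """
    if window_ms <= 0:
        raise ValueError(f"window_ms must be > 0, got {window_ms!r}")
    t = train.spike_times
    if len(t) == 0:
        return RateSeries(t=np.empty(0), rate=np.empty(0), window_ms=window_ms)
    left = np.searchsorted(t, t - window_ms, side="right")
    counts = np.arange(1, len(t) + 1) - left
    return RateSeries(t=t, rate=counts / (window_ms / 1000.0), window_ms=window_ms)


def peak_response(series: RateSeries) -> PeakResponse:
    """Maximum rate and its time; ties broken by the latest time."""
    if len(series) == 0:
        raise ValueError("cannot take the peak of an empty rate series")
    r = series.rate
    idx = len(r) - 1 - int(np.argmax(r[::-1]))
    return PeakResponse(peak_rate=float(r[idx]), peak_time=float(series.t[idx]))


def individual_mean_peak(
    trains: Iterable[SpikeTrain], window_ms: float = 25.0
) -> float:
    """Mean of per-presentation peak rates for one individual x stimulus."""
    peaks = [
        peak_response(rate_at_spikes(tr, window_ms)).peak_rate for tr in trains
    ]
    if not peaks:
        raise ValueError("need at least one spike train")
    return float(np.mean(peaks))


def psth(
    trains: Iterable[SpikeTrain],
    bin_ms: float = 25.0,
    t_range: Tuple[float, float] = (-500.0, 0.0),
) -> Psth:
    """Binned mean spike rate with SEM across individuals.

    Aggregation follows the repeated-measures design: each presentation's
    binned rate (count / bin duration) is averaged within individual first,
    and the mean +/- SEM is then taken across the individual means.
    """
    if bin_ms <= 0:
        raise ValueError(f"bin_ms must be > 0, got {bin_ms!r}")
    t0, t1 = t_range
    if t1 <= t0:
        raise ValueError(f"empty bin range {t_range!r}")
    n_bins = int(round((t1 - t0) / bin_ms))
    edges = t0 + bin_ms * np.arange(n_bins + 1)
    by_individual: Dict[str, List[np.ndarray]] = {}
    for tr in trains:
        counts, _ = np.histogram(tr.spike_times, bins=edges)
        by_individual.setdefault(tr.individual_id, []).append(
            counts / (bin_ms / 1000.0)
        )
    if not by_individual:
        raise ValueError("need at least one spike train")
    ind_means = np.vstack(
        [np.mean(rates, axis=0) for rates in by_individual.values()]
    )
    n = ind_means.shape[0]
    mean = ind_means.mean(axis=0)
    sem = (
        ind_means.std(axis=0, ddof=1) / np.sqrt(n)
        if n > 1
        else np.zeros_like(mean)
    )
    return Psth(bin_edges=edges, mean_rate=mean, sem=sem, n=n, bin_width=bin_ms)


def threshold_crossings(
    series: RateSeries, threshold_hz: float = 150.0
) -> Tuple[Optional[float], float]:
    """First suprathreshold time and the span spent at/above threshold.

    Returns ``(first_crossing_t, time_above)``: the first time with
    ``rate >= threshold_hz`` (or ``None`` if never reached) and the span in
    ms between the first and last suprathreshold points (0 if none or one).
    """
    if threshold_hz <= 0:
        raise ValueError(f"threshold_hz must be > 0, got {threshold_hz!r}")
    above = series.rate >= threshold_hz
    if not np.any(above):
        return (None, 0.0)
    idx = np.flatnonzero(above)
    return (float(series.t[idx[0]]), float(series.t[idx[-1]] - series.t[idx[0]]))


def group_summary(values: Sequence[float]) -> Tuple[float, float, int]:
    """Mean, SEM (sample SD / sqrt(n); 0 for n=1) and n across individuals."""
    v = np.asarray(list(values), dtype=float)
    if len(v) < 1:
        raise ValueError("need at least one value")
    n = len(v)
    sem = float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return (float(np.mean(v)), sem, n)
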