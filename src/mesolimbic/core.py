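"""Shared data containers for spike-train and behavioral analyses.

The atoms of every analysis in this package are a :class:`SpikeTrain`
(one unit's sorted spike times plus region metadata) and a
:class:`TrialTable` (per-trial stimulus, action, reward and event times).
Both serialize to tidy delimited tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpikeTrain", "TrialTable", "bin_spike_counts", "peri_event_counts"]


@dataclass
class SpikeTrain:
    """One unit's spike times in seconds, sorted and nonnegative."""

    unit_id: str
    times_s: np.ndarray
    region: str = "VS"
    session_id: str = ""

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.ndim != 1:
            raise ValueError("spike times must be a 1-D array")
        if self.times_s.size and np.any(np.diff(self.times_s) < 0):
            raise ValueError(f"spike times of {self.unit_id} must be sorted")
        if self.times_s.size and self.times_s[0] < 0:
            raise ValueError("spike times must be nonnegative")

    @property
    def n_spikes(self) -> int:
        return int(self.times_s.size)

    def rate(self, span_s: float | None = None) -> float:
        """Mean firing rate over ``span_s`` (default: first-to-last spike)."""
        if span_s is None:
            if self.n_spikes < 2:
                return 0.0
            span_s = self.times_s[-1] - self.times_s[0]
        return self.n_spikes / span_s if span_s > 0 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"unit_id": self.unit_id, "region": self.region, "time_s": self.times_s}
        )


@dataclass
class TrialTable:
    """Per-trial record of a go/no-go session.

    Columns of ``df``: trial (index), odor ('A'|'B'), cs_plus (bool: odor is
    the currently rewarded one), action ('lick'|'restrain'), reward (0|1),
    correct (bool), phase ('original'|'reversal' or 'pre'|'pairing'|'post'),
    onset_s (odor-onset time), reward_s (NaN if none).
    """

    df: pd.DataFrame
    complete: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"odor", "phase", "onset_s"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")
        if not self.df["onset_s"].is_monotonic_increasing:
            raise ValueError("trial onsets must be increasing")

    def __len__(self) -> int:
        return len(self.df)

    def phase(self, name: str) -> pd.DataFrame:
        return self.df[self.df["phase"] == name]

    def onsets(self, odor: str | None = None, phase: str | None = None) -> np.ndarray:
        sel = self.df
        if odor is not None:
            sel = sel[sel["odor"] == odor]
        if phase is not None:
            sel = sel[sel["phase"] == phase]
        return sel["onset_s"].to_numpy()


def bin_spike_counts(
    times_s: np.ndarray, delta_s: float, span: tuple[float, float]
) -> np.ndarray:
    """Spike counts in half-open bins ``[k*delta, (k+1)*delta)`` covering span.

    The number of bins is ``ceil((t1 - t0)/delta)``; every spike with
    ``t0 <= t < t0 + n_bins*delta`` is counted exactly once.
    """
    if delta_s <= 0:
        raise ValueError("bin width must be positive")
    t0, t1 = span
    if t1 <= t0:
        raise ValueError("span must be nonempty")
    n_bins = int(np.ceil((t1 - t0) / delta_s - 1e-9))
    times_s = np.asarray(times_s, dtype=float)
    idx = np.floor((times_s - t0) / delta_s).astype(np.int64)
    keep = (idx >= 0) & (idx < n_bins)
    return np.bincount(idx[keep], minlength=n_bins)


def peri_event_counts(
    times_s: np.ndarray,
    event_times: np.ndarray,
    window: tuple[float, float],
    bin_s: float | None = None,
) -> np.ndarray:
    """Spike counts per event, either one scalar per event (``bin_s`` None)
    or an events x bins matrix of counts in bins of ``bin_s`` tiling window."""
    times_s = np.asarray(times_s, dtype=float)
    event_times = np.asarray(event_times, dtype=float)
    a, b = window
    if bin_s is None:
        lo = np.searchsorted(times_s, event_times + a)
        hi = np.searchsorted(times_s, event_times + b)
        return hi - lo
    n_bins = int(round((b - a) / bin_s))
    out = np.empty((event_times.size, n_bins), dtype=np.int64)
    for i, ev in enumerate(event_times):
        out[i] = bin_spike_counts(times_s, bin_s, (ev + a, ev + a + n_bins * bin_s))
    return out
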