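"""Spike detection from multichannel voltage and respiration-cycle analysis.

Detection chain: per-sample median subtraction across channels (removes
any signal common to all channels exactly), 4th-order Butterworth
band-pass 300-5000 Hz, threshold at a multiple (default 7.5x) of the raw
median absolute deviation of the filtered trace, pruning of peaks closer
than 1 ms (keeping the higher; ties broken by the earlier sample), and,
within a tetrode, keeping the timestamp of the channel with the highest
peak.  Waveforms are cut -10..+21 samples around the peak.

The MAD is taken over the whole filtered trace and the Gaussian
consistency factor 1.4826 is deliberately NOT applied: the threshold is
a multiple of the raw MAD.  Detection polarity defaults to negative-going
peaks (extracellular convention) and is configurable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeDetectionResult",
    "bandpass_filter",
    "detect_spikes",
    "sniff_frequency_change",
]

WAVEFORM_PRE, WAVEFORM_POST = 10, 21


@dataclass
class SpikeDetectionResult:
    events: pd.DataFrame          # columns: time_s, sample, group, channel, height
    waveforms: np.ndarray         # events x (pre+post+1) samples, peak channel
    threshold_per_channel: np.ndarray
    fs: float


def bandpass_filter(x: np.ndarray, fs: float, low: float = 300.0,
                    high: float = 5000.0, order: int = 4) -> np.ndarray:
    if fs <= 2 * high:
        raise ValueError(f"sampling rate {fs} Hz too low for a {high} Hz corner")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def _prune_peaks(idx: np.ndarray, height: np.ndarray, min_dist: int) -> np.ndarray:
    """Greedy pruning: accept peaks by descending height (earlier wins ties);
    reject any peak within ``min_dist`` samples of an accepted one."""
    order = np.lexsort((idx, -height))
    accepted: list[int] = []
    for j in order:
        i = idx[j]
        if all(abs(i - k) >= min_dist for k in accepted):
            accepted.append(i)
    accepted_arr = np.sort(np.array(accepted, dtype=np.int64))
    return accepted_arr


def detect_spikes(
    v: np.ndarray,
    fs: float,
    thresh_mad: float = 7.5,
    polarity: str = "neg",
    tetrode_groups: list[list[int]] | None = None,
    subtract_median: bool = True,
    min_dist_s: float = 0.001,
) -> SpikeDetectionResult:
    """Detect spikes on a channels x samples voltage array.

    ``tetrode_groups`` lists channel indices per tetrode (default: one
    group of all channels); within a group, events closer than 1 ms are
    merged keeping the channel with the highest peak.
    """
    v = np.atleast_2d(np.asarray(v, dtype=float))
    n_ch, n = v.shape
    if fs < 20_000:
        raise ValueError("sampling rate must be at least 20 kHz")
    if subtract_median and n_ch > 1:
        v = v - np.median(v, axis=0, keepdims=True)
    y = bandpass_filter(v, fs)
    if polarity == "neg":
        y_det = -y
    elif polarity == "pos":
        y_det = y
    else:
        raise ValueError("polarity must be 'neg' or 'pos'")
    mad = np.median(np.abs(y - np.median(y, axis=1, keepdims=True)), axis=1)
    thr = thresh_mad * mad
    min_dist = max(int(round(min_dist_s * fs)), 1)
    if tetrode_groups is None:
        tetrode_groups = [list(range(n_ch))]

    per_channel: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for ch in range(n_ch):
        if thr[ch] == 0:
            warnings.warn(f"channel {ch} is flat; zero detections")
            per_channel[ch] = (np.empty(0, np.int64), np.empty(0))
            continue
        x = y_det[ch]
        above = x > thr[ch]
        # local maxima among above-threshold samples
        cand = np.nonzero(above[1:-1] & (x[1:-1] >= x[:-2]) & (x[1:-1] > x[2:]))[0] + 1
        keep = _prune_peaks(cand, x[cand], min_dist)
        per_channel[ch] = (keep, x[keep])

    rows = []
    for g, chans in enumerate(tetrode_groups):
        ev = []  # (sample, channel, height)
        for ch in chans:
            idx, h = per_channel[ch]
            ev.extend(zip(idx.tolist(), [ch] * idx.size, h.tolist()))
        if not ev:
            continue
        # merge across channels: accept by descending height, earlier on ties
        ev.sort(key=lambda e: (-e[2], e[0]))
        taken: list[int] = []
        for sample, ch, h in ev:
            if all(abs(sample - s0) >= min_dist for s0 in taken):
                taken.append(sample)
                rows.append(
                    {"sample": sample, "time_s": sample / fs, "group": g,
                     "channel": ch, "height": h}
                )
    events = pd.DataFrame(rows, columns=["sample", "time_s", "group", "channel", "height"])
    events = events.sort_values("sample", kind="stable").reset_index(drop=True)
    wf_len = WAVEFORM_PRE + WAVEFORM_POST + 1
    waveforms = np.zeros((len(events), wf_len))
    for i, row in events.iterrows():
        a = int(row["sample"]) - WAVEFORM_PRE
        b = int(row["sample"]) + WAVEFORM_POST + 1
        seg = y[int(row["channel"]), max(a, 0):min(b, n)]
        waveforms[i, max(-a, 0):max(-a, 0) + seg.size] = seg
    return SpikeDetectionResult(events, waveforms, thr, fs)


def _inhalation_onsets(pressure: np.ndarray, fs: float) -> np.ndarray:
    """Inhalation onsets = negative-going zero crossings of the 1-50 Hz
    band-passed pressure signal (configurable anchor of the sniff cycle)."""
    sos = signal.butter(2, [1.0, 50.0], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, pressure)
    crossings = np.nonzero((x[:-1] >= 0) & (x[1:] < 0))[0] + 1
    return crossings / fs


def sniff_frequency_change(
    pressure: np.ndarray,
    fs: float,
    odor_onsets: np.ndarray,
    n_cycles: int = 2,
) -> pd.DataFrame:
    """Per-trial pre/post sniff-cycle frequency around each odor onset.

    For each onset, the duration of ``n_cycles`` full cycles immediately
    before and after is converted to a frequency; the ratio post/pre is
    the per-trial statistic.  Trials without enough cycles on either side
    are dropped (logged).  Phase averages are left to the caller.
    """
    if fs <= 100:
        raise ValueError("sniff trace must be sampled above 100 Hz")
    onsets_inh = _inhalation_onsets(np.asarray(pressure, dtype=float), fs)
    rows = []
    n_dropped = 0
    for k, t0 in enumerate(np.asarray(odor_onsets, dtype=float)):
        before = onsets_inh[onsets_inh <= t0]
        after = onsets_inh[onsets_inh > t0]
        if before.size < n_cycles + 1 or after.size < n_cycles + 1:
            n_dropped += 1
            logger.info("trial %d dropped: <%d full sniff cycles available", k, n_cycles)
            continue
        dur_pre = before[-1] - before[-1 - n_cycles]
        dur_post = after[n_cycles] - after[0]
        f_pre = n_cycles / dur_pre
        f_post = n_cycles / dur_post
        rows.append(
            {"trial": k, "onset_s": t0, "freq_pre_hz": f_pre,
             "freq_post_hz": f_post, "ratio": f_post / f_pre}
        )
    out = pd.DataFrame(rows, columns=["trial", "onset_s", "freq_pre_hz",
                                      "freq_post_hz", "ratio"])
    out.attrs["n_dropped"] = n_dropped
    return out
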