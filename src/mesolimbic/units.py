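"""Cell-type and response classification from firing statistics.

Ventral-striatum units are labelled by baseline-rate and ISI criteria
(separate rule sets for passive and task-engaged recordings), VTA units
by hierarchical clustering of sliding-bin auROC response traces
(type I = dopaminergic), and optogenetically tagged units by a jittered
cross-correlogram test against laser pulses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment

from .core import SpikeTrain, TrialTable, peri_event_counts

__all__ = [
    "UnitLabel",
    "AuROCTrace",
    "classify_vs_passive",
    "classify_vs_active",
    "auroc",
    "auroc_trace",
    "cluster_vta",
    "opto_tag",
    "response_class",
]

SPN_RATE_PASSIVE_HZ = 5.0
SPN_RATE_ACTIVE_HZ = 2.0
FS_RATE_HZ = 12.0
CHAT_ISI_CV_MAX = 1.2
CHAT_SHORT_ISI_S = 0.060
CHAT_SHORT_ISI_FRAC_MAX = 0.20
SPN_PAUSE_S = 2.0
SPN_PAUSE_FRAC_MIN = 1e-4
DRIFT_MAX = 0.10
FLUCTUATION_MAX = 0.20


@dataclass
class UnitLabel:
    unit_id: str
    label: str               # SPN | FS | ChAT | DAN_typeI | typeII | typeIII | unclassified | excluded
    evidence: dict = field(default_factory=dict)


def _baseline_rates_per_trial(u: SpikeTrain, trials: TrialTable,
                              window: tuple[float, float] = (-1.0, 0.0)) -> np.ndarray:
    onsets = trials.df["onset_s"].to_numpy()
    counts = peri_event_counts(u.times_s, onsets, window)
    return counts / (window[1] - window[0])


def classify_vs_passive(
    u: SpikeTrain,
    trials: TrialTable,
    n_blocks: int = 3,
    n_habituation_trials: int = 10,
    baseline_window: tuple[float, float] = (-5.0, 0.0),
) -> UnitLabel:
    """Passive-paradigm rule: SPN iff baseline rate < 5 Hz, gated on
    baseline stability (start-to-end drift < 10%, intermittent fluctuation
    <= 20% of the session mean, measured on trial-blocked baseline rates).

    The first ``n_habituation_trials`` odor trials are excluded from all
    response statistics downstream; the returned evidence records the
    index from which trials are usable.  The stability gate uses a long
    pre-onset window (default 5 s) blocked into session thirds so that
    estimator noise at these low rates does not masquerade as drift.
    """
    rates = _baseline_rates_per_trial(u, trials, baseline_window)
    if rates.size < n_blocks:
        raise ValueError("too few trials to define a baseline")
    blocks = np.array_split(rates, n_blocks)
    block_means = np.array([b.mean() for b in blocks])
    mean_rate = rates.mean()
    if mean_rate == 0:
        drift = 0.0
        fluct = 0.0
    else:
        ref = block_means[0] if block_means[0] > 0 else mean_rate
        drift = abs(block_means[-1] - block_means[0]) / ref
        fluct = np.max(np.abs(block_means - mean_rate)) / mean_rate
    stable = (drift < DRIFT_MAX) and (fluct <= FLUCTUATION_MAX)
    evidence = {
        "baseline_hz": mean_rate,
        "drift": drift,
        "fluctuation": fluct,
        "stable": stable,
        "first_usable_trial": n_habituation_trials,
    }
    if not stable:
        return UnitLabel(u.unit_id, "excluded", evidence)
    label = "SPN" if mean_rate < SPN_RATE_PASSIVE_HZ else "unclassified"
    return UnitLabel(u.unit_id, label, evidence)


def classify_vs_active(u: SpikeTrain) -> UnitLabel:
    """Task-engaged rule set based on overall rate and ISI statistics.

    rate < 2 Hz -> SPN; rate > 12 Hz -> excluded fast-spiking;
    2-12 Hz -> cholinergic iff ISI CV < 1.2 and short ISIs (<60 ms) are
    at most 20% of all ISIs; otherwise SPN iff the unit ever pauses
    (fraction of ISIs > 2 s exceeds 1e-4), else fast-spiking.
    """
    isis = np.diff(u.times_s)
    if isis.size < 100:
        return UnitLabel(u.unit_id, "unclassified", {"n_isis": int(isis.size)})
    rate = u.rate()
    cv = isis.std(ddof=1) / isis.mean()
    frac_short = np.mean(isis < CHAT_SHORT_ISI_S)
    frac_pause = np.mean(isis > SPN_PAUSE_S)
    evidence = {
        "rate_hz": rate,
        "isi_cv": cv,
        "frac_isi_lt_60ms": frac_short,
        "frac_isi_gt_2s": frac_pause,
    }
    if rate < SPN_RATE_ACTIVE_HZ:
        return UnitLabel(u.unit_id, "SPN", evidence)
    if rate > FS_RATE_HZ:
        return UnitLabel(u.unit_id, "FS", evidence)
    if cv < CHAT_ISI_CV_MAX and frac_short <= CHAT_SHORT_ISI_FRAC_MAX:
        return UnitLabel(u.unit_id, "ChAT", evidence)
    if frac_pause > SPN_PAUSE_FRAC_MIN:
        return UnitLabel(u.unit_id, "SPN", evidence)
    return UnitLabel(u.unit_id, "FS", evidence)


def auroc(response: np.ndarray, control: np.ndarray) -> float:
    """Area under the ROC separating two count distributions.

    Computed by direct comparison counting, P(X > Y) + 0.5 P(X = Y),
    which equals the normalized rank-sum statistic U/(n1*n2).
    """
    response = np.asarray(response, dtype=float)
    control = np.sort(np.asarray(control, dtype=float))
    if control.size == 0 or response.size == 0:
        raise ValueError("empty distribution")
    lo = np.searchsorted(control, response, side="left")
    hi = np.searchsorted(control, response, side="right")
    greater = lo.sum()
    ties = (hi - lo).sum()
    return (greater + 0.5 * ties) / (response.size * control.size)


@dataclass
class AuROCTrace:
    unit_id: str
    event: str
    bin_starts_s: np.ndarray
    values: np.ndarray
    responsive: bool
    friedman_p: float


def auroc_trace(
    u: SpikeTrain,
    event_times: np.ndarray,
    event: str = "CS+",
    window: tuple[float, float] = (-0.5, 1.0),
    bin_s: float = 0.2,
    step_s: float = 0.05,
    baseline_span_s: float = 2.0,
    alpha: float = 0.05,
) -> AuROCTrace:
    """Sliding-bin auROC of trial spike counts against a pre-trial control.

    The control distribution pools the counts of non-overlapping 200-ms
    bins tiling the 2 s before each event.  A unit is marked responsive
    when a Friedman test across the per-trial layout of baseline and
    sliding response bins rejects at ``alpha``.
    """
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size < 10:
        raise ValueError("need at least 10 trials per event")
    n_base_bins = int(round(baseline_span_s / bin_s))
    base = peri_event_counts(u.times_s, event_times, (-baseline_span_s, 0.0), bin_s)
    control = base.ravel()
    if control.size == 0:
        raise ValueError("empty control distribution")
    starts = np.arange(window[0], window[1] - bin_s + 1e-9, step_s)
    values = np.empty(starts.size)
    resp_bins = np.empty((event_times.size, starts.size))
    for j, t0 in enumerate(starts):
        counts = peri_event_counts(u.times_s, event_times + t0, (0.0, bin_s))
        resp_bins[:, j] = counts
        values[j] = auroc(counts, control)
    # Friedman blocks = trials; treatments = baseline bins + sliding bins
    layout = np.hstack([base, resp_bins])
    try:
        _, p = stats.friedmanchisquare(*layout.T)
    except ValueError:  # identical columns everywhere
        p = 1.0
    if np.isnan(p):
        p = 1.0
    return AuROCTrace(u.unit_id, event, starts, values, bool(p < alpha), float(p))


# archetype templates for the three VTA response classes, expressed as
# deviations of the auROC trace from 0.5 (excited = +, inhibited = -)
def _templates(n_cs: int, n_us: int) -> np.ndarray:
    t1 = np.concatenate([np.full(n_cs, 0.75), np.full(n_us, 0.75)])   # I: CS+ & US excited
    t2 = np.concatenate([np.full(n_cs, 0.70), np.full(n_us, 0.50)])   # II: CS+ only
    t3 = np.concatenate([np.full(n_cs, 0.40), np.full(n_us, 0.35)])   # III: inhibited
    return np.vstack([t1, t2, t3])


def cluster_vta(
    traces: list[tuple[AuROCTrace, AuROCTrace]],
    n_clusters: int = 3,
) -> list[UnitLabel]:
    """Agglomerative clustering (L1 metric, average linkage, cut at 3) of
    concatenated CS+ and US auROC traces; clusters are mapped to type
    I/II/III by least-L1 assignment of cluster means to archetype
    templates (type I = phasic CS+ and US excitation = dopaminergic)."""
    if len(traces) < n_clusters:
        raise ValueError(f"need at least {n_clusters} responsive units")
    X = np.vstack([np.concatenate([cs.values, us.values]) for cs, us in traces])
    Z = linkage(X, method="average", metric="cityblock")
    assign = fcluster(Z, n_clusters, criterion="maxclust")
    n_cs = traces[0][0].values.size
    n_us = traces[0][1].values.size
    templ = _templates(n_cs, n_us)
    means = np.vstack([X[assign == c].mean(axis=0) for c in range(1, n_clusters + 1)])
    cost = np.abs(means[:, None, :] - templ[None, :, :]).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    type_of_cluster = {r + 1: ("DAN_typeI", "typeII", "typeIII")[c] for r, c in zip(rows, cols)}
    return [
        UnitLabel(cs.unit_id, type_of_cluster[c], {"cluster": int(c)})
        for (cs, _us), c in zip(traces, assign)
    ]


def opto_tag(
    u: SpikeTrain,
    pulse_times: np.ndarray,
    bin_s: float = 0.001,
    max_lag_s: float = 0.020,
    jitter_s: float = 0.030,
    n_controls: int = 10_000,
    seed: int = 0,
    percentile: float = 95.0,
) -> dict:
    """Jittered cross-correlogram tagging test.

    Test CCG: 1-ms bins over lags 0-20 ms from each laser pulse.  Control
    CCGs (default 10,000) jitter every pulse independently and uniformly
    in +-30 ms.  The unit is tagged when two consecutive test bins exceed
    the 95th percentile of the pooled bins of all control CCGs.
    """
    pulse_times = np.asarray(pulse_times, dtype=float)
    if pulse_times.size < 100:
        raise ValueError("need at least 100 laser pulses")
    times = u.times_s
    if times.size:
        span = (times[0], times[-1])
        inside = (pulse_times >= span[0] - max_lag_s) & (pulse_times <= span[1])
        if inside.sum() < pulse_times.size:
            import warnings

            warnings.warn("laser pulses outside the recording span were trimmed")
        # keep all pulses anyway: absent spikes just yield empty bins
    n_bins = int(round(max_lag_s / bin_s))
    edges = np.arange(n_bins + 1) * bin_s
    # pairs (spike - pulse) within the widest window any jitter can reach
    lo, hi = -jitter_s, max_lag_s + jitter_s
    diffs = []
    pulse_idx = []
    for i, p in enumerate(pulse_times):
        a = np.searchsorted(times, p + lo)
        b = np.searchsorted(times, p + hi)
        if b > a:
            diffs.append(times[a:b] - p)
            pulse_idx.append(np.full(b - a, i))
    if not diffs:
        test = np.zeros(n_bins)
        return {"tagged": False, "test_ccg": test, "threshold": np.inf,
                "n_pairs": 0, "bin_edges_s": edges}
    diffs = np.concatenate(diffs)
    pulse_idx = np.concatenate(pulse_idx)

    def _ccg(shifted: np.ndarray) -> np.ndarray:
        idx = np.floor(shifted / bin_s).astype(np.int64)
        ok = (idx >= 0) & (idx < n_bins)
        if shifted.ndim == 1:
            return np.bincount(idx[ok], minlength=n_bins)
        rows = np.broadcast_to(np.arange(shifted.shape[0])[:, None], idx.shape)
        flat = (rows * n_bins + idx)[ok]
        return np.bincount(flat, minlength=shifted.shape[0] * n_bins).reshape(
            shifted.shape[0], n_bins
        )

    test = _ccg(diffs)
    rng = np.random.default_rng(seed)
    pooled_parts = []
    chunk = max(1, int(2e7 // max(diffs.size, 1)))
    done = 0
    while done < n_controls:
        m = min(chunk, n_controls - done)
        jit = rng.uniform(-jitter_s, jitter_s, size=(m, pulse_times.size))
        pooled_parts.append(_ccg(diffs[None, :] - jit[:, pulse_idx]))
        done += m
    pooled = np.vstack(pooled_parts)
    threshold = np.percentile(pooled.ravel(), percentile)
    above = test > threshold
    tagged = bool(np.any(above[:-1] & above[1:]))
    return {
        "tagged": tagged,
        "test_ccg": test,
        "control_pooled_percentile": float(threshold),
        "threshold": float(threshold),
        "n_pairs": int(diffs.size),
        "bin_edges_s": edges,
    }


def response_class(
    u: SpikeTrain,
    trials: TrialTable,
    phases: tuple[str, str] = ("pre", "post"),
    odor: str | None = None,
    baseline_window: tuple[float, float] = (-1.0, 0.0),
    response_window: tuple[float, float] = (0.0, 1.0),
) -> str:
    """Excitatory / inhibitory / none odor-response label.

    Excitatory: mean response rate >= 1 Hz and >= +20% versus baseline in
    either phase.  Inhibitory: baseline >= 0.5 Hz and <= -20% in either
    phase.  Evaluated phase-by-phase; excitation takes precedence.
    """
    excit = inhib = False
    for ph in phases:
        sel = trials.df[trials.df["phase"] == ph]
        if odor is not None:
            sel = sel[sel["odor"] == odor]
        onsets = sel["onset_s"].to_numpy()
        if onsets.size == 0:
            continue
        b = peri_event_counts(u.times_s, onsets, baseline_window).mean() / (
            baseline_window[1] - baseline_window[0]
        )
        rsp = peri_event_counts(u.times_s, onsets, response_window).mean() / (
            response_window[1] - response_window[0]
        )
        if rsp >= 1.0 and rsp >= 1.2 * b:
            excit = True
        if b >= 0.5 and rsp <= 0.8 * b:
            inhib = True
    if excit:
        return "excitatory"
    if inhib:
        return "inhibitory"
    return "none"
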