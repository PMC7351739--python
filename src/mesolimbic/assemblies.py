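"""Pairwise cell-assembly detection across temporal resolutions.

A pair of units forms an assembly at resolution ``delta`` and lag ``l``
(positive: the second unit follows the first) when their binned spike
counts coincide, ``C(l) = sum_k min(a_k, b_{k+l})``, more often than a
non-stationarity-robust chance level.  The null is built from spike-time
jitter surrogates: every spike of the second train is displaced uniformly
within a window wide enough to destroy coordination at all tested lags
while preserving slow rate co-modulation, and the maximum of ``C`` over
lags is recomputed per surrogate, giving family-wise control across lags
within a pair and scale.  Benjamini-Hochberg correction is applied across
pairs and scales; for each significant pair only the scale with the
lowest detection p-value is kept (pruning), with an optional second pass
restricted to sharp scales (<= 250 ms) so that patterns expressed at both
a sharp and a broad scale are not absorbed by the broad one.

With the default scale set the smallest representable nonzero lag is one
bin of the finest resolution, i.e. 10 ms; finer delays fall into lag 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import SpikeTrain, TrialTable, bin_spike_counts

logger = logging.getLogger(__name__)

__all__ = [
    "ScaleConfig",
    "AssemblyPair",
    "PairTestResult",
    "bin_counts",
    "coincidence_counts",
    "pair_test",
    "detect_and_prune",
    "lag_directionality",
    "assembly_learning_dynamics",
]


@dataclass
class ScaleConfig:
    """Tested temporal resolutions and per-resolution maximum lags."""

    deltas_s: tuple = (0.01, 0.015, 0.03, 0.05, 0.08, 0.12, 0.25, 0.35, 0.5, 0.6)
    max_lag_bins: tuple = (20, 20, 20, 20, 20, 10, 7, 5, 5, 5)
    reference_lag: int = -2
    sharp_cutoff_s: float = 0.25

    def __post_init__(self) -> None:
        if len(self.deltas_s) != len(self.max_lag_bins):
            raise ValueError("one max lag per tested resolution is required")
        if np.any(np.diff(self.deltas_s) <= 0):
            raise ValueError("resolutions must be strictly increasing")

    @property
    def min_nonzero_lag_s(self) -> float:
        """Smallest representable nonzero lag: one bin at the finest scale."""
        return float(self.deltas_s[0])

    def sharp(self) -> "ScaleConfig":
        keep = [i for i, d in enumerate(self.deltas_s) if d <= self.sharp_cutoff_s]
        return ScaleConfig(
            tuple(self.deltas_s[i] for i in keep),
            tuple(self.max_lag_bins[i] for i in keep),
            self.reference_lag,
            self.sharp_cutoff_s,
        )


def bin_counts(train: SpikeTrain, delta_s: float, span: tuple[float, float]) -> np.ndarray:
    """Half-open binning of a spike train (thin wrapper for this module)."""
    return bin_spike_counts(train.times_s, delta_s, span)


def coincidence_counts(a: np.ndarray, b: np.ndarray, max_lag: int) -> np.ndarray:
    """C(l) = sum_k min(a_k, b_{k+l}) for l in [-max_lag, +max_lag]."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("count series must have equal length")
    n = a.size
    out = np.empty(2 * max_lag + 1, dtype=np.int64)
    for i, l in enumerate(range(-max_lag, max_lag + 1)):
        if l >= 0:
            out[i] = np.minimum(a[: n - l], b[l:]).sum()
        else:
            out[i] = np.minimum(a[-l:], b[: n + l]).sum()
    return out


def _spike_bins(counts: np.ndarray) -> np.ndarray:
    """Expand a count series into one bin index per spike."""
    return np.repeat(np.arange(counts.size), counts)


def _surrogate_counts(spike_bins: np.ndarray, n_bins: int, jitter_bins: int,
                      n_surr: int, rng: np.random.Generator) -> np.ndarray:
    """Jitter each spike uniformly within +-jitter_bins (wrapping at the
    edges) and rebin; returns an (n_surr, n_bins) int matrix."""
    shifts = rng.integers(-jitter_bins, jitter_bins + 1,
                          size=(n_surr, spike_bins.size))
    idx = (spike_bins[None, :] + shifts) % n_bins
    flat = (np.arange(n_surr)[:, None] * n_bins + idx).ravel()
    return np.bincount(flat, minlength=n_surr * n_bins).reshape(n_surr, n_bins)


@dataclass
class PairTestResult:
    delta_s: float
    lags: np.ndarray
    counts: np.ndarray            # observed C(l)
    best_lag: int
    p_value: float
    z_best: float                 # standardized excess at the best lag
    reference_contrast: float     # C(best) - C(reference lag)
    surrogate_max_mean: float
    n_surrogates: int


def pair_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    delta_s: float,
    max_lag: int,
    reference_lag: int = -2,
    n_surrogates: int = 199,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> PairTestResult:
    """Surrogate test for excess coincidences between two count series.

    The test statistic is ``max_l C(l)``; its null distribution comes from
    jitter surrogates of the second series (jitter half-width
    ``max(4, max_lag + 2)`` bins, chosen to exceed every tested lag while
    remaining short against behavioral-timescale rate drifts).  The best
    lag is the one with the largest standardized excess over the
    surrogate ensemble.
    """
    counts_a = np.asarray(counts_a, dtype=np.int64)
    counts_b = np.asarray(counts_b, dtype=np.int64)
    if counts_a.size != counts_b.size:
        raise ValueError("count series must have equal length")
    if counts_a.size < 2 * max_lag:
        raise ValueError("series shorter than twice the maximum lag")
    if rng is None:
        rng = np.random.default_rng(seed)
    lags = np.arange(-max_lag, max_lag + 1)
    n = counts_a.size
    jitter_bins = max(4, max_lag + 2)

    spike_bins_a = _spike_bins(counts_a)
    spike_bins_b = _spike_bins(counts_b)

    c_obs = coincidence_counts(counts_a, counts_b, max_lag)
    if spike_bins_b.size == 0 or spike_bins_a.size == 0:
        return PairTestResult(delta_s, lags, c_obs, 0, 1.0, 0.0, 0.0, 0.0, n_surrogates)
    # both trains are jittered independently so the surrogate ensemble
    # carries the full coincidence variance of two independent trains
    A = _surrogate_counts(spike_bins_a, n, jitter_bins, n_surrogates, rng)
    B = _surrogate_counts(spike_bins_b, n, jitter_bins, n_surrogates, rng)
    c_surr = np.empty((n_surrogates, lags.size), dtype=np.int64)
    for i, l in enumerate(lags):
        if l >= 0:
            c_surr[:, i] = np.minimum(A[:, : n - l], B[:, l:]).sum(axis=1)
        else:
            c_surr[:, i] = np.minimum(A[:, -l:], B[:, : n + l]).sum(axis=1)
    # reference-lag contrast: slow rate co-fluctuation raises C at every lag
    # alike, so differencing against the reference lag cancels it (and the
    # small rate-smoothing bias of the jitter surrogates with it)
    ref_where = np.nonzero(lags == reference_lag)[0]
    if ref_where.size:
        ref_i = int(ref_where[0])
        keep = lags != reference_lag
        d_obs = c_obs[keep] - c_obs[ref_i]
        d_surr = c_surr[:, keep] - c_surr[:, ref_i][:, None]
        lags_eff = lags[keep]
    else:  # reference outside the tested range: fall back to raw counts
        d_obs = c_obs.astype(float)
        d_surr = c_surr.astype(float)
        lags_eff = lags
    t_obs = d_obs.max()
    t_surr = d_surr.max(axis=1)
    p = (1.0 + np.sum(t_surr >= t_obs)) / (n_surrogates + 1.0)
    mu = d_surr.mean(axis=0)
    sd = d_surr.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    z = (d_obs - mu) / sd
    best_i = int(np.argmax(z))
    best_lag = int(lags_eff[best_i])
    return PairTestResult(
        delta_s, lags, c_obs, best_lag, float(p), float(z[best_i]),
        float(d_obs[best_i]), float(t_surr.mean()), n_surrogates,
    )


@dataclass
class AssemblyPair:
    unit_a: str
    unit_b: str
    label_a: str
    label_b: str
    delta_s: float
    lag_bins: int
    p_value: float
    p_adjusted: float
    z: float
    activation_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def lag_s(self) -> float:
        return self.lag_bins * self.delta_s


def _activation_times(counts_a, counts_b, lag, delta_s, t0) -> np.ndarray:
    """Times (first unit's bin start) at which the joint pattern occurs."""
    n = counts_a.size
    if lag >= 0:
        joint = np.minimum(counts_a[: n - lag], counts_b[lag:])
        k = np.nonzero(joint)[0]
    else:
        joint = np.minimum(counts_a[-lag:], counts_b[: n + lag])
        k = np.nonzero(joint)[0] - lag
    return t0 + k * delta_s


def detect_and_prune(
    trains: list[SpikeTrain],
    labels: dict[str, str] | None = None,
    cfg: ScaleConfig | None = None,
    alpha: float = 0.05,
    n_surrogates: int = 199,
    seed: int = 0,
    span: tuple[float, float] | None = None,
    sharp_second_pass: bool = True,
) -> list[AssemblyPair]:
    """Test every unit pair at every resolution; BH-correct across
    pairs x scales; keep per pair the scale with the lowest p-value.

    Detection runs on the whole recording span so patterns are found
    irrespective of when they activate.  When ``sharp_second_pass`` is
    set, pruning is repeated among the sharp scales only (<= 250 ms) and
    a pair whose optimal broad scale shadowed a sharp-scale pattern is
    reported at its best sharp scale instead.
    """
    from statsmodels.stats.multitest import multipletests

    if cfg is None:
        cfg = ScaleConfig()
    if labels is None:
        labels = {t.unit_id: t.region for t in trains}
    if len(trains) < 2:
        raise ValueError("need at least two units")
    if span is None:
        hi = max(t.times_s[-1] for t in trains if t.n_spikes)
        span = (0.0, float(hi) + 1e-9)
    rng = np.random.default_rng(seed)
    results = []  # (i, j, scale_idx, PairTestResult, counts_a, counts_b)
    for si, (delta, max_lag) in enumerate(zip(cfg.deltas_s, cfg.max_lag_bins)):
        binned = [bin_counts(t, delta, span) for t in trains]
        for i in range(len(trains)):
            for j in range(i + 1, len(trains)):
                res = pair_test(
                    binned[i], binned[j], delta, max_lag,
                    reference_lag=cfg.reference_lag,
                    n_surrogates=n_surrogates, rng=rng,
                )
                results.append((i, j, si, res, binned[i], binned[j]))
    pvals = np.array([r[3].p_value for r in results])
    reject, p_adj, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")

    def _prune(indices: list[int]) -> dict[tuple[int, int], int]:
        best: dict[tuple[int, int], int] = {}
        for k in indices:
            i, j, si, res, *_ = results[k]
            key = (i, j)
            if key not in best:
                best[key] = k
            else:
                cur = results[best[key]][3]
                if (res.p_value, -res.z_best) < (cur.p_value, -cur.z_best):
                    best[key] = k
        return best

    sig = [k for k in range(len(results)) if reject[k]]
    best = _prune(sig)
    if sharp_second_pass:
        sharp_sig = [
            k for k in sig if results[k][3].delta_s <= cfg.sharp_cutoff_s
        ]
        best_sharp = _prune(sharp_sig)
        for key, k in best_sharp.items():
            if results[best[key]][3].delta_s > cfg.sharp_cutoff_s:
                best[key] = k
    out = []
    for (i, j), k in sorted(best.items()):
        _, _, si, res, ca, cb = results[k]
        act = _activation_times(ca, cb, res.best_lag, res.delta_s, span[0])
        out.append(
            AssemblyPair(
                unit_a=trains[i].unit_id,
                unit_b=trains[j].unit_id,
                label_a=labels.get(trains[i].unit_id, ""),
                label_b=labels.get(trains[j].unit_id, ""),
                delta_s=res.delta_s,
                lag_bins=res.best_lag,
                p_value=res.p_value,
                p_adjusted=float(p_adj[k]),
                z=res.z_best,
                activation_times=act,
            )
        )
    return out


def lag_directionality(
    pairs: list[AssemblyPair],
    type_filter: tuple[str, str] | None = ("SPN", "DAN"),
) -> dict:
    """Signed-lag distribution for a label combination, oriented so that
    positive lags mean the second-type unit follows the first-type unit,
    with a two-sided sign test on the nonzero lags."""
    lags = []
    for p in pairs:
        if type_filter is None:
            lags.append(p.lag_s)
            continue
        t1, t2 = type_filter
        if p.label_a.startswith(t1) and p.label_b.startswith(t2):
            lags.append(p.lag_s)
        elif p.label_a.startswith(t2) and p.label_b.startswith(t1):
            lags.append(-p.lag_s)
    lags = np.array(lags)
    if lags.size == 0:
        logger.info("no assembly pairs match the requested label combination")
        return {"lags_s": lags, "n": 0, "sign_test_p": np.nan}
    nonzero = lags[lags != 0]
    if nonzero.size == 0:
        p = 1.0
    else:
        p = stats.binomtest(int((nonzero > 0).sum()), nonzero.size, 0.5).pvalue
    return {
        "lags_s": lags,
        "n": int(lags.size),
        "n_positive": int((lags > 0).sum()),
        "sign_test_p": float(p),
        "median_lag_s": float(np.median(lags)),
    }


def assembly_learning_dynamics(
    pair: AssemblyPair,
    trials: TrialTable,
    cs_window: tuple[float, float] = (0.0, 0.7),
    n_edge: int = 12,
) -> dict:
    """Initial-versus-late assembly activation around CS onsets.

    Per trial, the activation count is the number of joint-pattern
    occurrences inside ``cs_window`` after odor onset.  Means over the
    first and last ``n_edge`` CS+ (and CS-) trials per phase are compared
    with a paired Wilcoxon test; the per-trial series is returned as the
    regression input.
    """
    act = np.sort(pair.activation_times)
    df = trials.df
    per_trial = np.empty(len(df), dtype=np.int64)
    for k, onset in enumerate(df["onset_s"].to_numpy()):
        lo = np.searchsorted(act, onset + cs_window[0])
        hi = np.searchsorted(act, onset + cs_window[1])
        per_trial[k] = hi - lo
    out = {"per_trial_counts": per_trial, "cs_window": cs_window}
    cs_col = df["cs_plus"] if "cs_plus" in df.columns else (df["odor"] == "A")
    for name, mask in [("cs_plus", cs_col.to_numpy()), ("cs_minus", ~cs_col.to_numpy())]:
        counts = per_trial[mask]
        if counts.size < 2 * n_edge:
            logger.warning("%s: only %d trials; initial/late analysis restricted",
                           name, counts.size)
            k = counts.size // 2
        else:
            k = n_edge
        initial, late = counts[:k], counts[-k:] if k else counts[:0]
        if k == 0:
            out[name] = {"initial_mean": np.nan, "late_mean": np.nan, "p": np.nan}
            continue
        diff = late.astype(float) - initial.astype(float)
        if np.allclose(diff, 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(diff).pvalue)
        out[name] = {
            "initial_mean": float(initial.mean()),
            "late_mean": float(late.mean()),
            "p": p,
            "n_per_side": int(k),
        }
    return out
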