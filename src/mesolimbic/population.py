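"""Across-session population vectors and dopamine-pairing plasticity metrics.

Sessions are pooled unit-wise into an across-session population vector:
trials of each session are split by odor (paired / non-paired) and phase
(pre / pairing / post), averaged in consecutive groups of three, matched
across sessions either progressively (k-th group with k-th group) or by
independent per-session permutation, and truncated to the common minimum
group count ('pre' from the front, later phases from the back).

Distances between population vectors use the cosine metric
``d = 1 - x.y/(|x||y|)`` (in [0, 2]) and the length-normalized Euclidean
metric ``d = |x - y| / l`` with ``l`` the number of units.  Decoding of
paired versus non-paired responses uses PCA fitted jointly on all four
odor x phase groups followed by per-phase quadratic discriminant analysis
under leave-one-out cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA, FactorAnalysis
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.manifold import MDS
from statsmodels.stats.multitest import multipletests

from .core import SpikeTrain, TrialTable, peri_event_counts

logger = logging.getLogger(__name__)

__all__ = [
    "Paradigm",
    "PARADIGMS",
    "PopulationVector",
    "bin_session",
    "build_population_vectors",
    "cosine_distance",
    "euclidean_norm_distance",
    "deviation_from_baseline",
    "response_vectors_and_distances",
    "qda_decode",
    "qda_df_total",
    "embed_trajectories",
    "mds_responses",
]


@dataclass(frozen=True)
class Paradigm:
    """Analysis parameters tied to one experimental paradigm."""

    bin_s: float
    n_bl: int
    n_test: int
    baseline_start_s: float
    response_window_s: tuple[float, float]
    window_s: tuple[float, float]


PARADIGMS = {
    "behavioral": Paradigm(0.4, 3, 12, -1.8, (0.6, 1.8), (-2.0, 5.0)),
    "passive": Paradigm(0.25, 4, 7, -1.75, (0.5, 1.25), (-2.0, 2.0)),
}


def bin_session(
    trains: list[SpikeTrain],
    trials: TrialTable,
    bin_s: float,
    window: tuple[float, float],
) -> np.ndarray:
    """Trials x units x time-bins spike-count tensor aligned to odor onset."""
    onsets = trials.df["onset_s"].to_numpy()
    mats = [peri_event_counts(t.times_s, onsets, window, bin_s) for t in trains]
    return np.stack(mats, axis=1)


@dataclass
class PopulationVector:
    """Across-session trial-group x unit x time-bin tensors per condition."""

    counts: dict               # (odor, phase) -> groups x units x bins
    bin_s: float
    window: tuple[float, float]
    group_size: int = 3
    matching: str = "progressive"
    alignment: str = "odor-onset"
    meta: dict = field(default_factory=dict)

    @property
    def onset_bin(self) -> int:
        return int(round(-self.window[0] / self.bin_s))

    def n_units(self) -> int:
        return next(iter(self.counts.values())).shape[1]

    def bin_index(self, t_s: float) -> int:
        return int(np.floor((t_s - self.window[0]) / self.bin_s))


def _group_trials(tensor: np.ndarray, group_size: int, phase: str) -> np.ndarray:
    """Average consecutive non-overlapping groups; remainder dropped from
    the end ('pre': from the front, keeping the trials closest to pairing)."""
    n = tensor.shape[0]
    n_groups = n // group_size
    if n_groups == 0:
        raise ValueError("fewer trials than one group")
    if phase == "pre":
        tensor = tensor[n - n_groups * group_size:]
    else:
        tensor = tensor[: n_groups * group_size]
    return tensor.reshape(n_groups, group_size, *tensor.shape[1:]).mean(axis=1)


def build_population_vectors(
    sessions: list[dict],
    bin_s: float,
    window: tuple[float, float],
    group_size: int = 3,
    matching: str = "progressive",
    n_permutations: int = 300,
    seed: int = 0,
) -> PopulationVector | list[PopulationVector]:
    """Pool per-session tensors into across-session population vectors.

    Each session dict maps ``(odor, phase) -> trials x units x bins``
    tensor.  With ``matching='permuted'`` a list of ``n_permutations``
    realizations is returned, each permuting the trial-group order
    independently per session before concatenation.
    """
    if not sessions:
        raise ValueError("no sessions given")
    keys = sorted(sessions[0].keys())
    grouped = [
        {k: _group_trials(s[k], group_size, k[1]) for k in keys} for s in sessions
    ]
    n_groups = {k: min(g[k].shape[0] for g in grouped) for k in keys}
    for g in grouped:
        for k in keys:
            m = n_groups[k]
            # equalize across sessions: 'pre' loses initial groups, later
            # phases lose final groups
            g[k] = g[k][-m:] if k[1] == "pre" else g[k][:m]
    if any(g[keys[0]].shape[1] == 0 for g in grouped):
        raise ValueError("session without eligible units")

    def _concat(perm_rngs=None) -> PopulationVector:
        counts = {}
        for k in keys:
            parts = []
            for si, g in enumerate(grouped):
                x = g[k]
                if perm_rngs is not None:
                    x = x[perm_rngs[si].permutation(x.shape[0])]
                parts.append(x)
            counts[k] = np.concatenate(parts, axis=1)
        return PopulationVector(counts, bin_s, window, group_size,
                                matching=matching)

    if matching == "progressive":
        return _concat()
    if matching == "permuted":
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n_permutations):
            perm_rngs = [np.random.default_rng(rng.integers(2**31))
                         for _ in grouped]
            out.append(_concat(perm_rngs))
        return out
    raise ValueError("matching must be 'progressive' or 'permuted'")


def cosine_distance(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        logger.info("zero-norm vector: cosine distance undefined, excluded")
        return np.nan
    return float(1.0 - np.dot(x, y) / (nx * ny))


def euclidean_norm_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Euclidean distance normalized by the number of units."""
    return float(np.linalg.norm(np.asarray(x) - np.asarray(y)) / x.size)


_METRICS = {"cosine": cosine_distance, "euclidean_norm": euclidean_norm_distance}


def deviation_from_baseline(
    pv: PopulationVector,
    paradigm: str | Paradigm = "behavioral",
    odor: str = "A",
    phases: tuple[str, str] = ("pre", "post"),
    metric: str = "cosine",
) -> dict:
    """Per-bin deviation of the population vector from its own baseline.

    The baseline vector of each trial-group is the mean of ``n_bl``
    consecutive pre-onset bins starting at ``baseline_start_s``.  The
    first ``n_test`` post-onset bins are compared between the two phases
    with two-sided t-tests, Benjamini-Hochberg corrected across bins.
    """
    par = PARADIGMS[paradigm] if isinstance(paradigm, str) else paradigm
    dist = _METRICS[metric]
    b0 = pv.bin_index(par.baseline_start_s)
    if b0 < 0 or b0 + par.n_bl > pv.onset_bin:
        raise ValueError("baseline bins must precede odor onset")
    onset = pv.onset_bin
    traces = {}
    for ph in phases:
        tensor = pv.counts[(odor, ph)]
        n_groups = tensor.shape[0]
        n_post = tensor.shape[2] - onset
        d = np.empty((n_groups, n_post))
        for g in range(n_groups):
            baseline = tensor[g, :, b0: b0 + par.n_bl].mean(axis=1)
            for j in range(n_post):
                d[g, j] = dist(baseline, tensor[g, :, onset + j])
        traces[ph] = d
    n_test = min(par.n_test, traces[phases[0]].shape[1])
    pvals, tstats = [], []
    for j in range(n_test):
        a = traces[phases[0]][:, j]
        b = traces[phases[1]][:, j]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        t, p = stats.ttest_ind(a, b)
        pvals.append(p if np.isfinite(p) else 1.0)
        tstats.append(t)
    reject, p_adj, *_ = multipletests(pvals, method="fdr_bh")
    return {
        "deviation": traces,
        "metric": metric,
        "n_test": n_test,
        "t_stats": np.array(tstats),
        "p_adjusted": p_adj,
        "significant_bins": reject,
    }


def _response_vectors(pv: PopulationVector, window_s: tuple[float, float]) -> dict:
    a = pv.bin_index(window_s[0])
    b = pv.bin_index(window_s[1] - 1e-9) + 1
    if a < 0 or b > next(iter(pv.counts.values())).shape[2]:
        raise ValueError("response window outside the trial window")
    return {k: v[:, :, a:b].mean(axis=2) for k, v in pv.counts.items()}


def response_vectors_and_distances(
    pv: PopulationVector,
    paradigm: str | Paradigm = "behavioral",
    odors: tuple[str, str] = ("A", "B"),
    phases: tuple[str, str] = ("pre", "post"),
) -> dict:
    """Pairwise response-vector distances within and across conditions.

    Emits (a) per odor, all pre<->post pairwise distances against all
    pre<->pre pairwise distances (is the phase shift larger than the
    baseline trial-to-trial variability?); (b) per phase, all cross-odor
    distances; each as a tidy table per metric with t-test summaries,
    ready for ANOVA/posthoc routines.
    """
    par = PARADIGMS[paradigm] if isinstance(paradigm, str) else paradigm
    resp = _response_vectors(pv, par.response_window_s)
    rows = []
    for metric, dist in _METRICS.items():
        for odor in odors:
            pre = resp[(odor, phases[0])]
            post = resp[(odor, phases[1])]
            for i, j in combinations(range(pre.shape[0]), 2):
                rows.append({"metric": metric, "odor": odor,
                             "comparison": "pre-pre",
                             "distance": dist(pre[i], pre[j])})
            for i in range(pre.shape[0]):
                for j in range(post.shape[0]):
                    rows.append({"metric": metric, "odor": odor,
                                 "comparison": "pre-post",
                                 "distance": dist(pre[i], post[j])})
        for ph in phases:
            ra, rb = resp[(odors[0], ph)], resp[(odors[1], ph)]
            for i in range(ra.shape[0]):
                for j in range(rb.shape[0]):
                    rows.append({"metric": metric, "odor": "cross",
                                 "comparison": f"cross-odor-{ph}",
                                 "distance": dist(ra[i], rb[j])})
    table = pd.DataFrame(rows).dropna(subset=["distance"])

    # summary tests operate on one mean distance per trial-group (not on
    # raw pairs, which share group vectors and would be pseudo-replicated)
    def _pair_matrix(xa, xb, dist, same=False):
        m = np.array([[dist(a, b) for b in xb] for a in xa])
        if same:
            np.fill_diagonal(m, np.nan)
        return np.nanmean(m, axis=1)

    tests = {}
    for metric, dist in _METRICS.items():
        for odor in odors:
            pre = resp[(odor, phases[0])]
            post = resp[(odor, phases[1])]
            x = _pair_matrix(pre, pre, dist, same=True)
            y = _pair_matrix(post, pre, dist)
            t, p = stats.ttest_ind(x, y)
            tests[(metric, f"odor-{odor} pre-post vs pre-pre")] = {
                "t": float(t), "p": float(p),
                "mean_pre_pre": float(np.mean(x)), "mean_pre_post": float(np.mean(y)),
            }
        per_phase = {}
        for ph in phases:
            per_phase[ph] = _pair_matrix(resp[(odors[0], ph)], resp[(odors[1], ph)], dist)
        t, p = stats.ttest_ind(per_phase[phases[0]], per_phase[phases[1]])
        tests[(metric, "cross-odor post vs pre")] = {
            "t": float(t), "p": float(p),
            "mean_pre": float(np.mean(per_phase[phases[0]])),
            "mean_post": float(np.mean(per_phase[phases[1]])),
        }
    return {"table": table, "tests": tests, "response_vectors": resp}


def qda_df_total(d: int) -> int:
    """Free parameters of a two-class QDA in dimension ``d``:
    ``2*(d*(d-1)/2 + 2*d + 1) - 1``."""
    df_c = d * (d - 1) // 2 + 2 * d + 1
    return 2 * df_c - 1


def qda_decode(
    pv: PopulationVector,
    paradigm: str | Paradigm = "behavioral",
    dims: tuple[int, ...] = (3, 4, 5, 6),
    odors: tuple[str, str] = ("A", "B"),
    phases: tuple[str, str] = ("pre", "post"),
    reg_param: float = 0.0,
) -> dict:
    """Leave-one-out QDA accuracy for odor decoding, per phase and dimension.

    PCA is fitted once on the pooled response vectors of all four
    odor x phase groups so that pre and post share one space; per phase a
    QDA separates the two odors under LOOCV.  Dimensions whose total QDA
    parameter count reaches the number of points in a phase are refused.
    Pre-versus-post accuracies are compared with Fisher's exact test,
    BH-corrected across dimensions.
    """
    par = PARADIGMS[paradigm] if isinstance(paradigm, str) else paradigm
    resp = _response_vectors(pv, par.response_window_s)
    groups = [(odor, ph) for ph in phases for odor in odors]
    X_all = np.concatenate([resp[g] for g in groups], axis=0)
    max_dim = max(dims)
    pca = PCA(n_components=min(max_dim, *X_all.shape), random_state=0)
    scores = pca.fit_transform(X_all)
    sizes = [resp[g].shape[0] for g in groups]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    per_group = {g: scores[offsets[i]: offsets[i + 1]] for i, g in enumerate(groups)}

    results = {}
    fisher_p = []
    used_dims = []
    for d in dims:
        n_points = min(
            per_group[(odors[0], ph)].shape[0] + per_group[(odors[1], ph)].shape[0]
            for ph in phases
        )
        if qda_df_total(d) >= n_points or d > scores.shape[1]:
            logger.info("dimension %d refused: %d parameters vs %d points",
                        d, qda_df_total(d), n_points)
            continue
        used_dims.append(d)
        acc = {}
        counts = {}
        for ph in phases:
            X = np.concatenate(
                [per_group[(odors[0], ph)][:, :d], per_group[(odors[1], ph)][:, :d]]
            )
            y = np.concatenate(
                [np.zeros(per_group[(odors[0], ph)].shape[0]),
                 np.ones(per_group[(odors[1], ph)].shape[0])]
            )
            correct = 0
            for i in range(X.shape[0]):
                mask = np.ones(X.shape[0], dtype=bool)
                mask[i] = False
                clf = QuadraticDiscriminantAnalysis(reg_param=reg_param)
                try:
                    clf.fit(X[mask], y[mask])
                except Exception:
                    logger.info("singular covariance at dim %d; regularized refit", d)
                    clf = QuadraticDiscriminantAnalysis(reg_param=max(reg_param, 1e-3))
                    clf.fit(X[mask], y[mask])
                correct += int(clf.predict(X[i: i + 1])[0] == y[i])
            acc[ph] = correct / X.shape[0]
            counts[ph] = (correct, X.shape[0] - correct)
        tab = [list(counts[phases[0]]), list(counts[phases[1]])]
        _, p = stats.fisher_exact(tab)
        fisher_p.append(p)
        results[d] = {"accuracy": acc, "counts": counts, "fisher_p_raw": float(p)}
    if fisher_p:
        _, p_adj, *_ = multipletests(fisher_p, method="fdr_bh")
        for d, pa in zip(used_dims, p_adj):
            results[d]["fisher_p_adjusted"] = float(pa)
    return results


def embed_trajectories(
    pv: PopulationVector,
    m: int = 3,
    delay_bins: int = 1,
    n_factors: int = 3,
    seed: int = 0,
) -> dict:
    """Trial-averaged per-group trajectories, delay-embedded (m delayed
    coordinates per unit) and reduced to three latent factors.

    Output is for visualization; a constant trajectory is flagged as
    degenerate rather than factorized.
    """
    series = {k: v.mean(axis=0) for k, v in pv.counts.items()}  # units x bins
    n_bins = next(iter(series.values())).shape[1]
    if n_bins < m + 1:
        raise ValueError("need at least m+1 time bins for delay embedding")
    T = n_bins - (m - 1) * delay_bins
    embedded = {}
    for k, x in series.items():
        emb = np.concatenate(
            [x[:, i * delay_bins: i * delay_bins + T] for i in range(m)], axis=0
        )
        embedded[k] = emb  # (units*m) x T
    stacked = np.concatenate(list(embedded.values()), axis=1).T
    if np.allclose(stacked.std(axis=0), 0):
        return {"embedded": embedded, "factors": None, "degenerate": True}
    fa = FactorAnalysis(n_components=n_factors, random_state=seed)
    z = fa.fit_transform(stacked)
    out = {}
    start = 0
    for k, emb in embedded.items():
        out[k] = z[start: start + emb.shape[1]].T  # 3 x T
        start += emb.shape[1]
    return {"embedded": embedded, "factors": out, "degenerate": False}


def mds_responses(
    pv: PopulationVector,
    paradigm: str | Paradigm = "behavioral",
    n_components: int = 3,
    seed: int = 0,
) -> dict:
    """Metric MDS embedding of the odor-response vectors (3-D, for plots)."""
    par = PARADIGMS[paradigm] if isinstance(paradigm, str) else paradigm
    resp = _response_vectors(pv, par.response_window_s)
    keys = sorted(resp)
    X = np.concatenate([resp[k] for k in keys], axis=0)
    if X.shape[0] < n_components + 1:
        raise ValueError("need more points than embedding dimensions")
    mds = MDS(n_components=n_components, random_state=seed, normalized_stress=False)
    pts = mds.fit_transform(X)
    labels = np.concatenate([[str(k)] * resp[k].shape[0] for k in keys])
    return {"points": pts, "labels": labels, "stress": float(mds.stress_)}
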