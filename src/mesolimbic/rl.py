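"""Q-learning with Pearce-Hall associability for go/no-go reversal behavior.

Three generalizations of the hybrid Rescorla-Wagner / Pearce-Hall (Q-PH)
model are implemented.  In all of them the value ``Q[s, a]`` of taking
action ``a`` (lick / restrain) in state ``s`` (odor A / odor B) is updated
by a prediction error ``delta = r - Q[s, a]`` scaled by an associability
``alpha`` that itself tracks recent surprise:

* ``qph_kappa`` — two learning rates, one per action:
  ``Q[s,a] += kappa_a * alpha * delta``; ``alpha`` relaxes toward
  ``|delta|`` at rate ``eta``.
* ``qph_eta`` — one learning rate ``kappa`` but an action-specific
  ``eta_a`` in the associability update.
* ``qph_f`` — forgetting variant: the chosen action updates with
  ``kappa_L * alpha_L * delta`` while the unchosen action of the visited
  state decays, ``Q[s,a'] -= kappa_F * alpha_F * Q[s,a']``, with
  ``alpha_F`` relaxing toward the unchosen value.  Setting
  ``kappa_F = 0`` recovers the hybrid model exactly.

Action probabilities follow a softmax with inverse temperature ``beta``:
``P(a|s) = exp(beta*Q[s,a]) / sum_l exp(beta*Q[s,l])``.

Initialization: ``Q[s,a](1) = 0.5`` for all state/action pairs and
``alpha(1) = 0`` (also for ``alpha_L``, ``alpha_F``).  Original and
reversal phases are fit jointly as one series; no latent reset occurs at
reversal — the contingency change reaches the model only through the
rewards.

The per-trial stimulus value ``V_CS+(t) = max_a Q[cs+(t), a](t)`` (the max
over action values of the currently rewarded odor) is the latent trace
consumed by the assembly-activity regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MODELS",
    "PARAM_NAMES",
    "QModelFit",
    "qph_step",
    "qph_trajectory",
    "action_likelihood",
    "log_likelihood",
    "fit_model",
    "compare_models",
    "lrt_forgetting",
    "raftery_grade",
]

MODELS = ("qph_kappa", "qph_eta", "qph_f")
_MODEL_ID = {"qph_kappa": 0, "qph_eta": 1, "qph_f": 2}

PARAM_NAMES = {
    "qph_kappa": ("kappa1", "kappa2", "eta", "beta"),
    "qph_eta": ("kappa", "eta1", "eta2", "beta"),
    "qph_f": ("kappa_L", "kappa_F", "eta", "beta"),
}

#: box bounds: learning/forgetting rates in [0, 1]; eta in [0, 1]; beta in [0, 500]
BOUNDS = {
    "qph_kappa": ((0, 1), (0, 1), (0, 1), (0, 500)),
    "qph_eta": ((0, 1), (0, 1), (0, 1), (0, 500)),
    "qph_f": ((0, 1), (0, 1), (0, 1), (0, 500)),
}

Q_INIT = 0.5
ALPHA_INIT = 0.0


def _traj_py(model, s, a, r, p1, p2, p3, beta):
    n = s.shape[0]
    Q = np.full((2, 2), Q_INIT)
    alpha = ALPHA_INIT
    alpha_f = ALPHA_INIT
    logl = 0.0
    q_tr = np.empty((n, 2, 2))
    a_tr = np.empty((n, 2))
    d_tr = np.empty(n)
    for t in range(n):
        q_tr[t] = Q
        a_tr[t, 0] = alpha
        a_tr[t, 1] = alpha_f
        st = s[t]
        at = a[t]
        x0 = beta * Q[st, 0]
        x1 = beta * Q[st, 1]
        m = x0 if x0 > x1 else x1
        logl += (x0 if at == 0 else x1) - m - np.log(np.exp(x0 - m) + np.exp(x1 - m))
        d = r[t] - Q[st, at]
        d_tr[t] = d
        if model == 0:  # two learning rates
            kap = p1 if at == 0 else p2
            Q[st, at] += kap * alpha * d
            alpha = (1.0 - p3) * alpha + p3 * abs(d)
        elif model == 1:  # two etas
            Q[st, at] += p1 * alpha * d
            e = p2 if at == 0 else p3
            alpha = (1.0 - e) * alpha + e * abs(d)
        else:  # forgetting
            Q[st, at] += p1 * alpha * d
            au = 1 - at
            q_un = Q[st, au]
            Q[st, au] = q_un - p2 * alpha_f * q_un
            alpha = (1.0 - p3) * alpha + p3 * abs(d)
            alpha_f = (1.0 - p3) * alpha_f + p3 * q_un
    return logl, q_tr, a_tr, d_tr


def _loglik_py(model, s, a, r, p1, p2, p3, beta):
    n = s.shape[0]
    Q = np.full((2, 2), Q_INIT)
    alpha = ALPHA_INIT
    alpha_f = ALPHA_INIT
    logl = 0.0
    for t in range(n):
        st = s[t]
        at = a[t]
        x0 = beta * Q[st, 0]
        x1 = beta * Q[st, 1]
        m = x0 if x0 > x1 else x1
        logl += (x0 if at == 0 else x1) - m - np.log(np.exp(x0 - m) + np.exp(x1 - m))
        d = r[t] - Q[st, at]
        if model == 0:
            kap = p1 if at == 0 else p2
            Q[st, at] += kap * alpha * d
            alpha = (1.0 - p3) * alpha + p3 * abs(d)
        elif model == 1:
            Q[st, at] += p1 * alpha * d
            e = p2 if at == 0 else p3
            alpha = (1.0 - e) * alpha + e * abs(d)
        else:
            Q[st, at] += p1 * alpha * d
            au = 1 - at
            q_un = Q[st, au]
            Q[st, au] = q_un - p2 * alpha_f * q_un
            alpha = (1.0 - p3) * alpha + p3 * abs(d)
            alpha_f = (1.0 - p3) * alpha_f + p3 * q_un
    return logl


try:  # jit-compile the recursion; the pure-python path is the reference
    from numba import njit

    _traj = njit(cache=True)(_traj_py)
    _loglik = njit(cache=True)(_loglik_py)
    _loglik(2, np.zeros(2, np.int64), np.zeros(2, np.int64), np.zeros(2), 0.4, 0.1, 0.3, 5.0)
except Exception:  # pragma: no cover - numba unavailable or failed to compile
    _traj = _traj_py
    _loglik = _loglik_py


def _as_arrays(s, a, r):
    s = np.ascontiguousarray(s, dtype=np.int64)
    a = np.ascontiguousarray(a, dtype=np.int64)
    r = np.ascontiguousarray(r, dtype=np.float64)
    if not (s.shape == a.shape == r.shape):
        raise ValueError("state/action/reward series must share a length")
    return s, a, r


def _check_theta(model: str, theta) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    bounds = BOUNDS[model]
    if theta.shape != (len(bounds),):
        raise ValueError(f"{model} expects {len(bounds)} parameters")
    for v, (lo, hi) in zip(theta, bounds):
        if not (lo <= v <= hi):
            raise ValueError(f"parameter {v} outside bounds [{lo}, {hi}]")
    return theta


def qph_step(model: str, state: int, action: int, reward: float,
             Q: np.ndarray, alpha: np.ndarray, theta) -> tuple[np.ndarray, np.ndarray, float]:
    """One trial of the Q-PH update; returns (Q', alpha', delta).

    ``alpha`` is a length-2 array ``[alpha(_L), alpha_F]`` (the second entry
    is only used by the forgetting model).  Only the visited state changes.
    """
    theta = _check_theta(model, theta)
    p1, p2, p3, _beta = theta
    Q = np.array(Q, dtype=float)
    alpha = np.array(alpha, dtype=float)
    delta = reward - Q[state, action]
    mid = _MODEL_ID[model]
    if mid == 0:
        kap = p1 if action == 0 else p2
        Q[state, action] += kap * alpha[0] * delta
        alpha[0] = (1 - p3) * alpha[0] + p3 * abs(delta)
    elif mid == 1:
        Q[state, action] += p1 * alpha[0] * delta
        e = p2 if action == 0 else p3
        alpha[0] = (1 - e) * alpha[0] + e * abs(delta)
    else:
        Q[state, action] += p1 * alpha[0] * delta
        other = 1 - action
        q_un = Q[state, other]
        Q[state, other] = q_un - p2 * alpha[1] * q_un
        alpha[0] = (1 - p3) * alpha[0] + p3 * abs(delta)
        alpha[1] = (1 - p3) * alpha[1] + p3 * q_un
    return Q, alpha, delta


def action_likelihood(q_state: np.ndarray, beta: float) -> np.ndarray:
    """Softmax action probabilities for one state's action values."""
    x = beta * np.asarray(q_state, dtype=float)
    x = x - x.max()
    e = np.exp(x)
    return e / e.sum()


def qph_trajectory(model: str, s, a, r, theta):
    """Run the recursion over a whole series.

    Returns ``(logL, Q_trace, alpha_trace, delta_trace)`` where
    ``Q_trace[t]`` holds the values *in force at* trial ``t`` (pre-update),
    matching the quantities that generated the choice at ``t``.
    """
    theta = _check_theta(model, theta)
    s, a, r = _as_arrays(s, a, r)
    return _traj(_MODEL_ID[model], s, a, r, *theta)


def log_likelihood(model: str, s, a, r, theta) -> float:
    theta = _check_theta(model, theta)
    s, a, r = _as_arrays(s, a, r)
    return float(_loglik(_MODEL_ID[model], s, a, r, *theta))


@dataclass
class QModelFit:
    """A fitted Q-PH model with its latent traces."""

    model: str
    theta: dict
    log_lik: float
    bic: float
    n_trials: int
    q_trace: np.ndarray       # trials x state x action, pre-update values
    alpha_trace: np.ndarray   # trials x 2 (alpha_L, alpha_F)
    delta_trace: np.ndarray
    v_cs_plus: np.ndarray | None = None
    n_starts: int = 0
    converged: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def theta_vector(self) -> np.ndarray:
        return np.array([self.theta[k] for k in PARAM_NAMES[self.model]])


def value_trace(q_trace: np.ndarray, cs_plus_state: np.ndarray) -> np.ndarray:
    """V_CS+(t): max over action values of the currently rewarded odor."""
    idx = np.asarray(cs_plus_state, dtype=int)
    return q_trace[np.arange(q_trace.shape[0]), idx, :].max(axis=1)


def fit_model(
    s,
    a,
    r,
    model: str = "qph_f",
    n_starts: int = 256,
    seed: int = 0,
    tol: float = 1e-6,
    cs_plus_state: np.ndarray | None = None,
    fixed: dict | None = None,
    extra_starts: list | None = None,
) -> QModelFit:
    """Maximum-likelihood fit via bounded local optimization from random starts.

    Starts are drawn uniformly within the box bounds, except that half the
    ``beta`` starts are drawn from [0, 20] where the likelihood is typically
    curved.  ``fixed`` pins named parameters (e.g. ``{"kappa_F": 0.0}`` for
    the nested hybrid model in the likelihood-ratio test).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    s, a, r = _as_arrays(s, a, r)
    n = s.size
    if n < 50:
        raise ValueError("need at least 50 trials to fit")
    names = PARAM_NAMES[model]
    bounds = list(BOUNDS[model])
    fixed = fixed or {}
    fixed_idx = {names.index(k): v for k, v in fixed.items()}
    free = [i for i in range(len(names)) if i not in fixed_idx]
    mid = _MODEL_ID[model]

    def unpack(x_free):
        theta = np.empty(len(names))
        for j, i in enumerate(free):
            theta[i] = x_free[j]
        for i, v in fixed_idx.items():
            theta[i] = v
        return theta

    def nll(x_free):
        th = unpack(x_free)
        return -_loglik(mid, s, a, r, th[0], th[1], th[2], th[3])

    rng = np.random.default_rng(seed)
    best = None
    n_fail = 0
    x0_list = []
    for k in range(n_starts):
        x0 = np.array([rng.uniform(*bounds[i]) for i in free])
        for j, i in enumerate(free):
            if names[i] == "beta" and k % 2 == 0:
                x0[j] = rng.uniform(0, 20)
        x0_list.append(x0)
    for th in extra_starts or []:
        th = np.asarray(th, dtype=float)
        x0_list.append(np.array([th[i] for i in free]))
    for x0 in x0_list:
        try:
            res = optimize.minimize(
                nll, x0, method="L-BFGS-B",
                bounds=[bounds[i] for i in free], tol=tol,
            )
        except Exception:
            n_fail += 1
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"all {n_starts} optimization starts failed ({n_fail} errors)")
    theta_hat = unpack(best.x)
    logl, q_tr, a_tr, d_tr = _traj(mid, s, a, r, *theta_hat)
    k_free = len(free)
    bic = k_free * np.log(n) - 2.0 * logl
    fit = QModelFit(
        model=model,
        theta=dict(zip(names, theta_hat)),
        log_lik=float(logl),
        bic=float(bic),
        n_trials=n,
        q_trace=q_tr,
        alpha_trace=a_tr,
        delta_trace=d_tr,
        n_starts=n_starts,
        converged=bool(best.success),
        meta={"n_failed_starts": n_fail, "k_free": k_free},
    )
    if cs_plus_state is not None:
        fit.v_cs_plus = value_trace(q_tr, cs_plus_state)
    return fit


def raftery_grade(delta_bic: float) -> str:
    """Qualitative evidence grade for a BIC difference (Raftery convention)."""
    d = abs(delta_bic)
    if d < 2:
        return "weak"
    if d < 6:
        return "positive"
    if d < 10:
        return "strong"
    return "very strong"


def compare_models(fits_per_session: list[dict[str, QModelFit]]) -> dict:
    """BIC comparison across sessions with Friedman test and pairwise posthoc.

    ``fits_per_session`` maps model name -> fit, one dict per session; all
    fits of a session must share the underlying trial series.
    """
    models = sorted(fits_per_session[0])
    for fits in fits_per_session:
        ns = {f.n_trials for f in fits.values()}
        if len(ns) != 1:
            raise ValueError("fits of one session must share the trial count")
    bic = pd.DataFrame(
        [{m: fits[m].bic for m in models} for fits in fits_per_session]
    )
    mean_bic = bic.mean()
    winner = mean_bic.idxmin()
    out = {
        "bic_table": bic,
        "mean_bic": mean_bic.to_dict(),
        "best_model": winner,
        "raftery": {
            m: raftery_grade(mean_bic[m] - mean_bic[winner]) for m in models if m != winner
        },
    }
    if len(models) >= 3 and len(bic) >= 3:
        stat, p = stats.friedmanchisquare(*[bic[m].to_numpy() for m in models])
        out["friedman"] = {"statistic": float(stat), "p_value": float(p)}
        posthoc = {}
        pairs = [(m1, m2) for i, m1 in enumerate(models) for m2 in models[i + 1:]]
        pvals = []
        for m1, m2 in pairs:
            diff = bic[m1].to_numpy() - bic[m2].to_numpy()
            if np.allclose(diff, 0):
                pvals.append(1.0)
            else:
                pvals.append(float(stats.wilcoxon(diff).pvalue))
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(pvals, method="fdr_bh")[1] if pairs else []
        for (m1, m2), p_adj in zip(pairs, adj):
            posthoc[f"{m1} vs {m2}"] = float(p_adj)
        out["posthoc"] = posthoc
    return out


def lrt_forgetting(s, a, r, n_starts: int = 64, seed: int = 0) -> dict:
    """Likelihood-ratio test of the forgetting model against its hybrid
    (kappa_F = 0) nested restriction; chi-square with one degree of freedom.

    The full fit is additionally started from the restricted optimum so the
    likelihood ratio is nonnegative by construction."""
    restricted = fit_model(
        s, a, r, model="qph_f", n_starts=n_starts, seed=seed + 1,
        fixed={"kappa_F": 0.0},
    )
    full = fit_model(
        s, a, r, model="qph_f", n_starts=n_starts, seed=seed,
        extra_starts=[restricted.theta_vector],
    )
    lr = 2.0 * (full.log_lik - restricted.log_lik)
    if lr < 0:  # numerically possible at tolerance level only
        warnings.warn("restricted fit beat the full fit; reporting LR=0")
        lr = 0.0
    p = float(stats.chi2.sf(lr, df=1))
    return {"lr_stat": float(lr), "p_value": p, "full": full, "restricted": restricted}
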