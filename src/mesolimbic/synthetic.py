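"""Synthetic recordings and behavior with known ground truth.

Emulates the statistical structure the downstream analyses assume: a
go/no-go reversal session driven by a Q-PH agent, low-rate striatal
spiking with odor responses whose gain can track the learned stimulus
value, lagged source->target coincidence structure at a controlled
temporal precision, slow firing-rate drifts, laser-locked spikes for
optogenetic tagging, and spike-waveform-bearing multichannel voltage.

Every generator takes an explicit seed and is bit-reproducible under it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SpikeTrain, TrialTable
from . import rl

__all__ = [
    "TaskConfig",
    "AgentSpec",
    "UnitSpec",
    "OdorKernel",
    "AssemblyCouplingSpec",
    "simulate_task_session",
    "simulate_passive_session_table",
    "simulate_unit",
    "simulate_assembly_pair",
    "simulate_voltage",
    "default_waveform",
    "simulate_laser_block",
    "odor_sequence",
]

LICK, RESTRAIN = 0, 1


def specs_from_yaml(path) -> dict:
    """Load generator specifications from one YAML config file.

    Recognized top-level keys: ``seed`` (required), ``task`` (TaskConfig
    fields), ``agent`` (AgentSpec fields), ``units`` (list of UnitSpec
    fields, kernels as ``{odor: {amplitude_hz, latency_s, duration_s}}``),
    ``coupling`` (AssemblyCouplingSpec fields).
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "seed" not in raw:
        raise ValueError("generator config must set an explicit seed")
    out = {"seed": int(raw["seed"])}
    if "task" in raw:
        out["task"] = TaskConfig(**raw["task"])
    if "agent" in raw:
        spec = dict(raw["agent"])
        if "theta" in spec:
            spec["theta"] = tuple(spec["theta"])
        out["agent"] = AgentSpec(**spec)
    if "units" in raw:
        units = []
        for u in raw["units"]:
            u = dict(u)
            u["kernels"] = {
                odor: OdorKernel(**k) for odor, k in (u.get("kernels") or {}).items()
            }
            units.append(UnitSpec(**u))
        out["units"] = units
    if "coupling" in raw:
        out["coupling"] = AssemblyCouplingSpec(**raw["coupling"])
    return out


@dataclass
class TaskConfig:
    """Go/no-go task timing and criterion parameters."""

    stim_duration_s: float = 1.5
    retrieval_onset_s: float = 0.75
    retrieval_window_s: float = 1.75
    iti_mean_s: float = 10.0
    iti_jitter_s: float = 2.0
    criterion_frac: float = 0.8
    criterion_window: int = 50
    max_same_consecutive: int = 3
    #: delay after retrieval onset at which the third (reward-triggering) lick lands
    reward_latency_s: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.criterion_frac <= 1):
            raise ValueError("criterion_frac must be in (0, 1]")
        if self.max_same_consecutive < 1:
            raise ValueError("max_same_consecutive must be >= 1")
        for name in ("stim_duration_s", "retrieval_onset_s", "retrieval_window_s",
                     "iti_mean_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class AgentSpec:
    """A Q-PH agent: model family plus its parameter vector."""

    model: str = "qph_f"
    theta: tuple = (0.4, 0.1, 0.3, 5.0)

    def __post_init__(self) -> None:
        if self.model not in rl.MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        rl._check_theta(self.model, self.theta)


def odor_sequence(n: int, rng: np.random.Generator, max_same: int = 3) -> np.ndarray:
    """Pseudorandom binary odor sequence with at most ``max_same`` repeats."""
    seq = np.empty(n, dtype=np.int64)
    run = 0
    for t in range(n):
        if t > 0 and run >= max_same:
            seq[t] = 1 - seq[t - 1]
        else:
            seq[t] = rng.integers(2)
        run = run + 1 if t > 0 and seq[t] == seq[t - 1] else 1
    return seq


def simulate_task_session(
    cfg: TaskConfig,
    agent: AgentSpec,
    n_trials_max: int = 400,
    seed: int = 0,
) -> tuple[TrialTable, pd.DataFrame]:
    """Simulate one reversal session with a Q-PH agent.

    Odor 0 is CS+ in the original phase; the contingency reverses on the
    first trial after the trailing fraction correct over
    ``criterion_window`` trials reaches ``criterion_frac``.  The session is
    flagged incomplete when the original-phase criterion is never reached.
    Returns the trial table and a per-trial frame of the generating
    latents (Q, alpha, delta, V_CS+) for recovery tests.
    """
    if n_trials_max < cfg.criterion_window:
        raise ValueError("n_trials_max must cover at least one criterion window")
    rng = np.random.default_rng(seed)
    odors = odor_sequence(n_trials_max, rng, cfg.max_same_consecutive)
    theta = np.asarray(agent.theta, dtype=float)
    beta = theta[3]
    Q = np.full((2, 2), rl.Q_INIT)
    alpha = np.array([rl.ALPHA_INIT, rl.ALPHA_INIT])

    cs_plus = 0
    reversed_at = None
    correct_hist: list[bool] = []
    rows = []
    latents = []
    t_clock = rng.uniform(cfg.iti_mean_s - cfg.iti_jitter_s, cfg.iti_mean_s + cfg.iti_jitter_s)
    for t in range(n_trials_max):
        s = int(odors[t])
        p = rl.action_likelihood(Q[s], beta)
        a = LICK if rng.random() < p[LICK] else RESTRAIN
        is_cs_plus = s == cs_plus
        r = 1.0 if (is_cs_plus and a == LICK) else 0.0
        correct = (is_cs_plus and a == LICK) or (not is_cs_plus and a == RESTRAIN)
        latents.append(
            {
                "trial": t,
                "Q_s_lick": Q[s, LICK],
                "Q_s_restrain": Q[s, RESTRAIN],
                "alpha": alpha[0],
                "alpha_F": alpha[1],
                "V_cs_plus": Q[cs_plus].max(),
                "cs_plus_state": cs_plus,
            }
        )
        Q, alpha, delta = rl.qph_step(agent.model, s, a, r, Q, alpha, theta)
        latents[-1]["delta"] = delta
        reward_s = (
            t_clock + cfg.retrieval_onset_s + cfg.reward_latency_s if r > 0 else np.nan
        )
        rows.append(
            {
                "trial": t,
                "odor": "A" if s == 0 else "B",
                "state": s,
                "cs_plus": is_cs_plus,
                "action": "lick" if a == LICK else "restrain",
                "action_code": a,
                "reward": r,
                "correct": correct,
                "phase": "original" if reversed_at is None else "reversal",
                "onset_s": t_clock,
                "reward_s": reward_s,
            }
        )
        correct_hist.append(correct)
        if reversed_at is None and len(correct_hist) >= cfg.criterion_window:
            frac = np.mean(correct_hist[-cfg.criterion_window:])
            if frac >= cfg.criterion_frac:
                reversed_at = t + 1
                cs_plus = 1
                correct_hist = []
        t_clock += rng.uniform(
            cfg.iti_mean_s - cfg.iti_jitter_s, cfg.iti_mean_s + cfg.iti_jitter_s
        )
    df = pd.DataFrame(rows)
    complete = reversed_at is not None
    table = TrialTable(
        df,
        complete=complete,
        meta={"reversed_at": reversed_at, "seed": seed, "agent": agent.model},
    )
    return table, pd.DataFrame(latents)


def simulate_passive_session_table(
    n_trials_per_phase: dict[str, int] | None = None,
    iti_mean_s: float = 10.0,
    iti_jitter_s: float = 2.0,
    seed: int = 0,
    max_same: int = 3,
) -> TrialTable:
    """Trial table for the passive pairing paradigm (pre / pairing / post).

    Two odors alternate pseudorandomly; odor 'A' is the paired one.  No
    behavior is generated — this table only anchors stimulus times.
    """
    if n_trials_per_phase is None:
        n_trials_per_phase = {"pre": 40, "pairing": 30, "post": 30}
    rng = np.random.default_rng(seed)
    rows = []
    t_clock = rng.uniform(iti_mean_s - iti_jitter_s, iti_mean_s + iti_jitter_s)
    trial = 0
    for phase, n in n_trials_per_phase.items():
        odors = odor_sequence(n, rng, max_same)
        for s in odors:
            rows.append(
                {
                    "trial": trial,
                    "odor": "A" if s == 0 else "B",
                    "state": int(s),
                    "phase": phase,
                    "onset_s": t_clock,
                }
            )
            trial += 1
            t_clock += rng.uniform(iti_mean_s - iti_jitter_s, iti_mean_s + iti_jitter_s)
    return TrialTable(pd.DataFrame(rows), meta={"paradigm": "passive", "seed": seed})


@dataclass
class OdorKernel:
    """Boxcar rate modulation following one odor's onset (Hz; may be negative)."""

    amplitude_hz: float
    latency_s: float = 0.05
    duration_s: float = 1.0


@dataclass
class UnitSpec:
    """Rate model of one simulated unit.

    Instantaneous rate = rectify(baseline * drift(t) + sum of odor kernels),
    where the kernel amplitude on each trial is scaled by
    ``1 + learning_gain * V(trial)`` given a per-trial value trace.
    """

    role: str = "SPN"
    baseline_hz: float = 1.0
    kernels: dict[str, OdorKernel] = field(default_factory=dict)
    learning_gain: float = 0.0
    gain_odor: str | None = None   # restrict the gain to one odor's kernel
    drift_amplitude: float = 0.0   # fractional slow modulation of baseline
    drift_period_s: float = 600.0

    def __post_init__(self) -> None:
        if self.baseline_hz < 0:
            raise ValueError("baseline rate must be nonnegative")


def _rate_on_grid(
    spec: UnitSpec,
    trials: TrialTable | None,
    value_trace: np.ndarray | None,
    span_s: float,
    dt: float,
) -> np.ndarray:
    n = int(np.ceil(span_s / dt))
    t = (np.arange(n) + 0.5) * dt
    drift = 1.0 + spec.drift_amplitude * np.sin(2 * np.pi * t / spec.drift_period_s)
    rate = spec.baseline_hz * drift
    if trials is not None:
        onsets = trials.df["onset_s"].to_numpy()
        odors = trials.df["odor"].to_numpy()
        for i, (onset, odor) in enumerate(zip(onsets, odors)):
            ker = spec.kernels.get(odor)
            if ker is None:
                continue
            gain = 1.0
            if (
                value_trace is not None
                and spec.learning_gain
                and (spec.gain_odor is None or spec.gain_odor == odor)
            ):
                gain = 1.0 + spec.learning_gain * float(value_trace[i])
            a = int((onset + ker.latency_s) / dt)
            b = int((onset + ker.latency_s + ker.duration_s) / dt)
            rate[max(a, 0):min(b, n)] += ker.amplitude_hz * gain
    return np.clip(rate, 0.0, None)


def simulate_unit(
    spec: UnitSpec,
    trials: TrialTable | None = None,
    value_trace: np.ndarray | None = None,
    seed: int = 0,
    span_s: float | None = None,
    dt: float = 0.001,
    unit_id: str = "u0",
    region: str = "VS",
) -> SpikeTrain:
    """Inhomogeneous-Poisson spike train for one unit.

    Spikes are drawn per ``dt`` grid cell from the rectified rate and
    placed uniformly within the cell.  Negative requested rates are
    clamped to zero before sampling.
    """
    if trials is not None:
        onsets = trials.df["onset_s"].to_numpy()
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ValueError("trial onsets must be strictly increasing")
        if span_s is None:
            span_s = float(onsets[-1]) + 10.0
    if span_s is None:
        raise ValueError("span_s required when no trial table is given")
    rng = np.random.default_rng(seed)
    rate = _rate_on_grid(spec, trials, value_trace, span_s, dt)
    counts = rng.poisson(rate * dt)
    nz = np.nonzero(counts)[0]
    reps = counts[nz]
    lefts = np.repeat(nz * dt, reps)
    times = np.sort(lefts + rng.random(lefts.size) * dt)
    return SpikeTrain(unit_id=unit_id, times_s=times, region=region)


@dataclass
class AssemblyCouplingSpec:
    """Directed source->target spike coupling at a controlled precision."""

    lag_s: float = 0.2
    precision_s: float = 0.05
    efficacy: float = 0.5
    window: str = "all"  # 'all' or 'cs_plus' (couple only within CS+ trials)

    def __post_init__(self) -> None:
        if not (0 <= self.efficacy <= 1):
            raise ValueError("efficacy must be in [0, 1]")
        if self.precision_s <= 0:
            raise ValueError("precision must be positive")
        if self.lag_s < 0:
            raise ValueError("lag must be nonnegative")


def simulate_assembly_pair(
    src: UnitSpec,
    tgt: UnitSpec,
    coupling: AssemblyCouplingSpec,
    trials: TrialTable | None = None,
    seed: int = 0,
    span_s: float | None = None,
    efficacy_by_trial: np.ndarray | None = None,
    cs_window_s: float = 1.0,
    value_trace: np.ndarray | None = None,
    ids: tuple[str, str] = ("src", "tgt"),
) -> tuple[SpikeTrain, SpikeTrain]:
    """Source train plus a target whose spikes include induced events at
    ``src_time + lag + N(0, precision)`` with probability ``efficacy``.

    ``efficacy_by_trial`` multiplies the coupling efficacy per trial (used
    to let coupling strength track a learned value trace); it requires a
    trial table and ``window='cs_plus'`` restricts induction to spikes in
    the ``cs_window_s`` after CS+ onsets.
    """
    rng = np.random.default_rng(seed)
    s_src = simulate_unit(src, trials, value_trace, seed=rng.integers(2**31),
                          span_s=span_s, unit_id=ids[0], region="VS")
    s_bg = simulate_unit(tgt, trials, value_trace, seed=rng.integers(2**31),
                         span_s=span_s, unit_id=ids[1], region="VTA")
    src_t = s_src.times_s
    eff = np.full(src_t.size, coupling.efficacy)
    if coupling.window == "cs_plus" or efficacy_by_trial is not None:
        if trials is None:
            raise ValueError("trial-windowed coupling requires a trial table")
        sel_col = "cs_plus" if "cs_plus" in trials.df.columns else None
        sel = trials.df if sel_col is None else trials.df[trials.df[sel_col]]
        onsets = sel["onset_s"].to_numpy()
        trial_idx = sel["trial"].to_numpy()
        in_window = np.zeros(src_t.size, dtype=bool)
        which_trial = np.full(src_t.size, -1)
        for onset, ti in zip(onsets, trial_idx):
            m = (src_t >= onset) & (src_t < onset + cs_window_s)
            in_window |= m
            which_trial[m] = ti
        if coupling.window == "cs_plus":
            eff = np.where(in_window, eff, 0.0)
        if efficacy_by_trial is not None:
            scale = np.ones(src_t.size)
            ok = which_trial >= 0
            scale[ok] = np.asarray(efficacy_by_trial)[which_trial[ok].astype(int)]
            eff = np.clip(eff * scale, 0, 1)
    induce = rng.random(src_t.size) < eff
    induced = src_t[induce] + coupling.lag_s + rng.normal(0, coupling.precision_s, induce.sum())
    induced = induced[induced >= 0]
    times = np.sort(np.concatenate([s_bg.times_s, induced]))
    return s_src, SpikeTrain(unit_id=ids[1], times_s=times, region="VTA")


def simulate_plasticity_sessions(
    n_sessions: int = 8,
    inject_gain: float = 0.0,
    paired_odor: str = "A",
    seed: int = 0,
    n_trials_per_phase: dict[str, int] | None = None,
    bin_s: float = 0.25,
    window: tuple[float, float] = (-2.0, 2.0),
    n_habituation_trials: int = 10,
    dt: float = 0.002,
) -> list[dict]:
    """Sessions emulating the passive dopamine-pairing experiment.

    Each session records ten low-rate units around pseudorandom
    presentations of two odors: three excitatory units preferring each
    odor (weakly selective, as typical for this region), one inhibited
    unit per odor, and two unresponsive units.  ``inject_gain`` scales the
    paired odor's excitatory kernels in the 'post' phase (the plasticity
    effect under study; 0 = control).  Returns one dict per session
    mapping ``(odor, phase) -> trials x units x bins`` count tensors with
    the first ``n_habituation_trials`` trials excluded.
    """
    if n_trials_per_phase is None:
        n_trials_per_phase = {"pre": 210, "pairing": 30, "post": 200}
    master = np.random.default_rng(seed)
    out = []
    other = "B" if paired_odor == "A" else "A"
    for s in range(n_sessions):
        sseed = int(master.integers(2**31))
        rng = np.random.default_rng(sseed)
        table = simulate_passive_session_table(n_trials_per_phase, seed=sseed)
        post = (table.df["phase"] == "post").to_numpy().astype(float)
        trains = []
        for u in range(10):
            gain, gain_odor, vt = 0.0, None, None
            if u < 3:
                kern = {paired_odor: OdorKernel(2.8, 0.05, 1.2),
                        other: OdorKernel(2.55, 0.05, 1.2)}
                if inject_gain:
                    gain, gain_odor, vt = inject_gain, paired_odor, post
            elif u < 6:
                kern = {paired_odor: OdorKernel(2.55, 0.05, 1.2),
                        other: OdorKernel(2.8, 0.05, 1.2)}
            elif u == 6:
                kern = {paired_odor: OdorKernel(-1.5, 0.05, 1.2),
                        other: OdorKernel(-1.0, 0.05, 1.2)}
            elif u == 7:
                kern = {paired_odor: OdorKernel(-1.0, 0.05, 1.2),
                        other: OdorKernel(-1.5, 0.05, 1.2)}
            else:
                kern = {}
            spec = UnitSpec(baseline_hz=2.0, kernels=kern, learning_gain=gain,
                            gain_odor=gain_odor)
            trains.append(
                simulate_unit(spec, table, vt, seed=int(rng.integers(2**31)),
                              dt=dt, unit_id=f"s{s}u{u}")
            )
        from .population import bin_session  # local import avoids a cycle

        usable = table.df.iloc[n_habituation_trials:]
        tensors = {}
        for odor in ("A", "B"):
            for ph in ("pre", "post"):
                sel = usable[(usable["odor"] == odor) & (usable["phase"] == ph)]
                sub = TrialTable(sel.reset_index(drop=True))
                tensors[(odor, ph)] = bin_session(trains, sub, bin_s, window)
        out.append(tensors)
    return out


def default_waveform(fs: float, width_s: float = 0.0008, amplitude: float = -1.0) -> np.ndarray:
    """Biphasic extracellular-like template: sharp negative lobe, slow rebound."""
    n = max(int(round(width_s * fs)), 8)
    t = np.arange(n) / fs
    tau1, tau2 = width_s / 6, width_s / 2.5
    w = np.exp(-t / tau2) - np.exp(-t / tau1)
    w = w / np.abs(w).max() * amplitude
    return w


def simulate_voltage(
    trains: list[tuple[SpikeTrain, np.ndarray, np.ndarray]],
    fs: float,
    noise_sd: float,
    duration_s: float,
    n_channels: int = 4,
    seed: int = 0,
    common_mode: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Multichannel voltage: Gaussian noise + optional common-mode artifact
    + spike templates inserted at ground-truth times.

    Each entry of ``trains`` is ``(spike_train, waveform, channel_weights)``;
    the waveform is scaled by the per-channel weight.  Returns the
    channels x samples array and the ground-truth spike times per unit.
    """
    if fs < 20_000:
        raise ValueError("sampling rate must be at least 20 kHz")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    v = rng.normal(0.0, noise_sd, size=(n_channels, n))
    if common_mode is not None:
        cm = np.asarray(common_mode, dtype=float)
        if cm.size > n:
            raise ValueError("common-mode trace longer than the recording")
        v[:, : cm.size] += cm[None, :]
    truth = {}
    for st, wf, weights in trains:
        wf = np.asarray(wf, dtype=float)
        if wf.size > n:
            raise ValueError("template longer than the recording")
        weights = np.asarray(weights, dtype=float)
        idx = np.round(st.times_s * fs).astype(int)
        idx = idx[(idx >= 0) & (idx + wf.size <= n)]
        for ch in range(n_channels):
            if weights[ch] == 0:
                continue
            for i in idx:
                v[ch, i : i + wf.size] += weights[ch] * wf
        truth[st.unit_id] = idx / fs
    return v, truth


def simulate_laser_block(
    unit: SpikeTrain,
    latency_s: float = 0.003,
    jitter_s: float = 0.001,
    p_follow: float = 0.8,
    pulse_rate_hz: float = 10.0,
    n_pulses: int = 500,
    seed: int = 0,
    start_s: float = 0.0,
) -> tuple[SpikeTrain, np.ndarray]:
    """Append laser-locked spikes: each pulse adds a spike at
    ``pulse + latency + N(0, jitter)`` with probability ``p_follow``."""
    if not (0 <= p_follow <= 1):
        raise ValueError("p_follow must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pulses = start_s + np.arange(n_pulses) / pulse_rate_hz
    follow = rng.random(n_pulses) < p_follow
    locked = pulses[follow] + latency_s + rng.normal(0, jitter_s, follow.sum())
    locked = locked[locked >= 0]
    times = np.sort(np.concatenate([unit.times_s, locked]))
    return SpikeTrain(unit.unit_id, times, unit.region, unit.session_id), pulses
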