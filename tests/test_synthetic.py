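"""Tests of the synthetic recording and behavior generators."""

import numpy as np
import pytest

from mesolimbic import preprocessing as pre
from mesolimbic import rl
from mesolimbic import synthetic as syn
from mesolimbic.core import bin_spike_counts


class TestTaskSession:
    def test_seed_reproducibility(self):
        cfg, agent = syn.TaskConfig(), syn.AgentSpec()
        t1, l1 = syn.simulate_task_session(cfg, agent, 200, seed=9)
        t2, l2 = syn.simulate_task_session(cfg, agent, 200, seed=9)
        assert t1.df.equals(t2.df) and l1.equals(l2)

    def test_no_more_than_three_consecutive_odors(self):
        for seed in range(5):
            table, _ = syn.simulate_task_session(
                syn.TaskConfig(), syn.AgentSpec(), 400, seed=seed
            )
            odors = table.df["state"].to_numpy()
            run, longest = 1, 1
            for x, y in zip(odors[:-1], odors[1:]):
                run = run + 1 if x == y else 1
                longest = max(longest, run)
            assert longest <= 3

    def test_zero_beta_agent_licks_at_chance(self):
        agent = syn.AgentSpec("qph_f", (0.4, 0.1, 0.3, 0.0))
        table, _ = syn.simulate_task_session(syn.TaskConfig(), agent, 400, seed=2)
        frac_lick = (table.df["action"] == "lick").mean()
        assert abs(frac_lick - 0.5) < 3 * 0.5 / np.sqrt(400)

    def test_zero_learning_rates_freeze_q(self):
        agent = syn.AgentSpec("qph_f", (0.0, 0.0, 0.3, 5.0))
        _, latents = syn.simulate_task_session(syn.TaskConfig(), agent, 100, seed=3)
        assert (latents["Q_s_lick"] == 0.5).all()
        assert (latents["Q_s_restrain"] == 0.5).all()

    def test_rewards_only_on_cs_plus_licks(self):
        table, _ = syn.simulate_task_session(syn.TaskConfig(), syn.AgentSpec(), 300, seed=4)
        d = table.df
        rewarded = d[d["reward"] > 0]
        assert (rewarded["cs_plus"] & (rewarded["action"] == "lick")).all()

    def test_agent_reaches_criterion_in_most_sessions(self):
        """The forgetting agent at its reference parameters learns the task:
        the trailing fraction correct reaches 0.8 before trial 400 in nearly
        every run."""
        cfg = syn.TaskConfig()
        agent = syn.AgentSpec("qph_f", (0.4, 0.1, 0.3, 5.0))
        ok = sum(
            syn.simulate_task_session(cfg, agent, 400, seed=s)[0].complete
            for s in range(100)
        )
        assert ok >= 95

    def test_incomplete_session_flagged_not_dropped(self):
        agent = syn.AgentSpec("qph_f", (0.0, 0.0, 0.3, 0.0))  # cannot learn
        table, _ = syn.simulate_task_session(syn.TaskConfig(), agent, 120, seed=5)
        assert not table.complete
        assert len(table) == 120
        assert (table.df["phase"] == "original").all()


class TestSimulateUnit:
    def test_silent_spec_gives_empty_train(self):
        st = syn.simulate_unit(syn.UnitSpec(baseline_hz=0.0), span_s=100.0, seed=0)
        assert st.n_spikes == 0

    def test_poisson_count_within_ci(self):
        st = syn.simulate_unit(syn.UnitSpec(baseline_hz=2.0), span_s=1000.0, seed=1)
        assert abs(st.n_spikes - 2000) < 3 * np.sqrt(2000)

    def test_negative_kernel_never_yields_negative_rate(self):
        table = syn.simulate_passive_session_table({"pre": 20}, seed=0)
        spec = syn.UnitSpec(baseline_hz=0.5,
                            kernels={"A": syn.OdorKernel(-5.0, 0.0, 1.0)})
        st = syn.simulate_unit(spec, table, seed=2)  # clamped at zero, no error
        assert st.n_spikes >= 0

    def test_learning_gain_raises_late_response_rates(self):
        """With a rising value trace and positive gain, the CS-window rate in
        the last trials exceeds the first trials in most runs (sign test)."""
        table = syn.simulate_passive_session_table({"pre": 48}, seed=3)
        v = np.linspace(0.0, 1.0, len(table))
        wins = 0
        n_seeds = 30
        for seed in range(n_seeds):
            spec = syn.UnitSpec(baseline_hz=1.0,
                                kernels={"A": syn.OdorKernel(4.0, 0.0, 1.0)},
                                learning_gain=1.0)
            st = syn.simulate_unit(spec, table, v, seed=seed)
            onsets = table.df["onset_s"].to_numpy()
            counts = np.array([
                np.sum((st.times_s >= t) & (st.times_s < t + 1.0)) for t in onsets
            ])
            wins += counts[-12:].mean() > counts[:12].mean()
        from scipy.stats import binomtest

        assert binomtest(wins, n_seeds, 0.5, alternative="greater").pvalue < 0.01


class TestAssemblyPair:
    def test_uncoupled_ccg_uniform(self):
        coup = syn.AssemblyCouplingSpec(lag_s=0.2, precision_s=0.05, efficacy=0.0)
        a, b = syn.simulate_assembly_pair(
            syn.UnitSpec(baseline_hz=3.0), syn.UnitSpec(baseline_hz=3.0),
            coup, span_s=600.0, seed=7,
        )
        # lag histogram of b-spikes around a-spikes should be flat
        diffs = []
        for t in a.times_s:
            sel = b.times_s[(b.times_s > t - 0.5) & (b.times_s < t + 0.5)]
            diffs.extend(sel - t)
        hist, _ = np.histogram(diffs, bins=20, range=(-0.5, 0.5))
        from scipy.stats import chisquare

        assert chisquare(hist).pvalue > 0.01

    def test_coupled_ccg_peak_at_induced_lag(self, coupled_pair):
        a, b = coupled_pair
        diffs = []
        for t in a.times_s:
            sel = b.times_s[(b.times_s > t - 0.5) & (b.times_s < t + 0.5)]
            diffs.extend(sel - t)
        hist, edges = np.histogram(diffs, bins=40, range=(-0.5, 0.5))
        peak = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        assert 0.1 <= peak <= 0.3

    def test_swapping_roles_flips_peak_sign(self, coupled_pair):
        a, b = coupled_pair

        def peak_lag(x, y):
            diffs = []
            for t in x.times_s:
                sel = y.times_s[(y.times_s > t - 0.5) & (y.times_s < t + 0.5)]
                diffs.extend(sel - t)
            hist, edges = np.histogram(diffs, bins=40, range=(-0.5, 0.5))
            i = np.argmax(hist)
            return 0.5 * (edges[i] + edges[i + 1])

        assert peak_lag(a, b) > 0 > peak_lag(b, a)


class TestVoltage:
    def test_noise_free_template_fully_recovered(self):
        fs = 30000.0
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(1, 29, 60))
        st = syn.SpikeTrain("u", times) if hasattr(syn, "SpikeTrain") else None
        from mesolimbic.core import SpikeTrain

        st = SpikeTrain("u", times)
        wf = syn.default_waveform(fs) * 5.0
        v, truth = syn.simulate_voltage([(st, wf, np.array([1.0]))], fs, 1e-6, 30,
                                        n_channels=1, seed=1)
        res = pre.detect_spikes(v, fs)
        det = res.events["time_s"].to_numpy()
        assert all(np.any(np.abs(det - t) <= 0.001) for t in truth["u"])

    def test_template_longer_than_trace_rejected(self):
        from mesolimbic.core import SpikeTrain

        st = SpikeTrain("u", np.array([0.1]))
        fs = 30000.0
        wf = np.ones(int(2 * fs))
        with pytest.raises(ValueError):
            syn.simulate_voltage([(st, wf, np.array([1.0]))], fs, 1.0, 1.0,
                                 n_channels=1, seed=0)


class TestLaserBlock:
    def test_distant_latency_is_not_tagged(self, rng):
        from mesolimbic import units
        from mesolimbic.core import SpikeTrain

        base = SpikeTrain("u", np.sort(rng.uniform(0, 60, 300)))
        unit, pulses = syn.simulate_laser_block(
            base, latency_s=0.050, jitter_s=0.001, p_follow=0.9,
            pulse_rate_hz=10.0, n_pulses=500, seed=1,
        )
        out = units.opto_tag(unit, pulses, n_controls=2000, seed=2)
        assert not out["tagged"]

    def test_locked_spikes_added_with_probability(self):
        from mesolimbic.core import SpikeTrain

        base = SpikeTrain("u", np.array([]))
        unit, pulses = syn.simulate_laser_block(
            base, p_follow=0.5, n_pulses=400, seed=3
        )
        assert abs(unit.n_spikes - 200) < 3 * np.sqrt(100)


def test_generators_bit_reproducible_under_seed():
    a1 = syn.simulate_unit(syn.UnitSpec(baseline_hz=3.0), span_s=50, seed=42)
    a2 = syn.simulate_unit(syn.UnitSpec(baseline_hz=3.0), span_s=50, seed=42)
    assert np.array_equal(a1.times_s, a2.times_s)
    v1, _ = syn.simulate_voltage([], 20000.0, 1.0, 2.0, seed=6)
    v2, _ = syn.simulate_voltage([], 20000.0, 1.0, 2.0, seed=6)
    assert np.array_equal(v1, v2)


def test_yaml_config_roundtrip(tmp_path):
    cfg = tmp_path / "gen.yaml"
    cfg.write_text(
        "seed: 7\n"
        "task: {stim_duration_s: 1.0, retrieval_onset_s: 1.5}\n"
        "agent: {model: qph_f, theta: [0.4, 0.1, 0.3, 5.0]}\n"
        "units:\n"
        "  - {baseline_hz: 2.0, kernels: {A: {amplitude_hz: 3.0}}}\n"
        "coupling: {lag_s: 0.2, efficacy: 0.5}\n"
    )
    specs = syn.specs_from_yaml(cfg)
    assert specs["seed"] == 7
    assert specs["task"].stim_duration_s == 1.0
    assert specs["agent"].model == "qph_f"
    assert specs["units"][0].kernels["A"].amplitude_hz == 3.0
    assert specs["coupling"].efficacy == 0.5


def test_yaml_config_without_seed_rejected(tmp_path):
    cfg = tmp_path / "gen.yaml"
    cfg.write_text("task: {stim_duration_s: 1.0}\n")
    with pytest.raises(ValueError):
        syn.specs_from_yaml(cfg)
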