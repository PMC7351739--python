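"""Tests of cell-type classification, auROC traces, clustering and tagging."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from mesolimbic import synthetic as syn, units
from mesolimbic.core import SpikeTrain, TrialTable
from mesolimbic.units import AuROCTrace


def _trial_table(n=50, iti=10.0, phase="pre"):
    onsets = 5.0 + np.arange(n) * iti
    return TrialTable(pd.DataFrame({
        "trial": np.arange(n), "odor": ["A"] * n, "phase": [phase] * n,
        "onset_s": onsets,
    }))


def _poisson_train(rate, dur, seed, uid="u"):
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * dur)
    return SpikeTrain(uid, np.sort(rng.uniform(0, dur, n)))


class TestPassiveClassification:
    def test_low_rate_stable_unit_is_spn(self):
        trials = _trial_table()
        u = SpikeTrain("u", np.arange(0, 520, 1 / 1.2))  # metronomic 1.2 Hz
        lab = units.classify_vs_passive(u, trials)
        assert lab.label == "SPN"
        assert lab.evidence["baseline_hz"] == pytest.approx(1.2, rel=0.05)

    def test_high_rate_unit_is_not_spn(self):
        trials = _trial_table()
        u = SpikeTrain("u", np.arange(0, 520, 1 / 6.5))
        assert units.classify_vs_passive(u, trials).label != "SPN"

    def test_mid_session_rate_dip_excludes_unit(self):
        trials = _trial_table()
        times = np.arange(0, 520, 1.0)  # 1 Hz metronome ...
        dip = (times > 175) & (times < 345)
        keep = ~dip | (times % 10 >= 3)  # ... -30% dip inside baseline windows
        u = SpikeTrain("u", times[keep])
        lab = units.classify_vs_passive(u, trials)
        assert lab.label == "excluded"
        assert lab.evidence["fluctuation"] > 0.20


class TestActiveClassification:
    def _train_from_isis(self, isis, uid="u"):
        return SpikeTrain(uid, np.cumsum(isis))

    def test_low_rate_is_spn(self):
        u = _poisson_train(0.8, 600, seed=4)
        assert units.classify_vs_active(u).label == "SPN"

    def test_fast_spiking_excluded_above_12hz(self):
        u = _poisson_train(30.0, 60, seed=5)
        assert units.classify_vs_active(u).label == "FS"

    def test_regular_midrate_unit_is_cholinergic(self):
        rng = np.random.default_rng(6)
        sigma = 0.77  # lognormal ISIs: CV ~0.9, few short ISIs
        isis = rng.lognormal(np.log(0.25) - sigma**2 / 2, sigma, 2000)
        lab = units.classify_vs_active(self._train_from_isis(isis))
        assert lab.label == "ChAT"
        assert lab.evidence["isi_cv"] < 1.2
        assert lab.evidence["frac_isi_lt_60ms"] <= 0.20

    def test_irregular_no_pause_unit_is_fast_spiking(self):
        rng = np.random.default_rng(7)
        sigma = 1.27  # CV ~2 before clipping
        isis = np.clip(rng.lognormal(np.log(0.2) - sigma**2 / 2, sigma, 3000),
                       None, 1.9)
        lab = units.classify_vs_active(self._train_from_isis(isis))
        assert lab.label == "FS"
        assert lab.evidence["isi_cv"] > 1.2
        assert lab.evidence["frac_isi_gt_2s"] == 0.0

    def test_irregular_pausing_unit_is_spn(self):
        rng = np.random.default_rng(8)
        sigma = 1.27
        isis = rng.lognormal(np.log(0.25) - sigma**2 / 2, sigma, 3000)
        isis[::100] = 3.0  # clear pauses
        lab = units.classify_vs_active(self._train_from_isis(isis))
        assert lab.label == "SPN"

    def test_too_few_isis_unclassified(self):
        u = SpikeTrain("u", np.arange(50) * 0.1)
        assert units.classify_vs_active(u).label == "unclassified"

    def test_every_random_unit_gets_exactly_one_label(self, rng):
        allowed = {"SPN", "FS", "ChAT", "unclassified"}
        for k in range(20):
            rate = float(rng.uniform(0.3, 30))
            u = _poisson_train(rate, 300, seed=1000 + k)
            assert units.classify_vs_active(u).label in allowed


class TestAuROC:
    def test_equal_distributions_near_half_and_not_responsive(self):
        events = 10.0 + np.arange(40) * 10.0
        u = _poisson_train(3.0, 420, seed=9)
        tr = units.auroc_trace(u, events)
        assert np.all(np.abs(tr.values - 0.5) < 0.2)
        assert not tr.responsive

    def test_full_separation_gives_unit_auroc(self):
        events = 10.0 + np.arange(20) * 10.0
        resp = np.concatenate([e + np.arange(0.025, 1.0, 0.05) for e in events])
        u = SpikeTrain("u", np.sort(resp))
        tr = units.auroc_trace(u, events)
        inside = (tr.bin_starts_s >= 0) & (tr.bin_starts_s + 0.2 <= 1.0)
        assert np.allclose(tr.values[inside], 1.0)
        assert tr.responsive

    def test_auroc_equals_rank_statistic_oracle(self, rng):
        for _ in range(100):
            x = rng.poisson(rng.uniform(0.5, 6), rng.integers(10, 40))
            y = rng.poisson(rng.uniform(0.5, 6), rng.integers(20, 120))
            expected = mannwhitneyu(x, y).statistic / (x.size * y.size)
            assert units.auroc(x, y) == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.poisson(3, 30)
        y = rng.poisson(2, 60)
        assert units.auroc(x**2 + 1, y**2 + 1) == pytest.approx(units.auroc(x, y))

    def test_too_few_trials_rejected(self):
        u = _poisson_train(3.0, 100, seed=10)
        with pytest.raises(ValueError):
            units.auroc_trace(u, np.array([10.0, 20.0]))


def _archetype_traces(rng, n_per=20, noise=0.02):
    traces = []
    for kind in range(3):
        for i in range(n_per):
            base = np.full(54, 0.5)
            if kind == 0:    # phasic CS+ and US excitation
                base[5:15] += 0.25
                base[32:42] += 0.25
            elif kind == 1:  # sustained CS+ excitation only
                base[5:20] += 0.2
            else:            # inhibition
                base[5:15] -= 0.12
                base[32:42] -= 0.15
            tr = base + rng.normal(0, noise, 54)
            uid = f"k{kind}i{i}"
            traces.append((
                AuROCTrace(uid, "CS+", np.arange(27), tr[:27], True, 0.01),
                AuROCTrace(uid, "US", np.arange(27), tr[27:], True, 0.01),
            ))
    return traces


class TestVTAClustering:
    def test_archetypes_perfectly_recovered(self, rng):
        traces = _archetype_traces(rng)
        labels = [l.label for l in units.cluster_vta(traces)]
        assert labels[:20] == ["DAN_typeI"] * 20
        assert labels[20:40] == ["typeII"] * 20
        assert labels[40:] == ["typeIII"] * 20

    def test_duplicating_traces_leaves_labels_invariant(self, rng):
        traces = _archetype_traces(rng, n_per=8)
        base = [l.label for l in units.cluster_vta(traces)]
        doubled = [l.label for l in units.cluster_vta(traces + traces)]
        assert doubled[: len(base)] == base
        assert doubled[len(base):] == base

    def test_tagged_units_concentrate_in_one_cluster(self, rng):
        """Units drawn from the dopaminergic archetype should nearly all land
        in a single cluster (the logic behind tagged-unit enrichment)."""
        traces = _archetype_traces(rng, n_per=20, noise=0.04)
        tagged_idx = range(20)  # archetype-I units play the tagged role
        labels = units.cluster_vta(traces)
        tagged_clusters = [labels[i].evidence["cluster"] for i in tagged_idx]
        top = max(np.bincount(tagged_clusters))
        assert top / len(tagged_clusters) >= 0.9

    def test_fewer_than_three_units_rejected(self, rng):
        with pytest.raises(ValueError):
            units.cluster_vta(_archetype_traces(rng, n_per=1)[:2])


class TestOptoTag:
    def test_locked_unit_tagged(self, rng):
        base = SpikeTrain("u", np.sort(rng.uniform(0, 60, 300)))
        unit, pulses = syn.simulate_laser_block(
            base, latency_s=0.003, jitter_s=0.001, p_follow=0.8,
            pulse_rate_hz=10.0, n_pulses=500, seed=11,
        )
        assert units.opto_tag(unit, pulses, seed=12)["tagged"]

    def test_silent_unit_not_tagged_without_error(self):
        u = SpikeTrain("u", np.array([]))
        pulses = np.arange(200) / 10.0
        out = units.opto_tag(u, pulses, n_controls=500, seed=0)
        assert not out["tagged"]

    def test_too_few_pulses_rejected(self):
        u = SpikeTrain("u", np.arange(100) * 0.1)
        with pytest.raises(ValueError):
            units.opto_tag(u, np.arange(50) / 10.0)


class TestResponseClass:
    def _unit_with_rates(self, trials, base_rate, resp_rate, seed=0):
        """Deterministic counts: exactly the requested mean rates."""
        def count(rate, i):
            return int(rate) + (1 if (i % 10) < round((rate % 1) * 10) else 0)

        times = []
        for i, t in enumerate(trials.df["onset_s"]):
            nb, nr = count(base_rate, i), count(resp_rate, i)
            times.extend(t - 1 + (np.arange(nb) + 0.5) / max(nb, 1))
            times.extend(t + (np.arange(nr) + 0.5) / max(nr, 1))
        return SpikeTrain("u", np.sort(np.array(times)))

    @pytest.mark.parametrize(
        "base, resp, expected",
        [
            (1.0, 1.5, "excitatory"),   # >= 1 Hz and >= +20%
            (0.4, 0.1, "none"),         # inhibition gated by 0.5 Hz baseline
            (2.0, 1.4, "inhibitory"),   # -30%
            (2.0, 2.0, "none"),
        ],
    )
    def test_rule_examples(self, base, resp, expected):
        trials = _trial_table(n=60)
        u = self._unit_with_rates(trials, base, resp, seed=17)
        assert units.response_class(u, trials, phases=("pre",)) == expected
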