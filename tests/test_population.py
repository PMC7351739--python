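"""Tests of population-vector construction, distances, decoding, embedding."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mesolimbic import population as pop


class TestMetrics:
    def test_identical_vectors_zero_distance(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pop.cosine_distance(x, x) == pytest.approx(0.0)
        assert pop.euclidean_norm_distance(x, x) == 0.0

    def test_orthogonal_vectors_cosine_one(self):
        assert pop.cosine_distance(np.array([1.0, 0.0]), np.array([0.0, 2.0])) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        x, y = np.array([1.0, 2.0, 2.0]), np.array([3.0, 0.0, 4.0])
        assert pop.cosine_distance(x, y) == pytest.approx(1 - 11 / 15)
        assert pop.euclidean_norm_distance(x, y) == pytest.approx(np.sqrt(12) / 3)

    def test_zero_norm_cosine_is_nan(self):
        assert np.isnan(pop.cosine_distance(np.zeros(3), np.ones(3)))

    @given(st.floats(0.01, 100), st.floats(0.01, 100))
    def test_cosine_invariant_euclidean_linear_under_scaling(self, c1, c2):
        x = np.array([1.0, 2.0, 0.5])
        y = np.array([0.3, 1.0, 2.0])
        assert pop.cosine_distance(c1 * x, c2 * y) == pytest.approx(
            pop.cosine_distance(x, y), abs=1e-9
        )
        assert pop.euclidean_norm_distance(c1 * x, c1 * y) == pytest.approx(
            c1 * pop.euclidean_norm_distance(x, y), rel=1e-9
        )


def _session(n_trials_per_phase, n_units=4, n_bins=16, code=0.0):
    """Tensor stub whose values encode the trial index for traceability."""
    out = {}
    for ph, n in n_trials_per_phase.items():
        t = np.arange(n, dtype=float)[:, None, None] + code
        out[("A", ph)] = np.broadcast_to(t, (n, n_units, n_bins)).copy()
        out[("B", ph)] = np.broadcast_to(t, (n, n_units, n_bins)).copy() + 0.5
    return out


class TestBuildVectors:
    def test_single_session_equals_its_own_grouping(self):
        s = _session({"pre": 9, "post": 9})
        pv = pop.build_population_vectors([s], 0.25, (-2, 2))
        # groups of 3 averaged: means are 1, 4, 7
        assert np.allclose(pv.counts[("A", "pre")][:, 0, 0], [1, 4, 7])

    def test_sessions_truncated_to_common_minimum(self):
        s1 = _session({"pre": 30, "post": 30})
        s2 = _session({"pre": 39, "post": 39})
        pv = pop.build_population_vectors([s1, s2], 0.25, (-2, 2))
        a = pv.counts[("A", "post")]
        assert a.shape[0] == 10
        # longer session's 'post' loses its LAST groups: first group mean = 1
        assert a[0, 4, 0] == pytest.approx(1.0)
        # 'pre' loses its INITIAL groups instead: first kept group mean = 10
        b = pv.counts[("A", "pre")]
        assert b[0, 4, 0] == pytest.approx(10.0)

    def test_permuted_matching_is_rowwise_permutation(self):
        s1 = _session({"pre": 9, "post": 9})
        s2 = _session({"pre": 9, "post": 9}, code=100.0)
        prog = pop.build_population_vectors([s1, s2], 0.25, (-2, 2))
        perms = pop.build_population_vectors(
            [s1, s2], 0.25, (-2, 2), matching="permuted", n_permutations=4, seed=3
        )
        assert len(perms) == 4
        for pv in perms:
            for key in prog.counts:
                ref = np.sort(prog.counts[key][:, 0, 0])
                got = np.sort(pv.counts[key][:, 0, 0])
                assert np.allclose(ref, got)

    def test_empty_sessions_rejected(self):
        with pytest.raises(ValueError):
            pop.build_population_vectors([], 0.25, (-2, 2))


def _gaussian_pv(rng, sep=0.0, n_groups=20, n_units=12, n_bins=16, onset_bin=8):
    """Population vector with Gaussian response structure; classes separated
    by ``sep`` pooled SDs along a random direction."""
    direction = rng.normal(size=n_units)
    direction /= np.linalg.norm(direction)
    counts = {}
    for odor, mu in (("A", 0.0), ("B", sep)):
        for ph in ("pre", "post"):
            base = rng.normal(5.0, 1.0, size=(n_groups, n_units, n_bins))
            base[:, :, onset_bin:] += mu * direction[None, :, None]
            counts[(odor, ph)] = base
    return pop.PopulationVector(counts, 0.25, (-2.0, 2.0))


class TestQDA:
    def test_df_formula(self):
        assert pop.qda_df_total(3) == 19
        d = 3
        assert d * (d - 1) // 2 + 2 * d + 1 == 10

    def test_identical_classes_decode_at_chance(self, rng):
        accs = []
        for _ in range(5):
            pv = _gaussian_pv(rng, sep=0.0)
            out = pop.qda_decode(pv, "passive", dims=(3,))
            accs.append(out[3]["accuracy"]["pre"])
        assert abs(np.mean(accs) - 0.5) < 0.15

    def test_well_separated_classes_decode_reliably(self, rng):
        pv = _gaussian_pv(rng, sep=5.0)
        out = pop.qda_decode(pv, "passive", dims=(3,))
        assert out[3]["accuracy"]["pre"] >= 0.95
        assert out[3]["accuracy"]["post"] >= 0.95

    def test_overparameterized_dims_refused(self, rng):
        pv = _gaussian_pv(rng, sep=1.0, n_groups=9)  # 18 points < 19 params
        assert pop.qda_decode(pv, "passive", dims=(3,)) == {}


class TestDeviation:
    def test_constant_activity_zero_deviation(self):
        counts = {("A", ph): np.full((6, 5, 16), 4.0) for ph in ("pre", "post")}
        pv = pop.PopulationVector(counts, 0.25, (-2.0, 2.0))
        out = pop.deviation_from_baseline(pv, "passive", odor="A")
        assert np.allclose(out["deviation"]["pre"], 0.0)
        assert not out["significant_bins"].any()

    def test_response_shift_detected_in_post_only(self, rng):
        counts = {}
        for ph, gain in (("pre", 0.0), ("post", 3.0)):
            x = rng.poisson(2.0, size=(20, 10, 16)).astype(float)
            x[:, :3, 8:12] += gain
            counts[("A", ph)] = x
        pv = pop.PopulationVector(counts, 0.25, (-2.0, 2.0))
        out = pop.deviation_from_baseline(pv, "passive", odor="A",
                                          metric="euclidean_norm")
        assert out["significant_bins"][:4].any()


class TestEmbedding:
    def test_constant_trajectory_flagged_degenerate(self):
        counts = {("A", "pre"): np.full((6, 5, 16), 2.0),
                  ("A", "post"): np.full((6, 5, 16), 2.0)}
        pv = pop.PopulationVector(counts, 0.25, (-2.0, 2.0))
        out = pop.embed_trajectories(pv)
        assert out["degenerate"]

    def test_mds_preserves_distance_ranking_on_exact_configuration(self, rng):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 2, 0], [0, 0, 4.0]])
        counts = {("A", "pre"): np.repeat(pts[:, :, None], 16, axis=2)}
        pv = pop.PopulationVector(counts, 0.25, (-2.0, 2.0))
        out = pop.mds_responses(pv, "passive")
        emb = out["points"]
        from scipy.spatial.distance import pdist
        from scipy.stats import spearmanr

        rho = spearmanr(pdist(pts), pdist(emb)).statistic
        assert rho == pytest.approx(1.0)

    def test_mds_distances_invariant_under_rigid_rotation(self, rng):
        from scipy.spatial.distance import pdist
        from scipy.stats import ortho_group

        X = rng.normal(size=(10, 6))
        R = ortho_group.rvs(6, random_state=1)
        counts1 = {("A", "pre"): np.repeat(X[:, :, None], 16, axis=2)}
        counts2 = {("A", "pre"): np.repeat((X @ R)[:, :, None], 16, axis=2)}
        d1 = pop.mds_responses(pop.PopulationVector(counts1, 0.25, (-2, 2)), "passive")
        d2 = pop.mds_responses(pop.PopulationVector(counts2, 0.25, (-2, 2)), "passive")
        assert np.allclose(np.sort(pdist(d1["points"])), np.sort(pdist(d2["points"])),
                           rtol=0.05, atol=0.05)


def test_progressive_and_permuted_agree_on_effect_sign():
    """With a real injected gain, the progressive matching and permuted
    trial-matching realizations point the same way."""
    from mesolimbic import synthetic as syn

    sessions = syn.simulate_plasticity_sessions(
        2, inject_gain=0.5, seed=6,
        n_trials_per_phase={"pre": 100, "pairing": 12, "post": 90},
    )
    def effect(pv):
        t = pop.response_vectors_and_distances(pv, "passive")
        x = t["tests"][("euclidean_norm", "odor-A pre-post vs pre-pre")]
        return x["mean_pre_post"] - x["mean_pre_pre"]

    prog = pop.build_population_vectors(sessions, 0.25, (-2, 2))
    perms = pop.build_population_vectors(sessions, 0.25, (-2, 2),
                                         matching="permuted",
                                         n_permutations=10, seed=4)
    sign = np.sign(effect(prog))
    agree = sum(np.sign(effect(pv)) == sign for pv in perms)
    assert sign > 0
    assert agree >= 8
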