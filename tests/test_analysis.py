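"""Probe distances, curves, scores, pathway classes, ROC and bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hnmmc.analysis import (AnalysisError, BindingRecord, ProbeSet,
                            ReplicaSet, auroc, bootstrap_auroc_sd,
                            clamp_distance, classify_pathway,
                            detachment_score, detachment_time,
                            mean_sem_curves, pearson_r, per_replica_scores,
                            probe_distances)


def make_replicas(distances, steps=None, ceiling=3.0):
    d = np.asarray(distances, dtype=float)
    if steps is None:
        steps = np.arange(d.shape[1])
    return ReplicaSet("pep", "AAAAAAAAA", steps, d, ceiling=ceiling)


class TestProbeDistances:
    def test_three_four_five_triangle(self, toy):
        structure, _, probes = toy
        coords = structure.coords.copy()
        resolved = probes.resolve(structure)
        i, j = resolved[0]
        coords[i] = [0.0, 0.0, 0.0]
        coords[j] = [0.3, 0.4, 0.0]
        d = probe_distances(coords, probes, resolved)
        assert d[0] == pytest.approx(0.5)

    def test_coincident_pair_is_zero(self, toy):
        structure, _, probes = toy
        coords = structure.coords.copy()
        resolved = probes.resolve(structure)
        i, j = resolved[1]
        coords[j] = coords[i]
        assert probe_distances(coords, probes, resolved)[1] == 0.0

    def test_missing_probe_residue_raises(self, toy):
        bad = ProbeSet("P", "M", n=(1, 99), mid=(5, 100), c=(9, 101))
        with pytest.raises(Exception):
            bad.resolve(toy[0])


class TestClamp:
    def test_above_ceiling_clamped_to_three(self):
        assert clamp_distance(3.5) == 3.0

    def test_below_and_at_ceiling_unchanged(self):
        assert clamp_distance(2.9) == 2.9
        assert clamp_distance(3.0) == 3.0

    @given(st.floats(min_value=0, max_value=10),
           st.floats(min_value=0.1, max_value=5))
    @settings(max_examples=100, deadline=None)
    def test_idempotent_and_bounded(self, d, ceiling):
        once = clamp_distance(d, ceiling)
        assert once <= ceiling
        assert clamp_distance(once, ceiling) == once


class TestMeanSem:
    def test_identical_replicas_have_zero_sem(self):
        d = np.ones((4, 10, 3)) * 1.5
        curves = mean_sem_curves(make_replicas(d))
        assert np.all(curves["sem_nm"] == 0)
        assert np.all(curves["mean_nm"] == 1.5)

    def test_two_replica_hand_values(self):
        d = np.empty((2, 1, 3))
        d[0] = 1.0
        d[1] = 2.0
        curves = mean_sem_curves(make_replicas(d))
        assert np.all(curves["mean_nm"] == 1.5)
        # sample SD = sqrt(0.5) * sqrt(2) = 0.7071; SEM = SD/sqrt(2) = 0.5
        np.testing.assert_allclose(curves["sem_nm"], 0.5)

    def test_single_replica_sem_missing(self):
        curves = mean_sem_curves(make_replicas(np.ones((1, 5, 3))))
        assert curves["sem_nm"].isna().all()
        assert np.all(curves["mean_nm"] == 1.0)


class TestDetachmentScore:
    def test_all_at_ceiling(self):
        assert detachment_score(make_replicas(np.full((3, 5, 3), 3.0))) == 3.0

    def test_single_snapshot_mean(self):
        d = np.array([[[1.0, 2.0, 3.0]]])
        assert detachment_score(make_replicas(d)) == pytest.approx(2.0)

    def test_monotone_in_uniform_shift(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.5, 2.0, size=(3, 20, 3))
        s0 = detachment_score(make_replicas(base))
        s1 = detachment_score(make_replicas(base + 0.3))
        assert s1 > s0

    def test_probe_subset_option(self):
        d = np.zeros((1, 1, 3))
        d[..., 1] = 3.0
        r = make_replicas(d)
        assert detachment_score(r, probe_subset=("mid",)) == 3.0
        assert detachment_score(r, probe_subset=("N", "C")) == 0.0


def staircase(t_n, t_mid, t_c, n=200, low=1.0, high=2.5):
    """Trajectory whose probes cross 2 nm at the given snapshots."""
    d = np.full((n, 3), low)
    for k, t in enumerate((t_n, t_mid, t_c)):
        if t is not None:
            d[t:, k] = high
    return d


class TestPathway:
    def test_all_below_threshold_is_stable(self):
        assert classify_pathway(np.full((50, 3), 1.0)) == "stable"

    def test_c_first_constructed_ordering(self):
        assert classify_pathway(staircase(100, 120, 20)) == "C-first"

    def test_n_first_symmetric(self):
        assert classify_pathway(staircase(20, 120, 100)) == "N-first"

    def test_simultaneous_tie(self):
        assert classify_pathway(staircase(40, 80, 40)) == "simultaneous-ends"

    def test_middle_first_detected(self):
        assert classify_pathway(staircase(100, 20, 150)) == "middle-first"

    def test_persistence_window_filters_blips(self):
        d = np.full((100, 3), 1.0)
        d[10:15, 2] = 2.5  # 5-snapshot blip, below the 10-snapshot window
        assert detachment_time(d[:, 2], 2.0, 10) == np.inf
        assert classify_pathway(d) == "stable"

    def test_empty_trajectory_rejected(self):
        with pytest.raises(AnalysisError):
            classify_pathway(np.empty((0, 3)))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([3.0, 2.9, 1.0, 0.9],
                     ["non-binder", "non-binder", "binder", "binder"]) == 1.0

    def test_all_ties_give_half(self):
        assert auroc([1.0, 1.0, 1.0, 1.0],
                     ["non-binder", "binder", "non-binder", "binder"]) == 0.5

    def test_hand_enumerated_pairs(self):
        # non-binders (3.0, 1.0) vs binders (2.0, 0.5): 3 of 4 pairs correct
        got = auroc([3.0, 1.0, 2.0, 0.5],
                    ["non-binder", "non-binder", "binder", "binder"])
        assert got == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(AnalysisError):
            auroc([1.0, 2.0], ["binder", "binder"])

    def brute_force(self, scores, labels):
        pos = [s for s, l in zip(scores, labels) if l == "non-binder"]
        neg = [s for s, l in zip(scores, labels) if l == "binder"]
        total = 0.0
        for p in pos:
            for n in neg:
                total += 1.0 if p > n else (0.5 if p == n else 0.0)
        return total / (len(pos) * len(neg))

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(50):
            m = rng.integers(2, 30)
            n = rng.integers(2, 30)
            scores = np.round(rng.normal(size=m + n), 1)  # ties likely
            labels = ["non-binder"] * m + ["binder"] * n
            assert auroc(scores, labels) == pytest.approx(
                self.brute_force(scores, labels))

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        scores = rng.normal(size=40)
        labels = np.where(rng.random(40) < 0.5, "non-binder", "binder")
        if len(set(labels)) < 2:
            labels[0] = "binder"
            labels[1] = "non-binder"
        got = auroc(scores, labels)
        want = roc_auc_score((labels == "non-binder").astype(int), scores)
        assert got == pytest.approx(want)

    @given(st.lists(st.tuples(st.floats(-1e3, 1e3),
                              st.sampled_from(["binder", "non-binder"])),
                    min_size=4, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_complement_symmetry(self, data):
        scores = np.array([s for s, _ in data])
        labels = [l for _, l in data]
        if "binder" not in labels or "non-binder" not in labels:
            return
        if len(np.unique(scores)) < len(scores):
            return  # symmetry stated for tie-free scores
        assert auroc(scores, labels) + auroc(-scores, labels) == \
            pytest.approx(1.0)


class TestPearson:
    def test_perfect_positive_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        assert pearson_r([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_constant_vector_rejected(self):
        with pytest.raises(AnalysisError):
            pearson_r([1, 2, 3], [5, 5, 5])

    def test_too_few_points_rejected(self):
        with pytest.raises(AnalysisError):
            pearson_r([1, 2], [3, 4])


class TestBootstrap:
    def test_identical_replicas_zero_sd(self):
        X = np.tile(np.array([[1.0], [2.0], [3.0], [0.5]]), (1, 20))
        labels = ["non-binder", "non-binder", "binder", "binder"]
        sd = bootstrap_auroc_sd(X, labels, [1, 5, 20], B=100, seed=0)
        assert all(v == 0.0 for v in sd.values())

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 30))
        labels = ["non-binder"] * 4 + ["binder"] * 4
        a = bootstrap_auroc_sd(X, labels, [1, 10, 30], B=200, seed=7)
        b = bootstrap_auroc_sd(X, labels, [1, 10, 30], B=200, seed=7)
        assert a == b

    def test_invalid_n_rejected(self):
        X = np.zeros((4, 10))
        labels = ["non-binder", "non-binder", "binder", "binder"]
        with pytest.raises(AnalysisError):
            bootstrap_auroc_sd(X, labels, [0], B=10, seed=0)
        with pytest.raises(AnalysisError):
            bootstrap_auroc_sd(X, labels, [11], B=10, seed=0)


class TestBindingRecord:
    def test_class_implied_by_ic50_threshold(self):
        assert BindingRecord("PEP", ic50_nm=100.0).binding_class == "binder"
        assert BindingRecord("PEP", ic50_nm=5000.0).binding_class \
            == "non-binder"

    def test_inconsistent_label_and_ic50_rejected(self):
        with pytest.raises(AnalysisError):
            BindingRecord("PEP", label="binder", ic50_nm=5000.0)

    def test_label_without_ic50_kept(self):
        assert BindingRecord("PEP", label="non-binder").binding_class \
            == "non-binder"


class TestReplicaSetIO:
    def test_tidy_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        r = make_replicas(rng.uniform(0.3, 3.0, size=(3, 7, 3)))
        path = tmp_path / "replicas.tsv"
        r.to_tsv(path)
        back = ReplicaSet.from_tsv(path)
        assert back.peptide_id == r.peptide_id
        np.testing.assert_array_equal(back.steps, r.steps)
        np.testing.assert_allclose(back.distances, r.distances, atol=1e-8)

    def test_mismatched_grid_rejected(self):
        with pytest.raises(AnalysisError):
            ReplicaSet("p", "", np.arange(5), np.ones((2, 4, 3)))

    def test_per_replica_scores_step_window(self):
        d = np.zeros((2, 10, 3))
        d[:, 5:, :] = 3.0
        r = make_replicas(d)
        np.testing.assert_allclose(
            per_replica_scores(r, step_window=(5, 9)), 3.0)
        np.testing.assert_allclose(
            per_replica_scores(r, step_window=(0, 4)), 0.0)
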