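import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathpsn.io import PathwayRecord
from pathpsn.preprocess import OmicsMatrix
from pathpsn.psn import (SimilarityNetwork, attach_unknowns, build_psn,
                         filter_networks, pairwise_similarity,
                         score_separability, separability_power,
                         sparsify_psn)

unit_vectors = st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1,
                        max_size=12)


def make_network(weights, n_case, direction="activated"):
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    ids = [f"p{i}" for i in range(n)]
    labels = {p: ("case" if i < n_case else "control")
              for i, p in enumerate(ids)}
    return SimilarityNetwork("toy", ids, w, direction, labels)


def block_network(n_per_class, cohesive, other, inter,
                  cohesive_values=None):
    """Two-class network with constant (or listed) block similarities."""
    n = 2 * n_per_class
    w = np.zeros((n, n))
    it = iter(cohesive_values or [])
    for i in range(n):
        for j in range(i + 1, n):
            if j < n_per_class:
                w[i, j] = next(it) if cohesive_values else cohesive
            elif i >= n_per_class:
                w[i, j] = other
            else:
                w[i, j] = inter
            w[j, i] = w[i, j]
    return make_network(w, n_per_class)


class TestPairwiseSimilarity:
    def test_identical_max_profiles_activated(self):
        assert pairwise_similarity([1, 1, 1], [1, 1, 1], "activated") == 0.5

    def test_identical_max_profiles_inhibited_zero(self):
        assert pairwise_similarity([1, 1, 1], [1, 1, 1], "inhibited") == 0.0

    def test_hand_computed_activated(self):
        # Comp1 = 0.6/1.2 = 0.5; Comp2 = (0.3 + 0.6)/2 = 0.45; Sim = 0.1125
        sim = pairwise_similarity([0.2, 0.4], [0.4, 0.8], "activated")
        assert sim == pytest.approx(0.1125, abs=1e-12)

    def test_hand_computed_inhibited(self):
        # Comp2 flips to 0.55; Sim = 0.5 * 0.55 / 2 = 0.1375
        sim = pairwise_similarity([0.2, 0.4], [0.4, 0.8], "inhibited")
        assert sim == pytest.approx(0.1375, abs=1e-12)

    def test_all_zero_profiles_comp1_is_one(self):
        # 0/0 -> 1 (identical values); activated Comp2 = 0 so Sim = 0,
        # inhibited Comp2 = 1 so Sim = 0.5
        assert pairwise_similarity([0, 0], [0, 0], "activated") == 0.0
        assert pairwise_similarity([0, 0], [0, 0], "inhibited") == 0.5

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(unit_vectors, st.booleans())
    def test_symmetric_and_bounded(self, values, inhibited):
        rng = np.random.default_rng(42)
        a = np.array(values)
        b = rng.permutation(a)
        direction = "inhibited" if inhibited else "activated"
        s_ab = pairwise_similarity(a, b, direction)
        s_ba = pairwise_similarity(b, a, direction)
        assert s_ab == pytest.approx(s_ba, abs=1e-12)
        assert 0.0 <= s_ab <= 0.5 + 1e-12

    def test_self_similarity_is_half_comp2(self):
        v = np.array([0.2, 0.8, 0.5])
        assert pairwise_similarity(v, v, "activated") == pytest.approx(
            v.mean() / 2.0, abs=1e-12)

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            pairwise_similarity([0.5, 1.2], [0.1, 0.2])

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="same molecules"):
            pairwise_similarity([0.5], [0.1, 0.2])


class TestBuildPsn:
    def _matrix_and_pathway(self, n_mol=6, n_pat=7, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"g{i}" for i in range(n_mol)]
        patients = [f"p{j}" for j in range(n_pat)]
        values = pd.DataFrame(rng.random((n_mol, n_pat)), index=ids,
                              columns=patients)
        rec = PathwayRecord("P", "P", "t", frozenset(ids))
        return OmicsMatrix(values), rec, patients

    def test_complete_graph_weight_count(self):
        matrix, rec, patients = self._matrix_and_pathway()
        net = build_psn(matrix, rec, patients, direction="activated")
        n = len(patients)
        iu = np.triu_indices(n, k=1)
        assert net.weights[iu].shape[0] == n * (n - 1) // 2
        assert (net.weights[iu] > 0).all()

    def test_weights_match_bruteforce_double_loop(self):
        matrix, rec, patients = self._matrix_and_pathway(seed=3)
        for direction in ("activated", "inhibited"):
            net = build_psn(matrix, rec, patients, direction=direction)
            for i, pi in enumerate(patients):
                for j, pj in enumerate(patients):
                    if i == j:
                        continue
                    expected = pairwise_similarity(
                        matrix.values[pi], matrix.values[pj], direction)
                    assert net.weights[i, j] == pytest.approx(expected,
                                                              abs=1e-12)

    def test_patient_permutation_invariance(self):
        matrix, rec, patients = self._matrix_and_pathway(seed=5)
        net = build_psn(matrix, rec, patients, direction="activated")
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(patients))
        shuffled = [patients[i] for i in perm]
        net2 = build_psn(matrix, rec, shuffled, direction="activated")
        np.testing.assert_allclose(net2.weights,
                                   net.weights[np.ix_(perm, perm)],
                                   atol=1e-12)

    def test_too_few_members_skipped(self):
        matrix, _, patients = self._matrix_and_pathway()
        rec = PathwayRecord("tiny", "tiny", "t", frozenset(["g0", "nope"]))
        assert build_psn(matrix, rec, patients, direction="activated") is None


class TestSeparabilityPower:
    def test_dominating_class_scores_ten(self):
        net = block_network(15, cohesive=0.9, other=0.1, inter=0.1)
        result = separability_power(net)
        assert result.power == 10
        assert result.cohesive_class == "case"

    def test_all_equal_scores_zero(self):
        net = block_network(10, cohesive=0.5, other=0.5, inter=0.5)
        assert separability_power(net).power == 0
        assert separability_power(net).cohesive_class is None

    def test_spec_multiset_passes_only_level_one(self):
        # 35 x 0.1 and 65 x 0.9 cohesive intra vs everything at 0.1:
        # level-1 low quantile interpolates to 0.62 > 0.1; level 2 hits
        # the 0.1 block and the strict comparison fails
        cohesive = np.array([0.1] * 35 + [0.9] * 65)
        power, detail = score_separability(cohesive, np.full(105, 0.1),
                                           np.full(225, 0.1))
        assert power == 1
        assert detail[0]["cohesive_low"] == pytest.approx(0.62, abs=1e-9)
        assert detail[1]["passed"] is False

    def test_network_level_one_construction(self):
        # same mixture realized on a full network (105 cohesive edges,
        # 37/68 split keeps the 0.35 quantile inside the 0.9 block edge)
        values = [0.1] * 37 + [0.9] * 68
        net = block_network(15, cohesive=None, other=0.1, inter=0.1,
                            cohesive_values=values)
        result = separability_power(net)
        assert result.power == 1
        assert result.cohesive_class == "case"

    def test_monotone_in_cohesive_similarities(self):
        rng = np.random.default_rng(0)
        cohesive = rng.uniform(0.3, 0.7, 105)
        other = rng.uniform(0.05, 0.25, 105)
        inter = rng.uniform(0.05, 0.25, 225)
        p1, _ = score_separability(cohesive, other, inter)
        p2, _ = score_separability(cohesive + 0.2, other, inter)
        assert p2 >= p1

    def test_at_most_one_cohesive_orientation(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = 6
            w = rng.uniform(0, 0.5, (2 * n, 2 * n))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0)
            net = make_network(w, n)
            intra_case = w[:n, :n][np.triu_indices(n, 1)]
            intra_ctrl = w[n:, n:][np.triu_indices(n, 1)]
            inter = w[:n, n:].ravel()
            p_case, _ = score_separability(intra_case, intra_ctrl, inter)
            p_ctrl, _ = score_separability(intra_ctrl, intra_case, inter)
            assert not (p_case >= 1 and p_ctrl >= 1)

    def test_tiny_class_rejected(self):
        net = make_network(np.zeros((3, 3)), 1)
        with pytest.raises(ValueError, match="fewer than 2"):
            separability_power(net)


class TestFilterAndSparsify:
    def test_filter_keeps_power_at_least_one(self):
        nets = [block_network(5, 0.9, 0.1, 0.1),   # power 10
                block_network(5, 0.5, 0.5, 0.5),   # power 0
                block_network(5, 0.3, 0.1, 0.1)]   # power >= 1
        retained = filter_networks(nets)
        assert len(retained) == 2
        reordered = filter_networks(nets[::-1])
        assert {id(n) for n in retained} == {id(n) for n in reordered}

    def test_keep_fraction_one_is_identity(self):
        net = block_network(5, 0.9, 0.1, 0.2)
        out = sparsify_psn(net, keep_fraction=1.0)
        np.testing.assert_allclose(out.weights, net.weights)
        assert out.sparsified

    def test_strongest_neighbor_always_survives(self):
        rng = np.random.default_rng(2)
        w = rng.uniform(0.01, 0.5, (12, 12))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        net = make_network(w, 6)
        out = sparsify_psn(net, keep_fraction=0.1)
        for i in range(12):
            j = int(np.argmax(net.weights[i]))
            assert out.weights[i, j] == net.weights[i, j]

    def test_cohesive_class_keeps_higher_degree(self):
        net = block_network(10, 0.9, 0.05, 0.1)
        out = sparsify_psn(net, keep_fraction=0.2)
        degree = (out.weights > 0).sum(axis=1)
        assert degree[:10].mean() > degree[10:].mean()

    def test_bad_fraction_rejected(self):
        net = block_network(3, 0.9, 0.1, 0.1)
        with pytest.raises(ValueError, match="keep_fraction"):
            sparsify_psn(net, keep_fraction=0.0)


class TestAttachUnknowns:
    def _training_network(self, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"g{i}" for i in range(5)]
        patients = [f"p{j}" for j in range(8)]
        matrix = OmicsMatrix(pd.DataFrame(rng.random((5, 8)), index=ids,
                                          columns=patients))
        rec = PathwayRecord("P", "P", "t", frozenset(ids))
        labels = {p: ("case" if j < 4 else "control")
                  for j, p in enumerate(patients)}
        net = build_psn(matrix, rec, patients, direction="activated",
                        labels=labels)
        return net, matrix

    def test_training_edges_unchanged_and_removal_restores(self):
        net, matrix = self._training_network()
        rng = np.random.default_rng(9)
        unknown = OmicsMatrix(pd.DataFrame(
            rng.random((5, 3)), index=matrix.values.index,
            columns=["u0", "u1", "u2"]))
        extended = attach_unknowns(net, unknown)
        n = net.n_patients
        np.testing.assert_allclose(extended.weights[:n, :n], net.weights,
                                   atol=1e-12)
        assert extended.patient_ids[:n] == net.patient_ids

    def test_duplicate_of_training_patient_copies_edge_profile(self):
        net, matrix = self._training_network()
        clone = OmicsMatrix(matrix.values[["p0"]].rename(
            columns={"p0": "uclone"}))
        extended = attach_unknowns(net, clone)
        n = net.n_patients
        expected = net.weights[0].copy()
        got = extended.weights[n, :n].copy()
        # the clone's edge to p0 itself is a self-comparison, not in expected
        got[0] = expected[0] = 0.0
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_unknown_edges_match_bruteforce(self):
        net, matrix = self._training_network(seed=4)
        rng = np.random.default_rng(10)
        unknown = OmicsMatrix(pd.DataFrame(
            rng.random((5, 2)), index=matrix.values.index,
            columns=["u0", "u1"]))
        extended = attach_unknowns(net, unknown)
        n = net.n_patients
        for u, uid in enumerate(["u0", "u1"]):
            for t, tid in enumerate(net.patient_ids):
                expected = pairwise_similarity(
                    matrix.values[tid], unknown.values[uid], "activated")
                assert extended.weights[n + u, t] == pytest.approx(
                    expected, abs=1e-12)

    def test_sparsified_unknown_keeps_top_edges_only(self):
        net, matrix = self._training_network()
        sparse = sparsify_psn(net, keep_fraction=0.25)
        rng = np.random.default_rng(11)
        unknown = OmicsMatrix(pd.DataFrame(
            rng.random((5, 1)), index=matrix.values.index, columns=["u0"]))
        extended = attach_unknowns(sparse, unknown, keep_fraction=0.25)
        n = net.n_patients
        kept = (extended.weights[n, :n] > 0).sum()
        assert kept == int(np.ceil(0.25 * n))

    def test_overlapping_ids_rejected(self):
        net, matrix = self._training_network()
        with pytest.raises(ValueError, match="already in network"):
            attach_unknowns(net, matrix)
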