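"""Order parameter, tilt statistics and aggregate clustering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluorofilm import (GeneratorSpec, MonolayerFrame, average_op,
                        classify_upright, cluster_molecules, compute_op,
                        extract_chain_vectors, tilt_angles)
from fluorofilm.orderfield import compute_op_double_sum

from conftest import minimal_chain_frame


def random_unit_vectors(n, seed):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class TestComputeOP:
    def test_parallel_vectors_give_one(self):
        v = np.tile([0.2, 0.1, 0.9], (25, 1))
        assert compute_op(v) == pytest.approx(1.0, abs=1e-12)

    def test_antiparallel_pair_gives_minus_one(self):
        v = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])
        assert compute_op(v) == pytest.approx(-1.0, abs=1e-12)

    def test_identity_equals_literal_double_sum(self):
        for seed in range(5):
            v = random_unit_vectors(40, seed)
            fast = compute_op(v)
            slow = compute_op_double_sum(v)
            assert fast == pytest.approx(slow, rel=1e-12, abs=1e-13)

    def test_isotropic_upper_hemisphere_limit(self):
        # E[u] = (0, 0, 1/2) for uniform upper hemisphere, so OP -> 1/4
        rng = np.random.default_rng(42)
        n = 10_000
        uz = rng.uniform(0.0, 1.0, n)
        phi = rng.uniform(0.0, 2 * math.pi, n)
        s = np.sqrt(1.0 - uz**2)
        u = np.column_stack([s * np.cos(phi), s * np.sin(phi), uz])
        assert compute_op(u) == pytest.approx(0.25, abs=0.01)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            compute_op(np.array([[0.0, 0.0, 1.0]]))
        with pytest.raises(ValueError):
            compute_op(np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 0.0]]))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(n=st.integers(2, 30), seed=st.integers(0, 10_000))
    def test_bounds_and_symmetries(self, n, seed):
        """-1/(N-1) <= OP <= 1; invariant under global rotation and
        molecule re-ordering."""
        v = random_unit_vectors(n, seed)
        op = compute_op(v)
        assert -1.0 / (n - 1) - 1e-10 <= op <= 1.0 + 1e-10
        rng = np.random.default_rng(seed + 1)
        # random rotation via QR of a Gaussian matrix
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        assert compute_op(v @ q.T) == pytest.approx(op, abs=1e-10)
        perm = rng.permutation(n)
        assert compute_op(v[perm]) == pytest.approx(op, abs=1e-12)


class TestAverageOP:
    def _frames_with_ops(self, op_values, times):
        frames = []
        for opv, t in zip(op_values, times):
            # two-molecule frame whose pair cosine equals opv
            angle = math.acos(opv)
            f = minimal_chain_frame([[0.0, 0.0, 1.0],
                                     [math.sin(angle), 0.0, math.cos(angle)]])
            f.time_label = t
            frames.append(f)
        return frames

    def test_constant_series_has_zero_std(self):
        frames = self._frames_with_ops([0.9] * 4, [0.0, 1.0, 2.0, 3.0])
        res = average_op(frames, block_duration=2.0)
        assert res.op_mean == pytest.approx(0.9, abs=1e-12)
        assert res.op_std == 0.0

    def test_two_block_arithmetic_by_hand(self):
        # blocks [0,2) and [2,4): means 0.9 each -> std 0, mean 0.9
        frames = self._frames_with_ops([0.8, 1.0, 0.8, 1.0],
                                       [0.0, 1.0, 2.0, 3.0])
        res = average_op(frames, block_duration=2.0)
        assert res.op_mean == pytest.approx(0.9, abs=1e-9)
        assert res.op_std == pytest.approx(0.0, abs=1e-9)
        # blocks with different means: 0.8 and 1.0 -> sample std 0.1414
        frames = self._frames_with_ops([0.8, 0.8, 1.0, 1.0],
                                       [0.0, 1.0, 2.0, 3.0])
        res = average_op(frames, block_duration=2.0)
        assert res.op_mean == pytest.approx(0.9, abs=1e-9)
        assert res.op_std == pytest.approx(np.std([0.8, 1.0], ddof=1), abs=1e-9)

    def test_short_span_single_block(self):
        frames = self._frames_with_ops([0.8, 1.0], [0.0, 0.1])
        res = average_op(frames, block_duration=2.0)
        assert res.op_mean == pytest.approx(0.9, abs=1e-9)
        assert res.op_std == 0.0

    def test_ordered_film_with_small_tilt_disorder(self, f14):
        from fluorofilm import generate_hex_domain
        frames = []
        for seed in range(3):
            spec = GeneratorSpec(template=f14, n_molecules=200,
                                 tilt_sigma=5.0, seed=seed)
            f = generate_hex_domain(spec)
            f.time_label = float(seed)
            frames.append(f)
        res = average_op(frames, block_duration=2.0)
        assert res.op_mean >= 0.9
        assert res.n_molecules == 200

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            average_op([])


class TestTiltAndClassification:
    def test_reference_angles(self):
        assert tilt_angles(np.array([[0.0, 0.0, 1.0]]))[0] == pytest.approx(0.0)
        assert tilt_angles(np.array([[1.0, 0.0, 0.0]]))[0] == pytest.approx(90.0)
        assert tilt_angles(np.array([[0.0, 0.0, -2.0]]))[0] == pytest.approx(180.0)

    def test_half_normal_median_of_generated_tilt(self, f14):
        from fluorofilm import generate_hex_domain
        spec = GeneratorSpec(template=f14, n_molecules=400, tilt_sigma=10.0,
                             seed=13)
        frame = generate_hex_domain(spec)
        angles = tilt_angles(extract_chain_vectors(frame))
        # half-normal median = sigma * Phi^-1(3/4) = 0.6745 sigma
        assert np.median(angles) == pytest.approx(6.745, abs=3.0)

    def test_upright_classification(self):
        v = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [1.0, 0.0, 1.0]])
        out = classify_upright(v, 45.0)
        assert list(out) == [True, False, False]  # 45 deg is not upright

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            classify_upright(np.array([[0.0, 0.0, 1.0]]), 95.0)

    def test_counts_match_generator_ground_truth(self, gas_48_16):
        vec = extract_chain_vectors(gas_48_16)
        predicted = classify_upright(vec, 45.0)
        truth = gas_48_16.meta["true_tilt_deg"] < 45.0
        assert np.array_equal(predicted, truth)


class TestClustering:
    def test_two_molecules_within_cutoff(self):
        frame = minimal_chain_frame([[0, 0, 1], [0, 0, 1]])
        # move second molecule to 0.5 nm from the first, in-plane
        frame.positions[3:, 0] = frame.positions[:3, 0] + 0.5
        labels = cluster_molecules(frame, cutoff=0.7).labels
        assert list(labels) == [0, 0]

    def test_gas_fixture_partition(self, gas_48_16):
        cl = cluster_molecules(gas_48_16)
        assert cl.n_clusters == 1
        assert cl.sizes()[0] == 48
        assert int((cl.labels == -1).sum()) == 16

    def test_matches_brute_force_union_find(self):
        rng = np.random.default_rng(7)
        n = 100
        box = np.array([12.0, 12.0, 5.0])
        pos = rng.uniform(0, 1, (n, 3)) * box
        frame = MonolayerFrame(pos, np.array(["C"] * n, dtype=object),
                               np.arange(n), box)
        cutoff = 0.9
        labels = cluster_molecules(frame, cutoff).labels

        # oracle: O(N^2) union-find with periodic x,y distances
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                d = pos[i, :2] - pos[j, :2]
                d -= box[:2] * np.round(d / box[:2])
                if np.hypot(d[0], d[1]) < cutoff:
                    parent[find(i)] = find(j)
        roots = [find(i) for i in range(n)]
        # compare as partitions (cluster membership sets, singletons = -1)
        from collections import defaultdict
        oracle_groups = defaultdict(list)
        for i, r in enumerate(roots):
            oracle_groups[r].append(i)
        oracle_sets = {frozenset(g) for g in oracle_groups.values()
                       if len(g) > 1}
        ours = defaultdict(list)
        for i, lab in enumerate(labels):
            if lab >= 0:
                ours[lab].append(i)
        our_sets = {frozenset(g) for g in ours.values()}
        assert our_sets == oracle_sets
        oracle_singletons = {i for r, g in oracle_groups.items()
                             for i in g if len(g) == 1}
        assert set(np.nonzero(labels == -1)[0]) == oracle_singletons

    def test_labels_ordered_by_smallest_member(self, gas_48_16):
        labels = cluster_molecules(gas_48_16).labels
        firsts = [np.nonzero(labels == lab)[0][0]
                  for lab in range(labels.max() + 1)]
        assert firsts == sorted(firsts)

    def test_bad_cutoff(self, gas_48_16):
        with pytest.raises(ValueError):
            cluster_molecules(gas_48_16, cutoff=0.0)
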