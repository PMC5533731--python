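import numpy as np
import pytest

import mlclust as m
from mlclust.multilayer_clustering import Partition
from oracles import crv_instance_brute, diff_merge_brute


def random_est(rng, n):
    x = rng.random((n, n))
    x = (x + x.T) / 2.0
    np.fill_diagonal(x, 1.0)
    return x


def random_partition(rng, n):
    k = int(rng.integers(2, n + 1))
    labels = rng.integers(0, k, n)
    labels[rng.integers(0, n)] = 0  # ensure cluster 0 non-empty
    clusters = [set(np.where(labels == c)[0]) for c in range(k)
                if (labels == c).any()]
    return clusters


class TestCrvWorkedFixture:
    """Hand arithmetic on the 4x4 two-block table."""

    def test_singleton_instance(self, two_block_est):
        p = Partition.singletons(4)
        wc, oc = m.crv_instance(two_block_est, p, 0)
        assert wc == 0.0
        assert oc == pytest.approx(2.0 / 3.0)

    def test_pair_cluster_instance(self, two_block_est):
        p = Partition([{0, 1}, {2}, {3}])
        wc, oc = m.crv_instance(two_block_est, p, 0)
        assert wc == 0.0  # single within value equals its own mean
        assert oc == 0.0  # outside values {0, 0}

    def test_constant_est_has_zero_crv(self):
        x = np.full((5, 5), 0.4)
        np.fill_diagonal(x, 1.0)
        for p in (Partition.singletons(5), Partition([{0, 1, 2}, {3, 4}])):
            for i in range(5):
                wc, oc = m.crv_instance(x, p, i)
                assert wc == pytest.approx(0.0, abs=1e-12)
                assert oc == pytest.approx(0.0, abs=1e-12)

    def test_cluster_sums(self, two_block_est):
        singles = Partition.singletons(4)
        assert m.crv_cluster(two_block_est, singles, 0) == pytest.approx(2 / 3)
        pair = Partition([{0, 1}, {2}, {3}])
        assert m.crv_cluster(two_block_est, pair, 0) == pytest.approx(0.0)
        merged = Partition([{0, 1, 2, 3}])
        assert m.crv_cluster(two_block_est, merged, 0) == pytest.approx(8 / 3)

    def test_diff_values(self, two_block_est):
        singles = Partition.singletons(4)
        assert m.diff_merge(two_block_est, singles, 0, 1) == pytest.approx(4 / 3)
        blocks = Partition([{0, 1}, {2, 3}])
        ids = list(blocks.clusters)
        assert m.diff_merge(two_block_est, blocks, ids[0], ids[1]) == pytest.approx(-8 / 3)

    def test_constant_est_diff_zero(self):
        x = np.full((4, 4), 0.2)
        np.fill_diagonal(x, 1.0)
        p = Partition.singletons(4)
        for a in range(4):
            for b in range(a + 1, 4):
                assert m.diff_merge(x, p, a, b) == pytest.approx(0.0)

    def test_index_out_of_range(self, two_block_est):
        with pytest.raises(m.ConfigurationError):
            m.crv_instance(two_block_est, Partition.singletons(4), 7)
        with pytest.raises(m.ConfigurationError):
            m.diff_merge(two_block_est, Partition.singletons(4), 1, 1)


class TestOracleEquivalence:
    def test_crv_and_diff_match_brute_force(self):
        """>=100 random (EST, partition) pairs at N <= 12, tolerance 1e-9."""
        rng = np.random.default_rng(7)
        for _ in range(120):
            n = int(rng.integers(4, 13))
            x = random_est(rng, n)
            clusters = random_partition(rng, n)
            p = Partition([frozenset(c) for c in clusters])
            ids = list(p.clusters)
            i = int(rng.integers(0, n))
            assert m.crv_instance(x, p, i) == pytest.approx(
                crv_instance_brute(x, clusters, i), abs=1e-9)
            if len(clusters) >= 2:
                a, b = rng.choice(len(clusters), 2, replace=False)
                assert m.diff_merge(x, p, ids[a], ids[b]) == pytest.approx(
                    diff_merge_brute(x, clusters, a, b), abs=1e-9)


class TestJointDiff:
    def test_min_rule(self, two_block_est):
        contradict = m.generate_two_block_est(2, 2, 1.0, 0.0)
        # second layer groups {0,2} vs {1,3}: permute the first fixture
        perm = [0, 2, 1, 3]
        other = contradict.x[np.ix_(perm, perm)]
        p = Partition.singletons(4)
        d1 = m.diff_merge(two_block_est, p, 0, 1)
        d2 = m.diff_merge(other, p, 0, 1)
        assert m.joint_diff([two_block_est.x, other], p, 0, 1) == min(d1, d2)

    def test_single_layer_is_identity(self, two_block_est):
        p = Partition.singletons(4)
        assert m.joint_diff([two_block_est], p, 0, 1) == \
            m.diff_merge(two_block_est, p, 0, 1)

    def test_mismatched_sizes_rejected(self, two_block_est):
        small = m.generate_two_block_est(1, 2, 1.0, 0.0)
        with pytest.raises(m.ConfigurationError):
            m.joint_diff([two_block_est, small], Partition.singletons(4), 0, 1)


class TestCluster:
    def test_worked_fixture_full_run(self, two_block_est):
        trace = m.cluster(two_block_est)
        assert [s.joint for s in trace.steps] == pytest.approx([4 / 3, 4 / 3])
        assert trace.best_remaining_joint == pytest.approx(-8 / 3)
        assert sorted(trace.final) == [(0, 1), (2, 3)]

    def test_agreeing_layers_recover_blocks(self):
        a = m.generate_two_block_est(3, 3, 0.9, 0.1)
        b = m.generate_two_block_est(3, 3, 0.7, 0.2)
        trace = m.cluster([a, b])
        assert sorted(trace.final) == [(0, 1, 2), (3, 4, 5)]

    def test_contradictory_layers_first_step_diffs(self):
        """With fully contradictory block structures ({0,1}|{2,3} versus
        {0,2}|{1,3}) every pair crosses a block in at least one layer, so
        by direct evaluation all six first-step joint DIFFs equal the
        cross-block value 1/3: no pair is preferred, and the tie-break
        drives a deterministic (if arbitrary) agglomeration."""
        a = m.generate_two_block_est(2, 2, 1.0, 0.0)
        perm = [0, 2, 1, 3]
        b = a.x[np.ix_(perm, perm)]  # blocks {0,2} vs {1,3}
        p = Partition.singletons(4)
        joints = [m.joint_diff([a.x, b], p, i, j)
                  for i in range(4) for j in range(i + 1, 4)]
        assert joints == pytest.approx([1 / 3] * 6)
        trace = m.cluster([a.x, b])
        assert trace.steps[0].joint == pytest.approx(1 / 3)

    def test_every_merge_reduces_the_binding_layer(self):
        """Along the trace, the layer achieving the min strictly drops
        its total CRV at every executed step (DIFF > 0)."""
        rng = np.random.default_rng(3)
        x1 = random_est(rng, 30)
        x2 = random_est(rng, 30)
        # add block structure so merges happen
        x1[:15, :15] += 0.3
        x1[15:, 15:] += 0.3
        x2[:15, :15] += 0.3
        x2[15:, 15:] += 0.3
        x1 = np.clip((x1 + x1.T) / 2, 0, 1)
        x2 = np.clip((x2 + x2.T) / 2, 0, 1)
        np.fill_diagonal(x1, 1.0)
        np.fill_diagonal(x2, 1.0)
        trace = m.cluster([x1, x2])
        assert len(trace.steps) >= 1
        for step in trace.steps:
            assert step.joint > 0.0
            assert min(step.per_layer_diff) == pytest.approx(step.joint)

    def test_terminates_within_n_minus_one_merges(self):
        rng = np.random.default_rng(5)
        for n in (2, 5, 17):
            x = random_est(rng, n)
            trace = m.cluster(x)
            assert len(trace.steps) <= n - 1

    def test_final_state_has_no_positive_pair(self):
        rng = np.random.default_rng(11)
        x = random_est(rng, 20)
        x[:10, :10] += 0.2
        x[10:, 10:] += 0.2
        x = np.clip((x + x.T) / 2, 0, 1)
        np.fill_diagonal(x, 1.0)
        trace = m.cluster(x)
        part = trace.final_partition()
        ids = list(part.clusters)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                assert m.diff_merge(x, part, a, b) <= 1e-9

    def test_subject_permutation_gives_same_partition_up_to_relabeling(self):
        rng = np.random.default_rng(13)
        x = random_est(rng, 16)
        x[:8, :8] += 0.25
        x[8:, 8:] += 0.25
        x = np.clip((x + x.T) / 2, 0, 1)
        np.fill_diagonal(x, 1.0)
        base = {frozenset(c) for c in m.cluster(x).final}
        perm = rng.permutation(16)
        xp = x[np.ix_(perm, perm)]
        permuted = {frozenset(int(perm[i]) for i in c)
                    for c in m.cluster(xp).final}
        assert permuted == base

    def test_trace_json_round_trip(self, two_block_est, tmp_path):
        trace = m.cluster(two_block_est)
        path = tmp_path / "trace.json"
        trace.to_json(path)
        import json
        doc = json.loads(path.read_text())
        assert doc["n"] == 4
        assert len(doc["steps"]) == 2


class TestLabelUnclustered:
    def test_small_clusters_flagged(self):
        trace = m.MergeTrace(n=10, n_layers=1, steps=[],
                             final=[(0, 1, 2, 3), (4, 5, 6), (7,), (8, 9)],
                             best_remaining_joint=0.0)
        clustering = m.label_unclustered(trace, min_size=3)
        assert clustering.labels[0] == "C1"
        assert clustering.labels[4] == "C2"
        assert clustering.labels[7] == "unclustered"
        assert clustering.labels[8] == "unclustered"

    def test_min_size_one_keeps_everything(self):
        trace = m.MergeTrace(n=3, n_layers=1, steps=[],
                             final=[(0,), (1,), (2,)], best_remaining_joint=0.0)
        clustering = m.label_unclustered(trace, min_size=1)
        assert "unclustered" not in clustering.labels

    def test_all_singletons_min_two_all_unclustered(self):
        trace = m.MergeTrace(n=4, n_layers=1, steps=[],
                             final=[(0,), (1,), (2,), (3,)],
                             best_remaining_joint=-1.0)
        clustering = m.label_unclustered(trace, min_size=2)
        assert set(clustering.labels) == {"unclustered"}

    def test_ranking_by_size(self):
        trace = m.MergeTrace(n=9, n_layers=1, steps=[],
                             final=[(0, 1), (2, 3, 4, 5), (6, 7, 8)],
                             best_remaining_joint=0.0)
        clustering = m.label_unclustered(trace, min_size=2)
        assert clustering.labels[2] == "C1"   # size 4
        assert clustering.labels[6] == "C2"   # size 3
        assert clustering.labels[0] == "C3"   # size 2
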