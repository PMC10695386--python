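"""Chunking, cluster assignment, overfit handling, and the iterative driver."""

import numpy as np
import pytest

from promarch import (
    Cluster,
    Lineage,
    MutationModel,
    RunConfig,
    SequenceSet,
    adjusted_rand_index,
    assign_to_clusters,
    detect_overfit,
    encode,
    make_chunks,
    remerge_overfit,
    run_clustering,
)


class TestMakeChunks:
    def test_even_split(self):
        chunks = make_chunks(list(range(1000)), 500)
        assert [len(c) for c in chunks] == [500, 500]

    def test_single_chunk(self):
        assert len(make_chunks(list(range(1000)), 1000)) == 1

    def test_small_remainder_merged(self):
        chunks = make_chunks(list(range(1010)), 500)
        assert [len(c) for c in chunks] == [500, 510]

    def test_large_remainder_kept(self):
        chunks = make_chunks(list(range(1100)), 500)
        assert [len(c) for c in chunks] == [500, 500, 100]

    def test_chunks_preserve_order_and_partition(self):
        chunks = make_chunks(list(range(777)), 250)
        flat = [i for c in chunks for i in c]
        assert flat == list(range(777))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            make_chunks([], 10)


class TestAssign:
    def test_argmax_assignment(self):
        H = np.array([[0.1], [0.7], [0.2]])
        assert assign_to_clusters(H)[0] == 1

    def test_tie_breaks_low_index(self):
        H = np.array([[0.5], [0.5]])
        assert assign_to_clusters(H)[0] == 0

    def test_matches_brute_force_scan(self, rng):
        H = rng.uniform(0, 1, (4, 20))
        labels = assign_to_clusters(H)
        for j in range(20):
            assert H[labels[j], j] == H[:, j].max()

    def test_negative_coefficients_rejected(self):
        with pytest.raises(ValueError):
            assign_to_clusters(np.array([[-0.1, 0.2]]))


class TestOverfitDetection:
    def test_uniform_coefficients_not_overfit(self):
        assert detect_overfit(np.ones(5)) is False

    def test_dominated_distribution_is_overfit(self):
        coeffs = np.array([10.0, 0.01, 0.01, 0.01, 0.01])
        # CV computed by hand: mean 2.008, population std 3.996 -> CV ~ 1.99
        assert coeffs.std() / coeffs.mean() > 1.0
        assert detect_overfit(coeffs) is True

    def test_tiny_cluster_is_overfit(self):
        assert detect_overfit(np.ones(3), min_cluster_size=5) is True


def _cluster(members, basis_val, local):
    basis = np.full(8, 0.1)
    basis[local] = basis_val
    return Cluster(members=members, basis=basis, lineage=Lineage(0, 0, 0, local))


class TestRemerge:
    def test_flagged_merged_into_first_unflagged(self):
        c1, c2, c3 = (
            _cluster([0, 1], 1.0, 0),
            _cluster([2, 3], 1.0, 1),
            _cluster([4, 5], 1.0, 2),
        )
        out = remerge_overfit([c1, c2, c3], [False, True, False])
        assert sorted(out[0].members) == [0, 1, 2, 3]
        assert out[1].members == [4, 5]

    def test_no_flags_identity(self):
        cs = [_cluster([0], 1.0, 0), _cluster([1], 1.0, 1)]
        assert remerge_overfit(cs, [False, False]) == cs

    def test_first_flagged_merges_into_later_parent(self):
        c1, c2 = _cluster([0, 1], 1.0, 0), _cluster([2, 3], 1.0, 1)
        out = remerge_overfit([c1, c2], [True, False])
        assert len(out) == 1
        assert sorted(out[0].members) == [0, 1, 2, 3]
        assert np.array_equal(out[0].basis, c2.basis)  # parent is the unflagged one

    def test_all_flagged_collapses_with_warning(self, caplog):
        c1, c2 = _cluster([0], 1.0, 0), _cluster([1], 1.0, 1)
        out = remerge_overfit([c1, c2], [True, True])
        assert len(out) == 1 and sorted(out[0].members) == [0, 1]


class TestRunConfig:
    def test_collation_flags_must_match_iterations(self):
        with pytest.raises(ValueError, match="set_ocollation"):
            RunConfig(total_itr=2, set_ocollation=[True])

    def test_chunk_size_must_cover_k_max(self):
        with pytest.raises(ValueError):
            RunConfig(chunk_size=4, k_max=8)


@pytest.fixture(scope="module")
def small_config():
    return RunConfig(
        chunk_size=120, k_min=2, k_max=5, n_runs=6, total_itr=1,
        set_ocollation=[True], seed=9,
    )


class TestDriver:
    def test_partition_invariant_every_iteration(self, disjoint_encoded, small_config):
        V, _ = disjoint_encoded
        result = run_clustering(V, small_config)
        for sol in result.iterations + [result.final]:
            assert sol.member_set() == set(range(V.n))

    def test_exact_recovery_on_disjoint_data(self, disjoint_encoded, small_config):
        V, truth = disjoint_encoded
        result = run_clustering(V, small_config)
        ari = adjusted_rand_index(truth, result.final.labels(V.n))
        assert ari == pytest.approx(1.0)

    def test_reproducible_given_seed(self, disjoint_encoded, small_config):
        V, _ = disjoint_encoded
        a = run_clustering(V, small_config).final.labels(V.n)
        b = run_clustering(V, small_config).final.labels(V.n)
        assert np.array_equal(a, b)

    def test_single_chunk_equivalence(self, disjoint_encoded):
        """With chunk_size >= n the driver degenerates to one model-selection
        + assignment pass; doubling chunk_size beyond n changes nothing."""
        V, _ = disjoint_encoded
        cfgs = [
            RunConfig(chunk_size=s, k_max=5, n_runs=6, total_itr=1,
                      set_ocollation=[True], seed=9)
            for s in (V.n, 2 * V.n)
        ]
        labs = [run_clustering(V, c).final.labels(V.n) for c in cfgs]
        assert np.array_equal(labs[0], labs[1])

    def test_homogeneous_input_yields_single_cluster(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(150)]
        ss = SequenceSet(ids=[f"s{i}" for i in range(150)], seqs=seqs)
        V = encode(ss, "di")
        cfg = RunConfig(chunk_size=150, k_max=4, n_runs=6, total_itr=1,
                        set_ocollation=[True], seed=3)
        result = run_clustering(V, cfg)
        assert result.final.n_clusters == 1

    def test_report_bookkeeping(self, disjoint_encoded, small_config):
        V, _ = disjoint_encoded
        rep = run_clustering(V, small_config).report
        assert rep["n_sequences"] == V.n
        assert len(rep["iterations"]) == 1
        assert all(rec["selected_k"] >= 1 for rec in rep["chunks"])
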