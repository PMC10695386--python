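"""The simulated four-architecture benchmark generator and ARI evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from promarch import (
    MutationModel,
    adjusted_rand_index,
    enumerate_grid,
    four_cluster_spec,
    generate_dataset,
    plant_motif,
)
from promarch.synthetic import write_fasta


class TestSpec:
    def test_four_clusters_with_stated_counts(self):
        spec = four_cluster_spec()
        assert [c.count for c in spec.clusters] == [200, 350, 150, 300]
        assert spec.total == 1000
        assert spec.L == 100

    def test_repeat_cluster_is_immutable(self):
        spec = four_cluster_spec()
        a = spec.clusters[0]
        assert a.mutable is False
        assert [m.start for m in a.motifs] == list(range(10, 91, 10))
        assert all(m.pattern == "AT" for m in a.motifs)

    def test_all_motifs_fit(self):
        spec = four_cluster_spec()
        for c in spec.clusters:
            for m in c.motifs:
                assert m.start - 1 + len(m.pattern) <= spec.L

    def test_invalid_placement_rejected(self):
        from promarch.synthetic import ClusterSpec, MotifPlacement, SyntheticSpec

        with pytest.raises(ValueError):
            SyntheticSpec(
                clusters=(
                    ClusterSpec("x", (MotifPlacement("ACGT", 99),), 10),
                ),
                L=100,
            )


class TestMutationModel:
    def test_rate_bounds(self):
        with pytest.raises(ValueError):
            MutationModel(rate=1.5)

    def test_zero_rate_plants_verbatim(self, rng):
        seq = list("A" * 20)
        plant_motif(seq, "GATTACA", 5, MutationModel(0.0), rng)
        assert "".join(seq[4:11]) == "GATTACA"

    def test_out_of_range_placement(self, rng):
        with pytest.raises(ValueError):
            plant_motif(list("ACGT"), "GATTACA", 2, MutationModel(0.0), rng)

    def test_certain_mutation_changes_every_position(self, rng):
        pattern = "GAGAG"
        for _ in range(20):
            seq = list("T" * 10)
            plant_motif(seq, pattern, 1, MutationModel(1.0, positions=5), rng)
            planted = "".join(seq[:5])
            assert all(a != b for a, b in zip(planted, pattern))

    def test_empirical_mutation_rate(self):
        """Over many plantings at rate 0.3 with one mutable position, the
        fraction of motif instances that differ from the pattern is 0.3."""
        rng = np.random.default_rng(123)
        model = MutationModel(rate=0.3, positions=1)
        mutated = 0
        n = 10_000
        for _ in range(n):
            seq = list("C" * 10)
            plant_motif(seq, "GAGAG", 3, model, rng)
            mutated += "".join(seq[2:7]) != "GAGAG"
        assert mutated / n == pytest.approx(0.3, abs=0.02)


class TestGenerate:
    def test_dataset_size_and_labels(self):
        seqs, labels = generate_dataset(four_cluster_spec(), MutationModel(0.1), 0)
        assert len(seqs) == 1000 and seqs.L == 100
        counts = {lab: labels.count(lab) for lab in "ABCD"}
        assert counts == {"A": 200, "B": 350, "C": 150, "D": 300}

    def test_unmutated_cluster_c_has_exact_motif(self):
        seqs, labels = generate_dataset(four_cluster_spec(), MutationModel(0.0), 1)
        for s, lab in zip(seqs.seqs, labels):
            if lab == "C":
                assert s[59:64] == "GAGAG"

    def test_same_seed_byte_identical(self, tmp_path):
        model = MutationModel(0.2, 2)
        out = []
        for run in range(2):
            seqs, _ = generate_dataset(four_cluster_spec(), model, seed=42)
            path = tmp_path / f"run{run}.fa"
            write_fasta(seqs, path)
            out.append(path.read_bytes())
        assert out[0] == out[1]

    def test_output_order_is_shuffled(self):
        seqs, labels = generate_dataset(four_cluster_spec(), MutationModel(0.0), 3)
        # members of each cluster should be spread out, not contiguous
        first_200 = set(labels[:200])
        assert len(first_200) == 4


class TestARI:
    def test_identical_partitions(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0

    def test_relabel_invariance(self):
        assert adjusted_rand_index(list("AABB"), [5, 5, 0, 0]) == 1.0

    def test_random_permutation_near_zero(self):
        rng = np.random.default_rng(7)
        labels = [i % 4 for i in range(200)]
        scores = []
        for _ in range(100):
            shuffled = list(rng.permutation(labels))
            scores.append(adjusted_rand_index(labels, shuffled))
        assert abs(np.mean(scores)) < 0.02

    def test_bounded(self, rng):
        for _ in range(20):
            a = rng.integers(0, 3, 30)
            b = rng.integers(0, 3, 30)
            assert -1.0 <= adjusted_rand_index(a, b) <= 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([1, 2], [1, 2, 3])


class TestGrid:
    def test_default_grid_counts(self):
        grid = enumerate_grid()
        configs = grid[["rate", "positions", "chunk_size"]].drop_duplicates()
        assert len(configs) == 45
        variations = grid[["rate", "positions"]].drop_duplicates()
        assert len(variations) == 15
        assert len(grid) == 450  # 10 repeats per configuration

    def test_repeats_per_cell(self):
        grid = enumerate_grid(repeats=10)
        per_cell = grid.groupby(["rate", "positions", "chunk_size"]).size()
        assert (per_cell == 10).all()


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.lists(st.integers(0, 3), min_size=2, max_size=12))
def test_ari_self_agreement_property(labels):
    assert adjusted_rand_index(labels, labels) == pytest.approx(1.0)
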