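"""RPKM, mappability, k-mer curves, z-scaling and clustering."""

import numpy as np
import pytest

from conftest import kmer_curve_oracle, revcomp
from xerotome.expression import (
    choose_k,
    cluster_recovery,
    composite_expression,
    compute_rpkm,
    kmeans_cluster,
    kmer_discovery_curve,
    sample_correlation,
    unique_mappable_length,
    zscale_rows,
)
from xerotome.formats_io import ExpressionMatrix


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestUniqueMappableLength:
    def test_single_contig_all_windows_unique(self):
        rng = np.random.default_rng(0)
        seq = _random_seq(rng, 300)
        assert unique_mappable_length({"c": seq}, 36) == {"c": 300 - 36 + 1}

    def test_identical_contigs_have_zero(self):
        rng = np.random.default_rng(1)
        seq = _random_seq(rng, 200)
        assert unique_mappable_length({"a": seq, "b": seq}, 36) == {"a": 0,
                                                                    "b": 0}

    def test_short_contig_gets_zero(self):
        assert unique_mappable_length({"c": "ACGT"}, 36) == {"c": 0}

    def test_reverse_complement_copy_is_not_unique(self):
        rng = np.random.default_rng(2)
        seq = _random_seq(rng, 150)
        result = unique_mappable_length({"a": seq, "b": revcomp(seq)}, 36)
        assert result == {"a": 0, "b": 0}

    def test_matches_bruteforce_hash_count(self):
        rng = np.random.default_rng(3)
        contigs = {f"c{i}": _random_seq(rng, int(rng.integers(50, 200)))
                   for i in range(8)}
        contigs["dup"] = contigs["c0"][:100]  # plant shared windows
        k = 20
        # oracle: count every canonical window occurrence, then re-scan
        from collections import Counter
        counts = Counter()
        for seq in contigs.values():
            for i in range(len(seq) - k + 1):
                w = seq[i:i + k]
                counts[min(w, revcomp(w))] += 1
        expected = {
            cid: sum(1 for i in range(len(seq) - k + 1)
                     if counts[min(seq[i:i + k],
                                   revcomp(seq[i:i + k]))] == 1)
            for cid, seq in contigs.items()
        }
        assert unique_mappable_length(contigs, k) == expected

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            unique_mappable_length({}, 36)


class TestRpkm:
    def test_basic_arithmetic(self):
        assert compute_rpkm(10, 1000, 10**6) == pytest.approx(10.0)
        assert compute_rpkm(0, 1000, 10**6) == 0.0

    def test_scale_invariance(self):
        assert compute_rpkm(30, 500, 3 * 10**6) == pytest.approx(
            compute_rpkm(10, 500, 10**6))

    def test_zero_mappable_length_is_nan_not_zero(self):
        assert np.isnan(compute_rpkm(5, 0, 10**6))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            compute_rpkm(5, 100, 0)


class TestKmerCurve:
    def test_repeated_read_saturates_immediately(self):
        read = "ACGTACGGTACGGATCCGATGCATGCATGCAT"  # 32 nt, k=25 -> 8 kmers
        reads = [(f"r{i}", read) for i in range(30)]
        curve = kmer_discovery_curve(reads, k=25, batch_size=10)
        # first batch: 8 distinct of 80 scanned; later batches: nothing new
        assert curve[0].discovery_fraction == pytest.approx(8 / 80)
        assert all(p.discovery_fraction == 0.0 for p in curve[1:])

    def test_all_novel_reads_give_fraction_one(self):
        rng = np.random.default_rng(4)
        reads = [(f"r{i}", _random_seq(rng, 40)) for i in range(50)]
        curve = kmer_discovery_curve(reads, k=25, batch_size=10)
        assert all(p.discovery_fraction == 1.0 for p in curve)

    def test_n_containing_kmers_skipped(self):
        curve = kmer_discovery_curve([("r1", "N" * 40)], k=25, batch_size=5)
        assert curve == []

    def test_matches_set_based_oracle(self):
        from xerotome.synthetic import SimulationConfig, simulate_reads
        from xerotome.synthetic import simulate_transcriptome

        contigs, _ = simulate_transcriptome(SimulationConfig(seed=9, n_loci=10))
        reads, _ = simulate_reads(contigs, 2.0, 36, seed=9)
        ours = kmer_discovery_curve(reads, k=25, batch_size=100)
        oracle = kmer_curve_oracle(reads, k=25, batch_size=100)
        assert [(p.reads_sampled, p.discovery_fraction) for p in ours] == \
            pytest.approx(oracle)


class TestZscale:
    def test_hand_computed_row(self):
        z = zscale_rows(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(z, [[-1.2247448, 0.0, 1.2247448]],
                                   atol=1e-6)

    def test_constant_row_becomes_zero(self):
        z = zscale_rows(np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(z[0], 0.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        rows = rng.lognormal(1, 0.5, size=(10, 6))
        np.testing.assert_allclose(zscale_rows(rows),
                                   zscale_rows(3.0 * rows + 0.0), atol=1e-9)


class TestSampleCorrelation:
    def _matrix(self):
        rng = np.random.default_rng(6)
        vals = rng.lognormal(1, 1, size=(100, 3))
        return ExpressionMatrix([f"g{i}" for i in range(100)],
                                ["s1", "s2", "s3"], vals)

    def test_self_correlation_is_one(self):
        m = self._matrix()
        assert sample_correlation(m, 0, 0) == pytest.approx(1.0)

    def test_sample_ids_accepted(self):
        m = self._matrix()
        assert sample_correlation(m, "s1", "s2") == pytest.approx(
            sample_correlation(m, 0, 1))

    def test_gradient_adjacent_exceeds_extremes(self):
        from xerotome.synthetic import (SimulationConfig,
                                        simulate_expression_gradients)

        cfg = SimulationConfig(seed=12, n_loci=400)
        matrix, truth = simulate_expression_gradients(cfg)
        keep = [i for i, loc in enumerate(matrix.locus_ids)
                if truth[loc] in (0, 1)]
        sub = ExpressionMatrix([matrix.locus_ids[i] for i in keep],
                               matrix.sample_ids, matrix.values[keep])
        adjacent = sample_correlation(sub, 0, 1)
        extremes = sample_correlation(sub, 0, len(sub.sample_ids) - 1)
        assert adjacent > extremes


class TestClustering:
    def test_exact_copies_cluster_perfectly(self):
        base = np.array([[1.0, 0.0, -1.0, 0.0],
                         [-1.0, 0.0, 1.0, 0.0],
                         [0.0, 1.0, 0.0, -1.0]])
        data = np.repeat(base, 5, axis=0)
        model = kmeans_cluster(data, k=3, seed=0)
        assert model.within_ss == pytest.approx(0.0, abs=1e-12)
        labels = [model.assignments[str(i)] for i in range(15)]
        assert len({tuple(labels[i:i + 5]) for i in range(0, 15, 5)}) == 3

    def test_centroids_are_assignment_means(self):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(50, 4))
        model = kmeans_cluster(data, k=4, seed=1)
        labels = np.array([model.assignments[str(i)] for i in range(50)])
        for c in range(4):
            np.testing.assert_allclose(model.centroids[c],
                                       data[labels == c].mean(axis=0))

    def test_same_seed_reproduces_model(self):
        rng = np.random.default_rng(8)
        data = rng.normal(size=(60, 4))
        m1 = kmeans_cluster(data, k=5, seed=3)
        m2 = kmeans_cluster(data, k=5, seed=3)
        assert m1.assignments == m2.assignments
        assert m1.within_ss == m2.within_ss

    def test_choose_k_recovers_archetype_count(self):
        from xerotome.expression import zscale_rows as z
        from xerotome.synthetic import (SimulationConfig,
                                        simulate_expression_gradients)

        cfg = SimulationConfig(seed=13, n_loci=300, noise_sd=0.2)
        matrix, truth = simulate_expression_gradients(cfg)
        zm = z(matrix)
        assert choose_k(zm, range(2, 11), seed=13) == 6
        model = kmeans_cluster(zm, 6, seed=13)
        assert cluster_recovery(model, truth) >= 0.9

    def test_choose_k_requires_three_points(self):
        with pytest.raises(ValueError):
            choose_k(np.zeros((10, 4)), [2, 3], seed=0)

    def test_k_larger_than_data_rejected(self):
        with pytest.raises(ValueError):
            kmeans_cluster(np.zeros((3, 2)), k=5, seed=0)


class TestComposite:
    def _zmatrix(self):
        vals = np.array([[1.0, -1.0, 0.0], [-1.0, 1.0, 0.0],
                         [0.5, 0.0, -0.5]])
        m = ExpressionMatrix.__new__(ExpressionMatrix)
        m.locus_ids, m.sample_ids, m.values = ["a", "b", "c"], ["s1", "s2",
                                                                "s3"], vals
        return m

    def test_singleton_set_is_that_row(self):
        np.testing.assert_allclose(
            composite_expression(self._zmatrix(), {"c"}), [0.5, 0.0, -0.5])

    def test_mirror_rows_cancel(self):
        np.testing.assert_allclose(
            composite_expression(self._zmatrix(), {"a", "b"}), 0.0)

    def test_empty_set_is_nan(self):
        assert np.isnan(composite_expression(self._zmatrix(), set())).all()

    def test_matches_direct_average(self):
        m = self._zmatrix()
        np.testing.assert_allclose(
            composite_expression(m, {"a", "c"}),
            m.values[[0, 2]].mean(axis=0))
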