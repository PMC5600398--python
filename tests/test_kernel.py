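"""Entropy weighting, WIP/IP kernels, normalization, and distances."""

import numpy as np
import pytest

from kmerwip import (
    FrequencySketch,
    KernelMatrix,
    Sketch,
    WeightVector,
    check_psd,
    entropy_weights,
    ip_kernel,
    kernel_to_distance,
    normalize_kernel,
    population_frequency,
    wip_kernel,
)
from kmerwip.kernel import (
    load_matrix,
    load_weights,
    save_matrix,
    save_weights,
)

from conftest import random_sketches


def sketch_from_counts(counts, name="s", k=3, length=None) -> Sketch:
    counts = np.asarray(counts, dtype=np.uint8)
    return Sketch(
        sample_name=name,
        k=k,
        length=length or len(counts),
        counts=counts,
        n_kmers_consumed=int(counts.sum()),
    )


class TestPopulationFrequency:
    def test_presence_fraction(self):
        cols = np.array([[3, 0, 1], [0, 255, 0], [1, 7, 0], [0, 1, 0]])
        sketches = [sketch_from_counts(row, name=f"s{i}") for i, row in enumerate(cols)]
        freq = population_frequency(sketches)
        # bin 0: [3,0,1,0] -> 0.5; bin 1: [0,255,7,1] -> 0.75; bin 2 -> 0.25
        assert np.allclose(freq.freqs, [0.5, 0.75, 0.25])
        assert freq.n_samples == 4
        # frequencies times n_samples are integers
        assert np.allclose(freq.freqs * 4, np.round(freq.freqs * 4))

    def test_magnitude_ignored(self):
        sketches = [
            sketch_from_counts([c, 0, 0], name=f"s{i}")
            for i, c in enumerate([1, 255, 7])
        ]
        freq = population_frequency(sketches)
        assert freq.freqs[0] == 1.0
        assert freq.freqs[1] == 0.0

    def test_requires_two_sketches(self):
        with pytest.raises(ValueError, match="at least 2"):
            population_frequency([sketch_from_counts([1, 0, 0])])

    def test_rejects_mismatched_geometry(self):
        a = sketch_from_counts([1, 0, 0], name="a", k=3)
        b = sketch_from_counts([1, 0, 0], name="b", k=5)
        with pytest.raises(ValueError, match="disagree"):
            population_frequency([a, b])


class TestEntropyWeights:
    @pytest.mark.parametrize(
        "freq,weight",
        [
            (0.5, 1.0),
            (0.0, 0.0),
            (1.0, 0.0),
            (0.25, 0.8112781244591328),
        ],
    )
    def test_binary_entropy(self, freq, weight):
        fs = FrequencySketch(length=1, freqs=np.array([freq]), n_samples=4)
        assert entropy_weights(fs).weights[0] == pytest.approx(weight, abs=1e-12)

    def test_symmetric_about_half_and_bounded(self):
        f = np.linspace(0, 1, 101)
        w = entropy_weights(FrequencySketch(101, f, 100)).weights
        assert np.allclose(w, w[::-1])
        assert w.min() >= 0 and w.max() == 1.0
        assert not np.any(np.isnan(w))


class TestKernels:
    def test_wip_worked_example(self):
        si = sketch_from_counts([2, 0, 1], "i")
        sj = sketch_from_counts([1, 1, 1], "j")
        weights = WeightVector(3, np.array([1.0, 0.5, 0.0]))
        kern = wip_kernel([si, sj], weights)
        assert kern.values[0, 1] == pytest.approx(2.0)
        assert kern.values[1, 0] == pytest.approx(2.0)
        # diagonal: sum_b S_ib^2 H_b = 4*1 + 0 + 0
        assert kern.values[0, 0] == pytest.approx(4.0)

    def test_ip_worked_examples(self):
        si = sketch_from_counts([2, 0, 1], "i")
        sj = sketch_from_counts([1, 1, 1], "j")
        kern = ip_kernel([si, sj])
        assert kern.values[0, 1] == pytest.approx(3.0)
        assert kern.values[0, 0] == pytest.approx(5.0)  # squared norm

    def test_orthogonal_sketches(self):
        a = sketch_from_counts([1, 0], "a", k=2)
        b = sketch_from_counts([0, 1], "b", k=2)
        assert ip_kernel([a, b]).values[0, 1] == 0.0

    def test_uniform_weights_reduce_to_ip(self, rng):
        sketches = random_sketches(rng, 5)
        ones = WeightVector(97, np.ones(97))
        assert np.array_equal(
            wip_kernel(sketches, ones).values, ip_kernel(sketches).values
        )

    def test_zero_weights_zero_kernel(self, rng):
        sketches = random_sketches(rng, 4)
        zeros = WeightVector(97, np.zeros(97))
        assert np.all(wip_kernel(sketches, zeros).values == 0)

    def test_weight_length_mismatch(self, rng):
        sketches = random_sketches(rng, 3)
        with pytest.raises(ValueError, match="length"):
            wip_kernel(sketches, WeightVector(11, np.ones(11)))

    def test_gram_property_psd(self, rng):
        """WIP kernels are Gram matrices of a weighted inner product,
        hence PSD for any sketches and non-negative weights."""
        for _ in range(10):
            sketches = random_sketches(rng, int(rng.integers(3, 9)))
            weights = WeightVector(97, rng.random(97))
            flag, smallest = check_psd(wip_kernel(sketches, weights))
            assert flag, f"smallest eigenvalue {smallest}"


class TestNormalization:
    def test_worked_example(self):
        kern = KernelMatrix(["a", "b"], np.array([[4.0, 2.0], [2.0, 9.0]]))
        normed = normalize_kernel(kern)
        assert normed.values == pytest.approx(
            np.array([[1.0, 1 / 3], [1 / 3, 1.0]]), abs=1e-12
        )
        assert normed.normalized

    def test_identity_fixed_point(self):
        kern = KernelMatrix(["a", "b", "c"], np.eye(3))
        assert np.array_equal(normalize_kernel(kern).values, np.eye(3))

    def test_zero_self_similarity_names_sample(self):
        kern = KernelMatrix(["good", "empty"], np.array([[4.0, 0.0], [0.0, 0.0]]))
        with pytest.raises(ValueError, match="empty"):
            normalize_kernel(kern)

    def test_scale_invariance(self, rng):
        """Uniformly scaling one sample's counts (no saturation) must not
        change the normalized kernel or the distances."""
        sketches = random_sketches(rng, 5)
        weights = WeightVector(97, rng.random(97))
        base = normalize_kernel(wip_kernel(sketches, weights))
        scaled = [s for s in sketches]
        s0 = sketches[0]
        scaled[0] = Sketch(
            sample_name=s0.sample_name,
            k=s0.k,
            length=s0.length,
            counts=(s0.counts.astype(np.int64) * 3).clip(0, 255).astype(np.uint8),
            n_kmers_consumed=s0.n_kmers_consumed * 3,
        )
        assert s0.counts.max() * 3 <= 255  # no saturation: invariance is exact
        after = normalize_kernel(wip_kernel(scaled, weights))
        assert np.allclose(base.values, after.values, atol=1e-9)


class TestDistances:
    def test_worked_example(self):
        kern = KernelMatrix(
            ["a", "b"], np.array([[1.0, 1 / 3], [1 / 3, 1.0]]), normalized=True
        )
        dist = kernel_to_distance(kern)
        assert dist.values[0, 1] == pytest.approx(np.sqrt(4 / 3), abs=1e-12)
        assert dist.values[0, 0] == 0.0

    @pytest.mark.parametrize("kij,expected", [(1.0, 0.0), (0.0, np.sqrt(2))])
    def test_limits(self, kij, expected):
        kern = KernelMatrix(
            ["a", "b"], np.array([[1.0, kij], [kij, 1.0]]), normalized=True
        )
        assert kernel_to_distance(kern).values[0, 1] == pytest.approx(expected)

    def test_rejects_invalid_kernel(self):
        kern = KernelMatrix(
            ["a", "b"], np.array([[1.0, 1.5], [1.5, 1.0]]), normalized=True
        )
        with pytest.raises(ValueError, match="negative squared distance"):
            kernel_to_distance(kern)

    def test_metric_axioms_randomized(self, rng):
        for _ in range(10):
            sketches = random_sketches(rng, int(rng.integers(3, 8)))
            weights = WeightVector(97, rng.random(97))
            dist = kernel_to_distance(
                normalize_kernel(wip_kernel(sketches, weights))
            ).values
            n = dist.shape[0]
            assert np.allclose(dist, dist.T)
            assert np.all(np.diag(dist) == 0)
            assert np.all(dist >= 0)
            for i in range(n):
                for j in range(n):
                    for m in range(n):
                        assert dist[i, j] <= dist[i, m] + dist[m, j] + 1e-9


class TestRelativity:
    def test_wip_distance_depends_on_sample_set(self, rng):
        """H is population-specific: adding a sample changes the WIP
        distance between a fixed pair."""
        sketches = random_sketches(rng, 4)

        def pair_distance(subset):
            weights = entropy_weights(population_frequency(subset))
            dist = kernel_to_distance(
                normalize_kernel(wip_kernel(subset, weights))
            )
            return dist.values[0, 1]

        d3 = pair_distance(sketches[:3])
        d4 = pair_distance(sketches)
        assert d3 != pytest.approx(d4, abs=1e-12)


class TestPsdCheck:
    def test_identity(self):
        flag, smallest = check_psd(KernelMatrix(["a"], np.eye(1)))
        assert flag and smallest == pytest.approx(1.0)

    def test_indefinite_matrix(self):
        flag, smallest = check_psd(
            KernelMatrix(["a", "b"], np.array([[1.0, 2.0], [2.0, 1.0]]))
        )
        assert not flag
        assert smallest == pytest.approx(-1.0)

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError, match="symmetric"):
            check_psd(KernelMatrix(["a", "b"], np.array([[1.0, 2.0], [0.0, 1.0]])))

    def test_floating_point_jitter_tolerated(self):
        # a -1e-10 eigenvalue is within the 1e-8 relative tolerance
        kern = KernelMatrix(["a", "b"], np.diag([1.0, -1e-10]))
        flag, smallest = check_psd(kern)
        assert flag and smallest == pytest.approx(-1e-10)


class TestMatrixIO:
    def test_tsv_round_trip(self, tmp_path, rng):
        names = ["s0", "s1", "s2"]
        values = rng.random((3, 3))
        values = (values + values.T) / 2
        path = tmp_path / "m.tsv"
        save_matrix(names, values, path)
        got_names, got = load_matrix(path)
        assert got_names == names
        assert np.allclose(got, values, atol=1e-9)

    def test_phylip_shape(self, tmp_path):
        path = tmp_path / "m.phylip"
        save_matrix(["a", "b"], np.zeros((2, 2)), path, fmt="phylip")
        lines = path.read_text().splitlines()
        assert lines[0] == "2"
        assert lines[1].startswith("a ")

    def test_weights_round_trip(self, tmp_path, rng):
        weights = WeightVector(17, rng.random(17))
        path = tmp_path / "w.kwv"
        save_weights(weights, path)
        got = load_weights(path)
        assert got.length == 17
        assert np.array_equal(got.weights, weights.weights)
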