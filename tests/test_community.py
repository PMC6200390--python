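import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from microbiability import (SimConfig, axis_variance_decomposition,
                            bray_curtis, build_A, decile_contrast,
                            decile_groups, mann_whitney_axis,
                            percent_difference, pcoa, simulate_pedigree)
from microbiability.community import DissimilarityMatrix
from microbiability.simulate import last_generation, _gene_drop


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        d = bray_curtis(np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]]))
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_samples_one(self):
        d = bray_curtis(np.array([[1.0, 0.0], [0.0, 5.0]]))
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_hand_formula(self):
        # u=(1,2,0), v=(2,0,1): 1 - 2*min-sum/total = 1 - 2/6 = 2/3 on counts
        d = bray_curtis(np.array([[1.0, 2.0, 0.0], [2.0, 0.0, 1.0]]),
                        relative=False)
        assert d.values[0, 1] == pytest.approx(2.0 / 3.0)

    def test_invariant_to_per_sample_scaling(self, rng):
        x = rng.uniform(0, 5, size=(6, 10))
        scaled = x * rng.uniform(0.5, 20, size=(6, 1))
        np.testing.assert_allclose(bray_curtis(x).values,
                                   bray_curtis(scaled).values, atol=1e-12)

    def test_zero_sample_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(np.array([[0.0, 0.0], [1.0, 2.0]]))


class TestPcoa:
    def _dist(self, pts):
        return DissimilarityMatrix(
            [str(i) for i in range(len(pts))],
            squareform(pdist(np.asarray(pts, float)[:, None])) / 10.0)

    def test_euclidean_oracle_recovers_line(self):
        """PCoA of distances between points 0, 1, 3 on a line reproduces the
        inter-point spacing (1, 2) on PCo1 up to sign."""
        ordn = pcoa(self._dist([0.0, 1.0, 3.0]))
        c = ordn.axis(0)
        gaps = np.abs(np.diff(c))
        np.testing.assert_allclose(sorted(gaps * 10.0), [1.0, 2.0], atol=1e-10)

    def test_matches_classical_scaling_package(self, rng):
        skbio = pytest.importorskip("skbio")
        x = rng.uniform(0, 1, size=(12, 6))
        d = bray_curtis(x)
        mine = pcoa(d, n_axes=3)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.values, ids=d.labels))
        for k in range(3):
            a = mine.axis(k)
            b = ref.samples.iloc[:, k].to_numpy()
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8
        np.testing.assert_allclose(
            mine.proportion_explained,
            ref.proportion_explained.to_numpy()[:3], atol=1e-8)

    def test_identical_samples_identical_coordinates(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 1.0]])
        ordn = pcoa(bray_curtis(x))
        np.testing.assert_allclose(ordn.coordinates[0], ordn.coordinates[1],
                                   atol=1e-10)

    def test_eigenvalues_sorted_and_axes_centered(self, rng):
        ordn = pcoa(bray_curtis(rng.uniform(0, 1, size=(10, 8))))
        assert (np.diff(ordn.eigenvalues) <= 1e-12).all()
        np.testing.assert_allclose(ordn.coordinates.mean(axis=0), 0.0,
                                   atol=1e-10)

    def test_truncation_warning(self, rng):
        d = bray_curtis(rng.uniform(0, 1, size=(5, 4)))
        with pytest.warns(UserWarning, match="truncating"):
            ordn = pcoa(d, n_axes=10)
        assert ordn.coordinates.shape[1] <= 4


class TestDecileGroups:
    def test_counts_at_n_100(self):
        labels = decile_groups(np.arange(1, 101))
        assert (labels == "high").sum() == 10
        assert (labels == "low").sum() == 10
        assert (labels == "intermediate").sum() == 80

    def test_monotone_phenotype_assignment(self):
        labels = decile_groups(np.arange(1, 101))
        assert set(np.flatnonzero(labels == "high")) == set(range(90, 100))

    def test_too_few_animals_error(self):
        with pytest.raises(ValueError):
            decile_groups(np.arange(5))

    def test_printed_group_means_give_41_percent(self):
        # contrast computed from the printed decile means 519.28 and 303.8 g/d
        assert round(percent_difference(519.28, 303.8)) == 41

    def test_contrast_on_simulated_values(self, rng):
        v = rng.normal(400, 60, 200)
        c = decile_contrast(v)
        assert c["high_mean"] > c["low_mean"]
        assert c["percent_difference"] == pytest.approx(
            100 * (c["high_mean"] - c["low_mean"]) / c["high_mean"])


class TestMannWhitney:
    def test_exact_enumeration_example(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        groups = np.array(["high"] * 3 + ["low"] * 3, dtype=object)
        u, p = mann_whitney_axis(vals, groups)
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_null_calibration(self, rng):
        rej = 0
        reps = 500
        vals = rng.standard_normal(60)
        for _ in range(reps):
            g = np.array(["high"] * 30 + ["low"] * 30, dtype=object)
            rng.shuffle(g)
            _, p = mann_whitney_axis(vals, g)
            rej += p < 0.05
        assert 0.02 <= rej / reps <= 0.08

    def test_shift_increases_separation(self, rng):
        base = rng.standard_normal(40)
        g = np.array(["high"] * 20 + ["low"] * 20, dtype=object)
        shifted = base.copy()
        shifted[:20] += 2.0
        _, p0 = mann_whitney_axis(base, g)
        _, p1 = mann_whitney_axis(shifted, g)
        assert p1 < p0

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            mann_whitney_axis(np.arange(4.0),
                              np.array(["high"] * 4, dtype=object))

    @settings(max_examples=25, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_invariant_to_monotone_transform(self, scale):
        rng = np.random.default_rng(3)
        vals = rng.standard_normal(30)
        g = np.array(["high"] * 15 + ["low"] * 15, dtype=object)
        _, p_raw = mann_whitney_axis(vals, g)
        _, p_tr = mann_whitney_axis(np.exp(scale * vals), g)
        assert p_raw == pytest.approx(p_tr)


class TestAxisDecomposition:
    def _metadata(self, ped, rng):
        animals = last_generation(ped)
        n = len(animals)
        return animals, pd.DataFrame({
            "animal": animals,
            "herd": rng.integers(1, 7, n),
            "parity": rng.integers(1, 5, n),
            "dim": rng.integers(1, 351, n),
            "platform": np.where(rng.random(n) < 0.5, "MiSeq", "HiSeq"),
        }).assign(batch=lambda d: d["platform"] + "_b" +
                  rng.integers(0, 3, n).astype(str))

    def test_pure_noise_axis(self, rng):
        ped = simulate_pedigree(SimConfig(n_founders=150, n_generations=2,
                                          n_sires=8, seed=61))
        animals, md = self._metadata(ped, rng)
        A = build_A(ped, subset=animals)
        dec = axis_variance_decomposition(rng.standard_normal(len(animals)),
                                          md, A)
        assert dec.h2 < 0.2
        assert all(s < 0.15 for f, s in dec.factor_shares.items()
                   if f != "residual")

    def test_constructed_parity_signal(self, rng):
        ped = simulate_pedigree(SimConfig(n_founders=150, n_generations=2,
                                          n_sires=8, seed=62))
        animals, md = self._metadata(ped, rng)
        A = build_A(ped, subset=animals)
        parity_means = np.array([0.0, 3.0, 6.0, 9.0])
        axis = parity_means[md["parity"] - 1] \
            + 0.05 * rng.standard_normal(len(animals))
        dec = axis_variance_decomposition(axis, md, A)
        assert dec.factor_shares["parity"] > 0.95
        assert dec.factor_order[:3] == ("herd", "parity", "batch")

    def test_heritable_axis_recovery(self, rng):
        """Axis simulated at the archaeal-PCo1 heritability magnitude."""
        h2_true = 0.39
        ests = []
        for seed in (63, 64, 65):
            ped = simulate_pedigree(SimConfig(n_founders=600, n_generations=2,
                                              n_sires=15, seed=seed))
            animals, md = self._metadata(ped, rng)
            A = build_A(ped, subset=animals)
            idx = [ped.ids.index(a) for a in animals]
            F = np.diag(build_A(ped).values) - 1.0
            a = _gene_drop(ped, F, 1, rng)[idx, 0]
            axis = np.sqrt(h2_true) * a \
                + np.sqrt(1 - h2_true) * rng.standard_normal(len(animals))
            ests.append(axis_variance_decomposition(axis, md, A).h2)
        assert np.mean(ests) == pytest.approx(h2_true, abs=0.12)
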