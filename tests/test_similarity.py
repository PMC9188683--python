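"""Ring-kernel similarity: kernel geometry, regularization, and the three
similarity measures against independent estimators."""

import numpy as np
import pytest
from scipy import signal
from sklearn.metrics import mutual_info_score

import ceusrad as cr
from ceusrad.similarity import (
    KernelError,
    _coherence_params,
    _equal_frequency_bins,
    binned_mutual_information,
)


class TestRingKernel:
    def test_offsets_match_bruteforce_enumeration(self):
        """spacing 0.5 mm, radii (1, 2.5] mm -> offsets with norm in (2, 5] px."""
        k = cr.build_ring_kernel(0.5, 1.0, 2.5)
        brute = [
            (dy, dx)
            for dy in range(-6, 7)
            for dx in range(-6, 7)
            if 2.0 < np.hypot(dy, dx) <= 5.0
        ]
        assert sorted(map(tuple, k.offsets)) == sorted(brute)

    def test_first_ring_is_4_neighborhood(self):
        k = cr.build_ring_kernel(1.0, 0.0, 1.0)
        assert sorted(map(tuple, k.offsets)) == [(-1, 0), (0, -1), (0, 1), (1, 0)]

    def test_center_always_excluded(self):
        for spacing in (0.2, 0.5, 1.0):
            k = cr.build_ring_kernel(spacing)
            assert (0, 0) not in set(map(tuple, k.offsets))

    def test_invalid_radii(self):
        with pytest.raises(KernelError):
            cr.build_ring_kernel(0.5, 2.5, 2.5)

    def test_coarse_spacing_empty_kernel(self):
        with pytest.raises(KernelError):
            cr.build_ring_kernel(10.0, 1.0, 2.5)


class TestSpeckleRegularize:
    def test_constant_frame_unchanged(self):
        f = np.full((30, 30), 4.2)
        assert np.allclose(cr.speckle_regularize(f), f)

    def test_variance_reduced_and_mass_conserved(self):
        rng = np.random.default_rng(0)
        f = rng.gamma(4, 0.25, (40, 40))
        g = cr.speckle_regularize(f)
        assert g.var() < f.var()
        assert g.sum() == pytest.approx(f.sum(), rel=1e-3)

    def test_step_edge_preserved(self):
        """The half-max crossing of a strong step edge moves < 1 px."""
        f = np.zeros((30, 30))
        f[:, 15:] = 1.0
        g = cr.speckle_regularize(f)
        row = g[15]
        crossing = np.argmax(row >= 0.5)
        assert abs(crossing - 15) < 1.0


class TestSimilarityWindow:
    def test_index_arithmetic(self):
        t = np.arange(60, dtype=float)
        tics = np.arange(60, dtype=float)[:, None]
        w, tw = cr.similarity_window(tics, t, 12.0, 20.0)
        assert np.array_equal(tw, np.arange(12, 32, dtype=float))
        assert w.shape[0] == 20

    def test_truncation_warns(self, caplog):
        t = np.arange(60, dtype=float)
        with caplog.at_level("WARNING", logger="ceusrad.similarity"):
            w, _ = cr.similarity_window(np.ones((60, 2)), t, 50.0, 20.0)
        assert w.shape[0] == 10
        assert any("truncated" in r.message for r in caplog.records)

    def test_full_duration_identity(self):
        t = np.arange(30, dtype=float)
        w, _ = cr.similarity_window(np.ones((30, 3)), t, 0.0, 30.0)
        assert w.shape[0] == 30


class TestPairwiseSimilarity:
    def test_affine_pair_perfect_linear_similarity(self, rng):
        a = rng.standard_normal(24)
        coh, r, mi = cr.pairwise_similarity(a, 2.0 * a + 3.0)
        assert r == pytest.approx(1.0)
        assert coh == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_near_null(self, rng):
        """r and MI of independent pairs sit at the permutation-null level."""
        n = 24
        rs, mis = [], []
        for _ in range(300):
            coh, r, mi = cr.pairwise_similarity(
                rng.standard_normal(n), rng.standard_normal(n)
            )
            rs.append(r)
            mis.append(mi)
        assert abs(np.mean(rs)) < 0.05
        # estimator bias floor for the binned MI under independence
        null_mi = np.mean(mis)
        a = rng.standard_normal(n)
        _, _, mi_self = cr.pairwise_similarity(a, a)
        assert null_mi < 0.5 * mi_self

    def test_self_mi_equals_binned_entropy(self, rng):
        a = rng.standard_normal(25)
        mi = binned_mutual_information(a, a)
        bins = _equal_frequency_bins(a, 5)
        counts = np.bincount(bins, minlength=5) / a.size
        entropy = -(counts[counts > 0] * np.log(counts[counts > 0])).sum()
        assert mi == pytest.approx(entropy, rel=1e-12)

    def test_mi_matches_sklearn_contingency(self, rng):
        a = rng.standard_normal(30)
        b = rng.standard_normal(30) + 0.7 * a
        nb = int(np.ceil(np.sqrt(30)))
        mi = binned_mutual_information(a, b)
        ref = mutual_info_score(
            _equal_frequency_bins(a, nb), _equal_frequency_bins(b, nb)
        )
        assert mi == pytest.approx(ref, rel=1e-10)

    def test_coherence_matches_scipy_welch(self, rng):
        """The vectorized Welch coherence agrees with scipy.signal.coherence
        at matching segmentation, taper and detrending."""
        n = 40
        a = rng.standard_normal(n)
        b = rng.standard_normal(n) + 0.5 * a
        nperseg, noverlap = _coherence_params(n, None)
        f, cxy = signal.coherence(
            a, b, nperseg=nperseg, noverlap=noverlap,
            window="hann", detrend="constant",
        )
        coh, _, _ = cr.pairwise_similarity(a, b)
        assert coh == pytest.approx(cxy[1:].mean(), rel=1e-8)

    def test_zero_variance_flagged_missing(self):
        coh, r, mi = cr.pairwise_similarity(np.ones(20), np.arange(20.0))
        assert np.isnan(coh) and np.isnan(r) and np.isnan(mi)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            cr.pairwise_similarity(np.arange(5.0), np.arange(5.0))


class TestSimilarityMaps:
    def test_uniform_cine_all_ones(self):
        """Every pixel sharing one TIC gives coherence = correlation = 1."""
        t = np.arange(60, dtype=float)
        tic = cr.bolus_tic(t, 0.5, 10.0, np.log(20), 0.5)
        ceus = np.tile(tic[:, None, None], (1, 40, 40))
        maps = cr.similarity_map_stack(
            ceus, t, (0, 40, 0, 40), appearance_time_s=12.0,
            spacing_mm=0.5, regularize_iter=0,
        )
        assert len(maps) == 3
        inner = (slice(6, -6), slice(6, -6))
        assert np.allclose(maps["Coherence"][inner], 1.0, atol=1e-9)
        assert np.allclose(maps["Correlation"][inner], 1.0, atol=1e-9)
        assert np.all(maps["MutualInformation"][inner] > 0)

    def test_border_pixels_flagged_missing(self):
        t = np.arange(60, dtype=float)
        tic = cr.bolus_tic(t, 0.5, 10.0, np.log(20), 0.5)
        ceus = np.tile(tic[:, None, None], (1, 40, 40))
        maps = cr.similarity_map_stack(
            ceus, t, (0, 40, 0, 40), appearance_time_s=12.0,
            spacing_mm=0.5, regularize_iter=0,
        )
        assert np.isnan(maps["Coherence"][0, 0])

    def test_value_ranges(self, speckled_cine, small_config):
        cine, truth, ann = speckled_cine
        lin = cr.linearize(cine)
        roi = cr.square_roi(ann, cine.shape[1:], min_side=48, max_side=96)
        maps = cr.similarity_map_stack(
            lin.ceus, lin.times, roi,
            appearance_time_s=truth.appearance_time_s, spacing_mm=0.5,
        )
        coh = maps["Coherence"]
        r = maps["Correlation"]
        mi = maps["MutualInformation"]
        assert np.nanmin(coh) >= 0 and np.nanmax(coh) <= 1
        assert np.nanmin(r) >= -1 and np.nanmax(r) <= 1
        assert np.nanmin(mi) >= 0

    def test_heterogeneous_lesion_lower_coherence(self):
        """Per-pixel kinetic jitter inside the lesion lowers lesion-mean
        coherence below the homogeneous parenchyma."""
        cfg = cr.SimConfig(n_frames=60, height=96, width=96, lesion_radius=16,
                           kinetic_jitter=0.3, seed=6)
        cine, truth, ann = cr.generate_cine(cfg)
        lin = cr.linearize(cine)
        roi = cr.square_roi(ann, cine.shape[1:], min_side=64, max_side=96)
        maps = cr.similarity_map_stack(
            lin.ceus, lin.times, roi,
            appearance_time_s=truth.appearance_time_s, spacing_mm=0.5,
        )
        lesion = roi.lesion_mask_roi
        coh = maps["Coherence"]
        les_mean = np.nanmean(coh[lesion])
        par_mean = np.nanmean(coh[~lesion])
        assert les_mean < par_mean

    def test_time_shift_invariance(self):
        """Shifting the analysis window start by a constant leaves all
        three measures unchanged (they see the same samples)."""
        rng = np.random.default_rng(3)
        t = np.arange(60, dtype=float)
        base = cr.bolus_tic(t, 0.5, 10.0, np.log(20), 0.5)
        ceus = base[:, None, None] * (1 + 0.2 * rng.random((1, 30, 30)))
        m1 = cr.similarity_map_stack(ceus, t, (0, 30, 0, 30), 12.0,
                                     spacing_mm=0.5, regularize_iter=0)
        shifted = np.concatenate([np.zeros((5, 30, 30)), ceus], axis=0)
        t2 = np.arange(65, dtype=float)
        m2 = cr.similarity_map_stack(shifted, t2, (0, 30, 0, 30), 17.0,
                                     spacing_mm=0.5, regularize_iter=0)
        for name in m1:
            assert np.allclose(m1[name], m2[name], equal_nan=True), name
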