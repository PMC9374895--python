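"""HRF tensors, soft-threshold rescaling, CPD-ALS and reconstruction."""

import numpy as np
import pytest

from tensorhrf.hrf_core import spherical_laguerre_basis
from tensorhrf.signal_prep import STANDARD_BANDS, AmplitudeTensor, BandSpec
from tensorhrf.tensor_cpd import (HRFTensor, build_hrf_tensor,  # noqa: F401
                                  center_scale_order4, cpd_als,
                                  estimate_hrf_tensor, fit_multicomponent,
                                  nmode_vector_product, read_cpd_result,
                                  reconstruct_bold, rescale_soft_threshold,
                                  run_node_pipeline, write_cpd_result)

FS = 4.0


class TestBuildHRFTensor:
    def test_full_grid_assembly(self, rng):
        coll = {(i, b): rng.standard_normal(16)
                for i in range(6) for b in range(5)}
        hrf = build_hrf_tensor(coll, fs=FS)
        assert hrf.values.shape == (16, 6, 5)
        assert np.array_equal(hrf.values[:, 2, 3], coll[(2, 3)])

    def test_single_cell(self, rng):
        hrf = build_hrf_tensor({(0, 0): rng.standard_normal(8)}, fs=FS)
        assert hrf.values.shape == (8, 1, 1)

    def test_missing_cell_rejected(self, rng):
        coll = {(i, b): rng.standard_normal(8)
                for i in range(3) for b in range(2)}
        del coll[(1, 1)]
        with pytest.raises(ValueError, match="full grid"):
            build_hrf_tensor(coll, fs=FS)

    def test_unequal_kernel_length_rejected(self, rng):
        coll = {(0, 0): rng.standard_normal(8),
                (0, 1): rng.standard_normal(9),
                (1, 0): rng.standard_normal(8),
                (1, 1): rng.standard_normal(8)}
        with pytest.raises(ValueError, match="unequal"):
            build_hrf_tensor(coll, fs=FS)

    def test_order4_with_subjects(self, rng):
        coll = {(i, b, s): rng.standard_normal(8)
                for i in range(2) for b in range(3) for s in range(2)}
        hrf = build_hrf_tensor(coll, fs=FS)
        assert hrf.values.shape == (8, 2, 3, 2)


def _toy_amp_and_tensor(rng, n_nodes=3, n_bands=5, n_times=800, L=32):
    from scipy.ndimage import gaussian_filter1d

    vals = gaussian_filter1d(rng.standard_normal((n_nodes, n_bands, n_times)),
                             4, axis=-1)
    vals /= vals.std(axis=-1, keepdims=True)
    amp = AmplitudeTensor(values=vals + 2, fs=FS, band_spec=STANDARD_BANDS)
    kernels = rng.standard_normal((L, n_nodes, n_bands)) * 0.2
    return amp, HRFTensor(values=kernels, fs=FS)


class TestSoftThresholdRescale:
    def test_matches_definition_at_percentile_zero(self, rng):
        amp, hrf = _toy_amp_and_tensor(rng)
        bold = rng.standard_normal(800)
        out = rescale_soft_threshold(hrf, amp, bold, 0.0)
        # recompute the oracle correlation matrix by brute force
        r = np.zeros((3, 5))
        for i in range(3):
            for b in range(5):
                x = amp.values[i, b]
                xz = (x - x.mean()) / x.std()
                pred = np.convolve(xz, hrf.values[:, i, b])[:800]
                r[i, b] = np.corrcoef(pred, bold)[0, 1]
        theta = np.abs(r).min()
        s = np.sign(r) * np.maximum(np.abs(r) - theta, 0.0)
        assert np.allclose(out.values, hrf.values * s[None], atol=1e-12)
        # exactly the argmin cell(s) are zeroed
        zero_cells = np.linalg.norm(out.values, axis=0) == 0
        assert zero_cells.sum() >= 1
        assert zero_cells[np.unravel_index(np.argmin(np.abs(r)), r.shape)]

    def test_independent_noise_cell_suppressed(self, rng):
        # one cell whose amplitude signal genuinely drives BOLD, the rest
        # independent: thresholding at percentile >= 25 zeroes noise cells
        amp, hrf = _toy_amp_and_tensor(rng)
        basis = spherical_laguerre_basis(3, 1.2, 32.0, FS)
        h = basis.matrix @ np.array([1.0, -0.4, 0.1])
        bold = np.convolve(amp.values[1, 2], h)[:800]
        est = estimate_hrf_tensor(amp, bold, basis)
        out = rescale_soft_threshold(est, amp, bold, 50.0)
        norms = np.linalg.norm(out.values, axis=0)
        assert np.argmax(norms) == np.ravel_multi_index((1, 2), (3, 5))

    def test_zero_count_monotone_in_percentile(self, rng):
        amp, hrf = _toy_amp_and_tensor(rng)
        bold = rng.standard_normal(800)
        counts = []
        for pct in (0, 25, 50, 75, 90):
            out = rescale_soft_threshold(hrf, amp, bold, pct)
            counts.append(int((np.linalg.norm(out.values, axis=0) == 0).sum()))
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_invalid_percentile(self, rng):
        amp, hrf = _toy_amp_and_tensor(rng)
        with pytest.raises(ValueError):
            rescale_soft_threshold(hrf, amp, np.zeros(800), 100.0)


class TestCenterScaleOrder4:
    def test_postconditions(self, rng):
        X = rng.standard_normal((16, 4, 5, 3))
        out = center_scale_order4(HRFTensor(values=X, fs=FS))
        assert np.abs(out.values.mean(axis=2)).max() < 1e-12

    def test_unit_rms_slab_unchanged_by_scaling(self, rng):
        X = rng.standard_normal((8, 3, 4, 2))
        X /= np.sqrt(np.mean(X ** 2, axis=(0, 1, 2)))[None, None, None, :]
        out = center_scale_order4(HRFTensor(values=X, fs=FS))
        manual = X - X.mean(axis=2, keepdims=True)
        assert np.allclose(out.values, manual, atol=1e-12)

    def test_scale_equivalent_subjects_identical(self, rng):
        base = rng.standard_normal((8, 3, 4))
        X = np.stack([base, 10.0 * base], axis=-1)
        out = center_scale_order4(HRFTensor(values=X, fs=FS))
        assert np.allclose(out.values[..., 0], out.values[..., 1], atol=1e-12)

    def test_zero_slab_rejected(self, rng):
        X = rng.standard_normal((8, 3, 4, 2))
        X[..., 1] = 0.0
        with pytest.raises(ValueError):
            center_scale_order4(HRFTensor(values=X, fs=FS))


class TestCPDALS:
    def test_exact_rank1_recovery(self, fixtures):
        fx = fixtures["rank1"]
        res = cpd_als(fx["tensor"], rank=1, seed=1)
        a, b, c = fx["factors"]
        t_unit = res.temporal[:, 0] / np.linalg.norm(res.temporal[:, 0])
        assert abs(t_unit @ a) > 0.999
        assert abs(res.spatial[:, 0] @ b) > 0.999
        assert abs(res.spectral[:, 0] @ c) > 0.999
        assert abs(res.weights[0] - fx["weight"]) / fx["weight"] < 0.01

    def test_exact_rank2_recovery(self, fixtures):
        fx = fixtures["rank2"]
        res = cpd_als(fx["tensor"], rank=2, seed=2)
        A, B, C = fx["factors"]
        # components sorted by energy: match greedily by congruence
        for j in range(2):
            congr = [abs((res.spatial[:, j] @ B[:, k])
                         * (res.spectral[:, j] @ C[:, k])) for k in range(2)]
            assert max(congr) > 0.99

    def test_relative_error_non_increasing(self, rng):
        X = rng.standard_normal((12, 6, 5))
        res = cpd_als(X, rank=2, n_restarts=1, max_iter=50, seed=3)
        hist = res.error_history
        assert len(hist) > 1
        assert np.all(np.diff(hist) <= 1e-12)

    def test_order4_decomposition(self, rng):
        a, b, c, d = (rng.standard_normal(s) for s in (10, 4, 3, 5))
        X = np.einsum("i,j,k,l->ijkl", a, b, c, d)
        res = cpd_als(X, rank=1, seed=4)
        assert res.fit < 1e-8
        assert res.subject is not None
        assert res.subject.shape == (5, 1)

    def test_non_temporal_factors_unit_norm(self, rng):
        X = rng.standard_normal((12, 6, 5))
        res = cpd_als(X, rank=2, seed=5)
        assert np.allclose(np.linalg.norm(res.spatial, axis=0), 1.0)
        assert np.allclose(np.linalg.norm(res.spectral, axis=0), 1.0)
        assert np.all(res.weights >= 0)

    def test_zero_tensor_rejected(self):
        with pytest.raises(ValueError):
            cpd_als(np.zeros((4, 3, 2)), rank=1)


class TestNModeProduct:
    def test_one_hot_selects_slab(self, rng):
        T = rng.standard_normal((4, 3, 5))
        v = np.zeros(3)
        v[1] = 1.0
        assert np.allclose(nmode_vector_product(T, v, 1), T[:, 1, :])

    def test_agrees_with_nested_loops(self, rng):
        T = rng.standard_normal((4, 3, 5))
        v = rng.standard_normal(3)
        manual = np.zeros((4, 5))
        for i in range(4):
            for j in range(3):
                for k in range(5):
                    manual[i, k] += T[i, j, k] * v[j]
        assert np.abs(nmode_vector_product(T, v, 1) - manual).max() < 1e-12

    def test_contractions_commute(self, rng):
        T = rng.standard_normal((4, 3, 5))
        u = rng.standard_normal(3)
        w = rng.standard_normal(5)
        a = nmode_vector_product(nmode_vector_product(T, u, 1), w, 1)
        b = nmode_vector_product(nmode_vector_product(T, w, 2), u, 1)
        assert np.allclose(a, b, atol=1e-12)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            nmode_vector_product(rng.standard_normal((4, 3, 5)),
                                 np.zeros(4), 1)


class TestReconstruction:
    def test_closed_loop_recovery(self, fixtures):
        fx = fixtures["closed_loop"]
        basis = spherical_laguerre_basis(3, fx["decay"], 32.0, FS)
        cpd, est, r = run_node_pipeline(fx["amplitude"], fx["bold"], basis,
                                        percentile=0.0, rank=1, seed=0)
        assert r > 0.9
        # recovered spatial weights match the generative ones up to sign
        w = cpd.spatial[:, 0]
        assert abs(w @ fx["w_space"]) > 0.95

    def test_reconstruction_from_matching_tensor(self, fixtures):
        # CPD fed the exact generative tensor h (x) w_space (x) w_freq:
        # the reconstruction must hit the noiseless BOLD almost perfectly
        fx = fixtures["closed_loop"]
        true_tensor = np.einsum("l,i,b->lib", fx["hrf"], fx["w_space"],
                                fx["w_freq"])
        cpd = cpd_als(true_tensor, rank=1, seed=0)
        _, est, r = reconstruct_bold(fx["amplitude"], cpd, 0, fx["bold"])
        assert r > 0.95

    def test_sign_flip_invariance(self, fixtures, rng):
        fx = fixtures["closed_loop"]
        basis = spherical_laguerre_basis(3, fx["decay"], 32.0, FS)
        cpd, _, r = run_node_pipeline(fx["amplitude"], fx["bold"], basis,
                                      percentile=0.0, rank=1, seed=0)
        flipped = cpd
        flipped.spatial = -flipped.spatial
        flipped.spectral = -flipped.spectral
        _, _, r2 = reconstruct_bold(fx["amplitude"], flipped, 0, fx["bold"])
        assert abs(abs(r2) - abs(r)) < 1e-9

    def test_zero_factor_rejected(self, fixtures):
        fx = fixtures["closed_loop"]
        basis = spherical_laguerre_basis(3, fx["decay"], 32.0, FS)
        cpd, _, _ = run_node_pipeline(fx["amplitude"], fx["bold"], basis,
                                      percentile=0.0, rank=1, seed=0)
        cpd.spatial = np.zeros_like(cpd.spatial)
        with pytest.raises(ValueError):
            reconstruct_bold(fx["amplitude"], cpd, 0, fx["bold"])


def test_precomputed_pipeline_matches_reference_path(fixtures):
    """NodePipeline (cached designs) and run_node_pipeline agree exactly."""
    from tensorhrf.tensor_cpd import NodePipeline

    fx = fixtures["closed_loop"]
    basis = spherical_laguerre_basis(3, 1.2, 32.0, FS)
    _, _, r_ref = run_node_pipeline(fx["amplitude"], fx["bold"], basis,
                                    percentile=25.0, rank=1, n_restarts=3,
                                    seed=2)
    pipe = NodePipeline(fx["amplitude"], basis, percentile=25.0, rank=1,
                        n_restarts=3, seed=2)
    _, _, r_pipe = pipe(fx["bold"])
    assert abs(r_ref - r_pipe) < 1e-10


class TestMulticomponentFit:
    def test_two_orthogonal_regressors_sum_exactly(self, rng):
        e1 = np.sin(2 * np.pi * np.arange(400) / 50)
        e2 = np.cos(2 * np.pi * np.arange(400) / 50)
        bold = 2.0 * e1 - 3.0 * e2
        _, r = fit_multicomponent([e1, e2], bold)
        assert abs(r - 1.0) < 1e-12

    def test_ols_beats_best_individual(self, rng):
        e1 = rng.standard_normal(500)
        e2 = rng.standard_normal(500)
        bold = e1 + 0.5 * e2 + 0.1 * rng.standard_normal(500)
        _, r = fit_multicomponent([e1, e2], bold)
        r1 = abs(np.corrcoef(e1, bold)[0, 1])
        r2 = abs(np.corrcoef(e2, bold)[0, 1])
        assert r >= max(r1, r2) - 1e-12

    def test_collinear_regressor_dropped_with_warning(self, rng):
        e1 = rng.standard_normal(300)
        with pytest.warns(UserWarning):
            _, r = fit_multicomponent([e1, 2.0 * e1], e1)
        assert r > 0.999


def test_cpd_result_roundtrip(tmp_path, fixtures):
    res = cpd_als(fixtures["rank2"]["tensor"], rank=2, seed=0)
    write_cpd_result(res, tmp_path / "cpd")
    back = read_cpd_result(tmp_path / "cpd")
    assert back.rank == 2
    assert np.allclose(back.temporal, res.temporal, atol=1e-6)
    assert np.allclose(back.spectral, res.spectral, atol=1e-6)
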