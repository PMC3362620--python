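"""Band-power features, monopolar/ICA feature extraction, and CSP."""

import numpy as np
import pytest

from rest2task.features import (
    band_power,
    csp_features,
    csp_oracle,
    csp_train,
    ica_features,
    monopolar_features,
)

FS = 256.0


def _sine(freq, amp=1.0, dur=2.0, fs=FS):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def _orthonormal_rows(n_rows, n):
    """Zero-mean orthonormal rows (sin/cos at integer frequencies)."""
    t = np.arange(n)
    rows = []
    k = 1
    while len(rows) < n_rows:
        rows.append(np.sin(2 * np.pi * k * t / n))
        if len(rows) < n_rows:
            rows.append(np.cos(2 * np.pi * k * t / n))
        k += 1
    B = np.array(rows)
    return B / np.linalg.norm(B, axis=1, keepdims=True)


def _trials_with_cov(C, n=512):
    """Two identical trials whose exact sample covariance is C."""
    import scipy.linalg

    B = _orthonormal_rows(C.shape[0], n)
    X = scipy.linalg.sqrtm(C).real @ B
    return np.stack([X, X])


class TestBandPower:
    def test_parseval_on_bin_aligned_sinusoid(self):
        assert band_power(_sine(10.0), FS) == pytest.approx(0.5, abs=1e-9)

    def test_out_of_band_sinusoid(self):
        assert band_power(_sine(40.0), FS) == pytest.approx(0.0, abs=1e-9)

    def test_total_power_equals_mean_square(self, rng):
        x = rng.standard_normal(1024)
        total = band_power(x, FS, band=(0, FS / 2))
        assert total == pytest.approx(np.mean(x**2), rel=1e-12)

    def test_white_noise_band_fraction(self, rng):
        sigma = 1.7
        x = sigma * rng.standard_normal(int(480 * FS))
        expected = sigma**2 * (30.0 - 8.0) / (FS / 2)
        assert band_power(x, FS) == pytest.approx(expected, rel=0.10)

    def test_additive_over_disjoint_bands(self, rng):
        x = rng.standard_normal(2048)
        full = band_power(x, FS, band=(8, 30))
        parts = band_power(x, FS, band=(8, 15)) + band_power(x, FS, band=(15, 30))
        # the 15 Hz bin is counted twice when splitting on a shared edge
        overlap = band_power(x, FS, band=(15, 15.0001))
        assert full == pytest.approx(parts - overlap, rel=1e-9)

    def test_preconditions(self, rng):
        with pytest.raises(ValueError, match="0.5 s"):
            band_power(rng.standard_normal(10), FS)
        with pytest.raises(ValueError, match="band"):
            band_power(rng.standard_normal(1024), FS, band=(8, 200))


class TestMonopolarFeatures:
    def test_equals_direct_band_power_and_ignores_other_channels(self, rng):
        labels = ["Fz", "C3", "Cz", "C4", "Pz"]
        seg = rng.standard_normal((5, 512))
        fv = monopolar_features(seg, labels, FS)
        assert fv.left == pytest.approx(band_power(seg[1], FS))
        assert fv.right == pytest.approx(band_power(seg[3], FS))
        seg2 = seg.copy()
        seg2[[0, 2, 4]] = rng.standard_normal((3, 512))
        fv2 = monopolar_features(seg2, labels, FS)
        assert (fv2.left, fv2.right) == (fv.left, fv.right)

    def test_zero_signal(self):
        fv = monopolar_features(np.zeros((2, 512)), ["C3", "C4"], FS)
        assert fv.left == 0.0 and fv.right == 0.0

    def test_missing_electrode(self):
        with pytest.raises(KeyError, match="C3"):
            monopolar_features(np.zeros((2, 512)), ["Cz", "Pz"], FS)


class TestICAFeatures:
    def test_composition_and_quadratic_scaling(self, sim_subject, rest_decomposition):
        from rest2task.decomposition import apply_filters

        _, ts, _ = sim_subject
        dec, _ = rest_decomposition
        seg = ts.state_trials("imagery")[0]
        fv = ica_features(seg, dec, 0, 1, ts.fs)
        tc = apply_filters(dec, seg, [0, 1])
        assert fv.left == pytest.approx(band_power(tc.data[0], ts.fs))
        assert fv.right == pytest.approx(band_power(tc.data[1], ts.fs))
        # scaling a filter by c scales its feature by c^2
        import dataclasses

        dec2 = dataclasses.replace(dec, filters=dec.filters.copy())
        dec2.filters[0] *= 3.0
        fv2 = ica_features(seg, dec2, 0, 1, ts.fs)
        assert fv2.left == pytest.approx(9.0 * fv.left, rel=1e-9)

    def test_contralateral_erd_separates_classes(
        self, sim_subject, rest_decomposition, rest_selection
    ):
        """Left-hand imagery suppresses the right motor component in most
        trials (erd_depth -0.5)."""
        _, ts, _ = sim_subject
        dec, _ = rest_decomposition
        sel = rest_selection
        wins = 0
        left_trials = ts.state_trials("imagery")[ts.labels == "left"]
        for seg in left_trials:
            fv = ica_features(seg, dec, sel.selected_left, sel.selected_right, ts.fs)
            wins += fv.right < fv.left
        assert wins / len(left_trials) >= 0.8


class TestCSP:
    def test_analytic_two_channel_case(self):
        c1 = np.diag([2.0, 1.0])
        c2 = np.diag([1.0, 2.0])
        model = csp_train(_trials_with_cov(c1), _trials_with_cov(c2))
        wmax = model.w_max / np.abs(model.w_max).max()
        wmin = model.w_min / np.abs(model.w_min).max()
        assert abs(wmax[0]) == pytest.approx(1.0) and abs(wmax[1]) < 1e-8
        assert abs(wmin[1]) == pytest.approx(1.0) and abs(wmin[0]) < 1e-8

    def test_identical_covariances_degenerate(self, caplog):
        c = np.array([[2.0, 0.3], [0.3, 1.0]])
        with caplog.at_level("WARNING"):
            model = csp_train(_trials_with_cov(c), _trials_with_cov(c))
        assert np.allclose(model.eigenvalues, 0.5, atol=1e-10)
        assert any("degenerate" in r.message for r in caplog.records)

    def test_matches_generalized_eigenproblem_oracle(self, rng):
        for _ in range(5):
            A = rng.standard_normal((6, 6))
            B = rng.standard_normal((6, 6))
            c1 = A @ A.T + 1e-3 * np.eye(6)
            c2 = B @ B.T + 1e-3 * np.eye(6)
            c1 /= np.trace(c1)
            c2 /= np.trace(c2)
            model = csp_train(_trials_with_cov(c1, 1024), _trials_with_cov(c2, 1024))
            w_hi, w_lo = csp_oracle(c1, c2)
            for w, ref in ((model.w_max, w_hi), (model.w_min, w_lo)):
                r = abs(w @ ref) / (np.linalg.norm(w) * np.linalg.norm(ref))
                assert r == pytest.approx(1.0, abs=1e-6)

    def test_variance_ratio_optimality_against_random_directions(self, rng):
        A = rng.standard_normal((5, 5))
        B = rng.standard_normal((5, 5))
        c1 = A @ A.T + 1e-3 * np.eye(5)
        c2 = B @ B.T + 1e-3 * np.eye(5)
        model = csp_train(_trials_with_cov(c1 / np.trace(c1), 1024),
                          _trials_with_cov(c2 / np.trace(c2), 1024))
        best = (model.w_max @ c1 @ model.w_max) / (model.w_max @ c2 @ model.w_max)
        ws = rng.standard_normal((1000, 5))
        ratios = np.einsum("ij,jk,ik->i", ws, c1, ws) / np.einsum(
            "ij,jk,ik->i", ws, c2, ws)
        assert ratios.max() <= best * (1 + 1e-9)

    def test_simultaneous_diagonalization(self, rng):
        A = rng.standard_normal((4, 4))
        B = rng.standard_normal((4, 4))
        c1 = A @ A.T + 1e-2 * np.eye(4)
        c2 = B @ B.T + 1e-2 * np.eye(4)
        model = csp_train(_trials_with_cov(c1 / np.trace(c1), 1024),
                          _trials_with_cov(c2 / np.trace(c2), 1024))
        W = np.vstack([model.w_max, model.w_min])
        for c in (c1 / np.trace(c1), c2 / np.trace(c2)):
            proj = W @ c @ W.T
            assert abs(proj[0, 1]) < 1e-8 and abs(proj[1, 0]) < 1e-8

    def test_needs_two_trials_per_class(self):
        x = np.zeros((1, 2, 100))
        with pytest.raises(ValueError, match="2 trials"):
            csp_train(x, x)

    def test_csp_features_composition(self, rng):
        c1 = np.diag([2.0, 1.0])
        c2 = np.diag([1.0, 2.0])
        model = csp_train(_trials_with_cov(c1), _trials_with_cov(c2))
        seg = rng.standard_normal((2, 512))
        fv = csp_features(seg, model, FS)
        assert fv.left == pytest.approx(band_power(model.w_max @ seg, FS))
        assert fv.right == pytest.approx(band_power(model.w_min @ seg, FS))
        with pytest.raises(ValueError, match="channel"):
            csp_features(rng.standard_normal((3, 512)), model, FS)
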