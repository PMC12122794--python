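"""Feature-extraction tests: parcellation means, filtering, motion QC, ICA
recovery, sliding-window connectivity and the Fisher-z pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from impact.features import (AtlasLabelImage, BoldVolumeSeries, RoiTimeSeries,
                             build_subject_features, compute_dfc,
                             discard_initial_volumes, extract_roi_timeseries,
                             fisher_z, fit_ica_components, flatten_dfc,
                             frame_displacement_qc, harmonize_roi_count,
                             highpass_filter, sliding_windows, unflatten_dfc,
                             window_correlation, zscore_normalize)


def make_ts(values, tr=2.0, normalized=False):
    values = np.asarray(values, dtype=float)
    names = [f"r{i}" for i in range(values.shape[1])]
    return RoiTimeSeries(values, names, tr, normalized=normalized)


class TestDiscardAndQc:
    @pytest.mark.parametrize("t,k,expected", [(137, 5, 132), (239, 5, 234)])
    def test_scanner_stabilization_discard(self, t, k, expected):
        vol = BoldVolumeSeries(np.random.default_rng(0).standard_normal((2, 2, 2, t)),
                               2.0, np.eye(4))
        out = discard_initial_volumes(vol, k)
        assert out.data.shape[3] == expected
        np.testing.assert_array_equal(out.data, vol.data[..., k:])

    def test_zero_discard_is_identity_and_short_series_rejected(self):
        vol = BoldVolumeSeries(np.ones((1, 1, 1, 4)), 2.0, np.eye(4))
        assert discard_initial_volumes(vol, 0).data.shape[3] == 4
        with pytest.raises(ValueError, match="4"):
            discard_initial_volumes(vol, 5)

    def test_framewise_displacement_oracle(self):
        # constant 1 mm jump per frame in one translation axis
        motion = np.zeros((11, 6))
        motion[:, 0] = np.arange(11)
        mean_fd, keep = frame_displacement_qc(motion, threshold_mm=0.5)
        assert mean_fd == pytest.approx(1.0)
        assert not keep
        # hand-computed mixed case: backward differences, rotations on 50 mm sphere
        motion = np.zeros((3, 6))
        motion[1, 1] = 0.2            # +0.2 mm then back
        motion[2, 4] = 0.01           # +0.01 rad
        fd_expected = np.mean([0.2, 0.2 + 50 * 0.01])
        mean_fd, keep = frame_displacement_qc(motion)
        assert mean_fd == pytest.approx(fd_expected)
        assert keep

    def test_fd_edge_cases(self):
        assert frame_displacement_qc(np.zeros((5, 6))) == (0.0, True)
        big = np.cumsum(np.ones((5, 6)), axis=0)
        assert frame_displacement_qc(big, threshold_mm=np.inf)[1]
        with pytest.raises(ValueError, match="T x 6"):
            frame_displacement_qc(np.zeros((5, 4)))


class TestHighpass:
    def test_constant_column_removed(self):
        ts = make_ts(np.full((64, 2), 7.0))
        out = highpass_filter(ts, 100.0)
        assert np.max(np.abs(out.values)) < 1e-8

    def _sine_attenuation(self, period_s, tr=2.0, cutoff=100.0, T=600):
        t = np.arange(T) * tr
        x = np.sin(2 * np.pi * t / period_s)[:, None]
        out = highpass_filter(make_ts(x, tr), cutoff).values[:, 0]
        freqs = np.fft.rfftfreq(T, tr)
        k = np.argmin(np.abs(freqs - 1.0 / period_s))
        amp_in = np.abs(np.fft.rfft(x[:, 0]))[k]
        amp_out = np.abs(np.fft.rfft(out))[k]
        return amp_out / amp_in

    def test_passband_sine_preserved(self):
        assert self._sine_attenuation(10.0) == pytest.approx(1.0, abs=0.05)

    def test_slow_drift_attenuated(self):
        assert self._sine_attenuation(400.0) < 0.2

    def test_cutoff_below_resolvable_band_rejected(self):
        with pytest.raises(ValueError, match="resolvable"):
            highpass_filter(make_ts(np.zeros((64, 1))), cutoff_seconds=3.0)


class TestParcellation:
    def test_region_mean_is_arithmetic_mean(self):
        data = np.zeros((2, 1, 1, 3))
        data[0, 0, 0] = [1, 2, 3]
        data[1, 0, 0] = [3, 4, 5]
        atlas = AtlasLabelImage(np.array([[[1]], [[1]]]), ["a"])
        out = extract_roi_timeseries(BoldVolumeSeries(data, 2.0, np.eye(4)), atlas)
        np.testing.assert_array_equal(out.values[:, 0], [2, 3, 4])

    def test_voxel_order_irrelevant_and_empty_region_listed(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((4, 1, 1, 5))
        atlas = AtlasLabelImage(np.array([1, 1, 2, 2]).reshape(4, 1, 1), ["a", "b"])
        out1 = extract_roi_timeseries(BoldVolumeSeries(data, 2.0, np.eye(4)), atlas)
        out2 = extract_roi_timeseries(
            BoldVolumeSeries(data[[1, 0, 3, 2]], 2.0, np.eye(4)), atlas)
        np.testing.assert_array_equal(out1.values, out2.values)
        bad = AtlasLabelImage(np.array([1, 1, 1, 1]).reshape(4, 1, 1), ["a", "b"])
        with pytest.raises(ValueError, match=r"\[2\]"):
            extract_roi_timeseries(BoldVolumeSeries(data, 2.0, np.eye(4)), bad)

    def test_scaling_linearity(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((4, 2, 1, 6))
        atlas = AtlasLabelImage((np.arange(8).reshape(4, 2, 1) % 2) + 1, ["a", "b"])
        vol = BoldVolumeSeries(data, 2.0, np.eye(4))
        scaled = BoldVolumeSeries(3.0 * data, 2.0, np.eye(4))
        np.testing.assert_allclose(
            extract_roi_timeseries(scaled, atlas).values,
            3.0 * extract_roi_timeseries(vol, atlas).values, rtol=1e-12)


class TestZscore:
    def test_population_std_closed_form(self):
        out = zscore_normalize(make_ts([[0.0], [2.0]]))
        np.testing.assert_allclose(out.values[:, 0], [-1.0, 1.0])

    def test_constant_column_becomes_zeros(self):
        out = zscore_normalize(make_ts(np.full((5, 1), 3.0)))
        np.testing.assert_array_equal(out.values, np.zeros((5, 1)))

    def test_idempotent(self):
        x = np.random.default_rng(0).standard_normal((30, 4))
        once = zscore_normalize(make_ts(x)).values
        twice = zscore_normalize(make_ts(once)).values
        np.testing.assert_allclose(once, twice, atol=1e-10)


class TestIca:
    def test_recovers_independent_sources_from_noiseless_mixture(self):
        rng = np.random.default_rng(0)
        T, C, R = 400, 3, 10
        sources = np.column_stack([
            np.sign(np.sin(np.arange(T) * 0.7)),
            rng.uniform(-1, 1, T),
            np.sin(np.arange(T) * 0.13),
        ])
        mixing = rng.standard_normal((C, R))
        ts = make_ts(sources @ mixing)
        ica = fit_ica_components(ts, n_components=C, seed=0)
        # greedy matching by absolute correlation
        corr = np.abs(np.corrcoef(sources.T, ica.values.T)[:C, C:])
        matched = []
        used = set()
        for i in np.argsort(-corr.max(axis=1)):
            j = max((j for j in range(C) if j not in used),
                    key=lambda j: corr[i, j])
            used.add(j)
            matched.append(corr[i, j])
        assert min(matched) > 0.95

    def test_rank_one_data_single_component(self):
        rng = np.random.default_rng(1)
        latent = rng.standard_normal(200)
        ts = make_ts(np.outer(latent, rng.standard_normal(6)))
        ica = fit_ica_components(ts, n_components=1, seed=0)
        r = np.corrcoef(latent, ica.values[:, 0])[0, 1]
        assert abs(r) > 0.999

    def test_seeded_and_unit_variance_and_sign_convention(self):
        rng = np.random.default_rng(2)
        ts = make_ts(rng.standard_normal((100, 8)))
        a = fit_ica_components(ts, 4, seed=7)
        b = fit_ica_components(ts, 4, seed=7)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_allclose(a.values.std(axis=0), 1.0, atol=1e-8)
        for c in range(4):
            j = np.argmax(np.abs(a.mixing[:, c]))
            assert a.mixing[j, c] > 0

    def test_component_count_bounds(self):
        ts = make_ts(np.random.default_rng(0).standard_normal((20, 4)))
        with pytest.raises(ValueError, match="smaller"):
            fit_ica_components(ts, 4)


class TestSlidingWindows:
    @pytest.mark.parametrize("T,W,stride,starts", [
        (132, 50, 25, [0, 25, 50, 75]),
        (234, 50, 25, [0, 25, 50, 75, 100, 125, 150, 175]),
        (50, 50, 25, [0]),
    ])
    def test_window_starts_match_enumeration(self, T, W, stride, starts):
        wins = sliding_windows(T, W, stride)
        assert [s for s, _ in wins] == starts
        assert all(e - s == W for s, e in wins)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            sliding_windows(10, 20)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(2, 200), st.integers(2, 200), st.integers(1, 50))
    def test_count_formula_equals_brute_force(self, T, W, stride):
        brute = [s for s in range(T) if s % stride == 0 and s + W <= T]
        if T < W:
            with pytest.raises(ValueError):
                sliding_windows(T, W, stride)
        else:
            wins = sliding_windows(T, W, stride)
            assert len(wins) == len(brute) == (T - W) // stride + 1


class TestWindowCorrelation:
    def test_identical_and_negated_columns(self):
        x = np.random.default_rng(0).standard_normal(20)
        ts = make_ts(np.column_stack([x, x, -x]))
        c = window_correlation(ts, (0, 20))
        assert c[0, 1] == pytest.approx(1.0)
        assert c[0, 2] == pytest.approx(-1.0)
        np.testing.assert_array_equal(np.diag(c), np.ones(3))

    def test_matches_definitional_pearson(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((50, 4))
        c = window_correlation(make_ts(x), (0, 50))
        # oracle: definitional covariance / std computation
        xc = x - x.mean(axis=0)
        oracle = (xc.T @ xc / 49) / np.outer(x.std(axis=0, ddof=1),
                                             x.std(axis=0, ddof=1))
        np.testing.assert_allclose(c, oracle, atol=1e-12)

    def test_affine_invariance_positive_scale(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((40, 5))
        a = window_correlation(make_ts(x), (5, 40))
        b = window_correlation(make_ts(x * 3.7 + 11.0), (5, 40))
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_zero_variance_column_zeroed(self):
        x = np.random.default_rng(5).standard_normal((20, 3))
        x[:, 1] = 2.0
        c = window_correlation(make_ts(x), (0, 20))
        assert np.all(c[1, [0, 2]] == 0) and np.all(c[[0, 2], 1] == 0)
        assert c[1, 1] == 1.0

    def test_minimum_window_length(self):
        with pytest.raises(ValueError, match="3"):
            window_correlation(make_ts(np.zeros((10, 2))), (0, 2))


class TestFisherZ:
    def test_closed_forms(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5 * np.log(3.0), abs=1e-12)

    def test_clamp_keeps_unit_correlation_finite(self):
        z = fisher_z(1.0)
        assert np.isfinite(z)
        assert z == pytest.approx(np.arctanh(1 - 1e-7))

    def test_odd_and_increasing(self):
        r = np.linspace(-0.99, 0.99, 21)
        z = fisher_z(r)
        np.testing.assert_allclose(z, -fisher_z(-r), atol=1e-14)
        assert np.all(np.diff(z) > 0)

    def test_tanh_inverse_identity(self):
        z = np.linspace(-7.9, 7.9, 41)
        np.testing.assert_allclose(fisher_z(np.tanh(z)), z, atol=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="<= 1"):
            fisher_z(1.01)


class TestFlattenDfc:
    def test_pair_ordering_contract(self):
        Z = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        seq = flatten_dfc([Z], [0], 10, 5)
        np.testing.assert_array_equal(seq.vectors[0], [1.0, 2.0, 3.0])

    def test_vector_length_48_regions(self):
        Z = np.zeros((48, 48))
        seq = flatten_dfc([Z], [0], 50, 25)
        n_pairs = sum(1 for i in range(48) for j in range(48) if i < j)
        assert seq.vectors.shape[1] == n_pairs == 1128

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        Z = rng.standard_normal((5, 5))
        Z = Z + Z.T
        np.fill_diagonal(Z, 0.0)
        seq = flatten_dfc([Z], [0], 10, 5)
        np.testing.assert_array_equal(unflatten_dfc(seq.vectors[0], 5), Z)

    def test_asymmetry_rejected(self):
        Z = np.zeros((3, 3))
        Z[0, 1] = 1e-6
        with pytest.raises(ValueError, match="symmetric"):
            flatten_dfc([Z], [0], 10, 5)

    def test_dfc_always_finite(self):
        # two identical columns give r = 1; the clamp keeps z finite
        x = np.random.default_rng(1).standard_normal(60)
        ts = make_ts(np.column_stack([x, x, -x]))
        seq = compute_dfc(ts, W=20, stride=10)
        assert np.all(np.isfinite(seq.vectors))


class TestPipeline:
    @pytest.mark.parametrize("t,exp_T,exp_windows", [(137, 132, 4), (239, 234, 8)])
    def test_documented_cohort_shapes(self, t, exp_T, exp_windows):
        rng = np.random.default_rng(0)
        roi = make_ts(rng.standard_normal((t - 5, 48)), tr=2.0)
        feats = build_subject_features(roi, subject_id="s", n_ica=5,
                                       window_width=50, stride=25, seed=0)
        assert feats.roi.values.shape == (exp_T, 48)
        assert feats.dfc.vectors.shape == (exp_windows, 1128)
        assert feats.ica.values.shape == (exp_T, 5)

    def test_harmonize_to_45_regions(self):
        rng = np.random.default_rng(1)
        roi = make_ts(rng.standard_normal((132, 48)))
        feats = build_subject_features(roi, subject_id="s", n_ica=5,
                                       window_width=50, stride=25, seed=0)
        out = harmonize_roi_count(feats, 45)
        assert out.roi.values.shape == (132, 45)
        assert out.dfc.vectors.shape[1] == 45 * 44 // 2 == 990
        assert out.roi.region_names == feats.roi.region_names[:45]
        assert out.ica.values.shape == feats.ica.values.shape
        # identity when keeping everything
        assert harmonize_roi_count(feats, 48) is feats

    def test_roi_matrix_entry_point_skips_parcellation(self):
        roi = make_ts(np.random.default_rng(2).standard_normal((80, 6)))
        feats = build_subject_features(roi, subject_id="x", n_ica=3,
                                       window_width=40, stride=20, seed=0)
        assert feats.dfc.vectors.shape == (3, 15)

    def test_deterministic_given_seed(self):
        roi = make_ts(np.random.default_rng(3).standard_normal((80, 6)))
        a = build_subject_features(roi, subject_id="x", n_ica=3,
                                   window_width=40, stride=20, seed=5)
        b = build_subject_features(roi, subject_id="x", n_ica=3,
                                   window_width=40, stride=20, seed=5)
        np.testing.assert_array_equal(a.ica.values, b.ica.values)
        np.testing.assert_array_equal(a.dfc.vectors, b.dfc.vectors)
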