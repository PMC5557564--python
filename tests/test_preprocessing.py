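import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from semgbench.errors import (ConfigurationError, DegenerateChannelError,
                              StratificationError)
from semgbench.preprocessing import (FeatureWindowConfig, SplitConfig,
                                     downsample_split, extract_td_features,
                                     scale_channels, stratified_split_70_30,
                                     td_feature_columns)
from semgbench.synthetic import RecordingSession


def session_from(signal, labels, rep=None, fs=1000.0):
    signal = np.asarray(signal, float)
    labels = np.asarray(labels, np.int64)
    if rep is None:
        rep = np.zeros(len(labels), np.int64)
    names = tuple(f"g{i}" for i in range(int(labels.max()) + 1))
    return RecordingSession(signal=signal, labels=labels,
                            rep_index=np.asarray(rep, np.int64),
                            sampling_rate=fs, gesture_names=names)


class TestScaling:
    def test_symmetric_example(self):
        x = np.arange(5.0)[:, None]  # mean 2, range 4
        out, params = scale_channels(x)
        np.testing.assert_allclose(out[:, 0], [-0.5, -0.25, 0.0, 0.25, 0.5])
        assert params.mean[0] == 2.0 and params.range[0] == 4.0

    def test_constant_channel_rejected(self):
        x = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.raises(DegenerateChannelError):
            scale_channels(x)

    def test_scaled_columns_have_unit_range_zero_mean(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(100, 6))
        out, _ = scale_channels(x)
        np.testing.assert_allclose(out.max(0) - out.min(0), 1.0, atol=1e-12)
        np.testing.assert_allclose(out.mean(0), 0.0, atol=1e-12)

    def test_fitted_params_apply_exactly_to_new_data(self):
        rng = np.random.default_rng(1)
        train, other = rng.normal(size=(50, 3)), rng.normal(size=(20, 3))
        _, params = scale_channels(train)
        out, returned = scale_channels(other, params)
        assert returned is params
        np.testing.assert_array_equal(out, (other - params.mean) / params.range)


class TestDownsampleSplit:
    def make_session(self, n, n_classes=5):
        rng = np.random.default_rng(0)
        labels = np.repeat(np.arange(n_classes), n // n_classes)
        return session_from(rng.normal(size=(n, 6)), labels)

    @pytest.mark.parametrize("n,step,expected", [
        (1000, 10, (60, 20, 20, 900)),
        (1000, 1, (600, 200, 200, 0)),
        (100, 10, (6, 2, 2, 90)),
    ])
    def test_split_proportions(self, n, step, expected):
        split = downsample_split(self.make_session(n),
                                 SplitConfig(downsample_step=step, seed=1))
        sizes = tuple(len(s.y) for s in (split.TR, split.CV, split.TS, split.GS))
        assert sizes == expected

    @pytest.mark.parametrize("n,step,seed", [
        (500, 3, 0), (1000, 7, 1), (750, 10, 2), (600, 1, 3),
    ])
    def test_disjoint_and_exhaustive(self, n, step, seed):
        split = downsample_split(self.make_session(n),
                                 SplitConfig(downsample_step=step, seed=seed))
        idx = [s.indices for s in (split.TR, split.CV, split.TS, split.GS)]
        combined = np.concatenate(idx)
        assert len(combined) == n
        assert len(np.unique(combined)) == n  # pairwise disjoint + exhaustive
        pool = np.arange(0, n, step)
        np.testing.assert_array_equal(
            np.sort(np.concatenate(idx[:3])), pool)

    def test_per_class_balance_within_tolerance(self):
        split = downsample_split(self.make_session(1000),
                                 SplitConfig(downsample_step=10, seed=4))
        for subset, frac in ((split.TR, 0.6), (split.CV, 0.2), (split.TS, 0.2)):
            counts = np.bincount(subset.y, minlength=5)
            assert np.all(np.abs(counts - frac * 20) <= 1)

    def test_missing_class_in_pool_raises(self):
        # class 1 occupies only odd rows, step 2 keeps only even rows
        labels = np.arange(100) % 2
        sess = session_from(np.random.default_rng(0).normal(size=(100, 2)), labels)
        with pytest.raises(StratificationError):
            downsample_split(sess, SplitConfig(downsample_step=2, seed=0))

    def test_gs_scaled_with_pool_params(self):
        sess = self.make_session(1000)
        split = downsample_split(sess, SplitConfig(downsample_step=10, seed=5))
        expected = (sess.signal[split.GS.indices] - split.scaling.mean) / split.scaling.range
        np.testing.assert_array_equal(split.GS.X, expected)


class TestStratified7030:
    def test_exact_proportionality(self):
        y = np.repeat(np.arange(5), 20)
        X = np.random.default_rng(0).normal(size=(100, 3))
        tr, ts = stratified_split_70_30(X, y, seed=0)
        assert len(tr.y) == 70 and len(ts.y) == 30
        assert np.all(np.bincount(tr.y) == 14)
        assert np.all(np.bincount(ts.y) == 6)

    def test_seeding_contract(self):
        y = np.repeat(np.arange(2), 10)
        X = np.random.default_rng(1).normal(size=(20, 2))
        a1, _ = stratified_split_70_30(X, y, seed=5)
        a2, _ = stratified_split_70_30(X, y, seed=5)
        b, _ = stratified_split_70_30(X, y, seed=6)
        np.testing.assert_array_equal(a1.indices, a2.indices)
        assert not np.array_equal(a1.indices, b.indices)

    def test_small_split_sizes(self):
        y = np.repeat(np.arange(2), 5)
        X = np.random.default_rng(2).normal(size=(10, 2))
        tr, ts = stratified_split_70_30(X, y, seed=1)
        assert (len(tr.y), len(ts.y)) == (7, 3)
        # valid allocation: per class 3 or 4 in TR
        assert set(np.bincount(tr.y)) <= {3, 4}

    def test_too_few_samples_per_class(self):
        with pytest.raises(StratificationError):
            stratified_split_70_30(np.zeros((3, 2)), np.array([0, 0, 1]), seed=0)


class TestTDFeatures:
    def test_constant_window_closed_forms(self):
        c = 1.7
        sess = session_from(np.full((250, 1), c), np.zeros(250))
        feats, labels = extract_td_features(sess, FeatureWindowConfig())
        assert feats.shape == (1, 5)
        mav, rms, ssc, wl, var = feats[0]
        assert mav == pytest.approx(c) and rms == pytest.approx(c)
        assert ssc == 0 and wl == 0
        assert var == pytest.approx(0.0, abs=1e-24)

    def test_window_count_on_protocol_segment(self):
        # one 2000-sample segment @1 kHz, 250 ms windows, 200 ms overlap
        sess = session_from(np.random.default_rng(0).normal(size=(2000, 1)),
                            np.zeros(2000))
        feats, _ = extract_td_features(sess)
        assert feats.shape[0] == (2000 - 250) // 50 + 1 == 36

    def test_monotone_ramp(self):
        ramp = np.linspace(0.0, 1.0, 250)
        sess = session_from(ramp[:, None], np.zeros(250))
        feats, _ = extract_td_features(sess)
        _, _, ssc, wl, _ = feats[0]
        assert ssc == 0
        assert wl == pytest.approx(ramp[-1] - ramp[0])

    def test_feature_count_and_labels(self, small_config, small_profile):
        from semgbench.synthetic import generate_session
        sess = generate_session(small_config, small_profile, seed=9)
        cfgw = FeatureWindowConfig(window_length_ms=50, overlap_ms=25)
        feats, labels = extract_td_features(sess, cfgw)
        assert feats.shape[1] == 5 * small_config.n_channels
        assert set(np.unique(labels)) == set(range(small_config.n_classes))
        assert len(td_feature_columns(6)) == 30

    def test_windows_do_not_straddle_labels(self):
        # 300+300 samples of two classes; a 250 ms window fits once per segment
        sig = np.concatenate([np.zeros(300), np.ones(300)])[:, None]
        labels = np.concatenate([np.zeros(300), np.ones(300)])
        feats, wl = extract_td_features(session_from(sig, labels))
        assert np.all(feats[wl == 0][:, 3] == 0)  # WL zero within pure segments
        assert np.all(feats[wl == 1][:, 3] == 0)

    def test_short_segment_warns_and_skips(self):
        sig = np.random.default_rng(0).normal(size=(100, 1))
        sess = session_from(sig, np.zeros(100))
        with pytest.warns(UserWarning, match="skipped"):
            feats, _ = extract_td_features(sess, FeatureWindowConfig())
        assert feats.shape[0] == 0

    def test_invalid_overlap(self):
        with pytest.raises(ConfigurationError):
            FeatureWindowConfig(window_length_ms=100, overlap_ms=100)


@settings(max_examples=25, derandomize=True)
@given(st.integers(2, 6), st.integers(1, 4))
def test_scaling_roundtrip_property(n_channels, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(40, n_channels))
    out, params = scale_channels(x)
    reconstructed = out * params.range + params.mean
    np.testing.assert_allclose(reconstructed, x, atol=1e-12)
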