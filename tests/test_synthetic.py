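import numpy as np
import pytest

from semgbench.errors import ConfigurationError, SessionParseError
from semgbench.synthetic import (AcquisitionConfig, GestureProfile,
                                 default_profile, generate_session,
                                 read_session, write_session)


@pytest.mark.parametrize("n_classes,reps,duration,rate,channels", [
    (5, 2, 0.1, 1000, 6),
    (3, 1, 0.05, 500, 2),
    (2, 4, 0.2, 100, 1),
])
def test_sample_count_arithmetic(n_classes, reps, duration, rate, channels):
    cfg = AcquisitionConfig(n_channels=channels, sampling_rate=rate,
                            duration_per_rep=duration, reps_per_gesture=reps,
                            gesture_names=tuple(f"g{i}" for i in range(n_classes)))
    prof = GestureProfile(
        mean_activation=np.linspace(0.5, 3.0, n_classes)[:, None]
        * np.ones((n_classes, channels)))
    sess = generate_session(cfg, prof, seed=0)
    expected = n_classes * reps * int(round(duration * rate))
    assert sess.signal.shape == (expected, channels)
    assert sess.labels.shape == (expected,)
    # each (class, rep) block is contiguous with the right length
    block = int(round(duration * rate))
    for g in range(n_classes):
        assert np.sum(sess.labels == g) == reps * block


def test_zero_noise_reproduces_class_means(small_config):
    prof = default_profile(noise_sd=0.0, within_rep_jitter=0.0)
    sess = generate_session(small_config, prof, seed=1)
    for g in range(small_config.n_classes):
        block = sess.signal[sess.labels == g]
        assert np.allclose(block, prof.mean_activation[g][None, :])


def test_seeding_contract(small_config, small_profile):
    a = generate_session(small_config, small_profile, seed=1)
    b = generate_session(small_config, small_profile, seed=1)
    c = generate_session(small_config, small_profile, seed=2)
    np.testing.assert_array_equal(a.signal, b.signal)
    assert not np.array_equal(a.signal, c.signal)


def test_signal_stays_in_voltage_range(small_config):
    prof = default_profile(noise_sd=2.0)  # strong noise forces clipping
    sess = generate_session(small_config, prof, seed=3)
    lo, hi = small_config.voltage_range
    assert sess.signal.min() >= lo and sess.signal.max() <= hi


def test_class_means_converge_with_small_noise():
    cfg = AcquisitionConfig(reps_per_gesture=4, duration_per_rep=0.5)
    sd = 0.02
    prof = default_profile(noise_sd=sd, within_rep_jitter=0.0)
    sess = generate_session(cfg, prof, seed=7)
    n = np.sum(sess.labels == 0)
    tol = 6 * sd / np.sqrt(n) + 1e-9
    # low-pass shaping correlates samples, so allow a wide correlation factor
    tol *= np.sqrt(cfg.sampling_rate / prof.noise_bandwidth)
    for g in range(cfg.n_classes):
        emp = sess.signal[sess.labels == g].mean(axis=0)
        assert np.all(np.abs(emp - prof.mean_activation[g]) < tol)


def test_separability_scales_class_distances():
    def min_pairwise(sep):
        means = default_profile(separability=sep).effective_means()
        d = [np.linalg.norm(means[i] - means[j])
             for i in range(len(means)) for j in range(i + 1, len(means))]
        return min(d)

    dists = [min_pairwise(s) for s in (0.5, 1.0, 1.5, 2.0)]
    assert all(a < b for a, b in zip(dists, dists[1:]))


def test_profile_config_dimension_mismatch(small_config):
    prof = GestureProfile(mean_activation=np.ones((3, 4)))
    with pytest.raises(ConfigurationError):
        generate_session(small_config, prof, seed=0)


def test_default_session_shape(default_session):
    # full protocol: 5 gestures x 10 reps x 2000 samples on 6 channels
    assert default_session.signal.shape == (100000, 6)


class TestSessionIO:
    def test_round_trip(self, small_config, small_profile, tmp_path):
        sess = generate_session(small_config, small_profile, seed=5)
        path = tmp_path / "session.csv"
        write_session(path, sess)
        back = read_session(path)
        np.testing.assert_allclose(back.signal, sess.signal, atol=5e-7)
        np.testing.assert_array_equal(back.labels, sess.labels)
        np.testing.assert_array_equal(back.rep_index, sess.rep_index)
        assert back.sampling_rate == sess.sampling_rate
        assert back.gesture_names == sess.gesture_names

    def test_missing_label_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("ch1,ch2\n0.1,0.2\n")
        with pytest.raises(SessionParseError, match="label"):
            read_session(path)

    def test_non_numeric_channel_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("ch1,label\n0.1,0\nxyz,1\n")
        with pytest.raises(SessionParseError, match="ch1"):
            read_session(path)

    def test_handcrafted_csv(self, tmp_path):
        path = tmp_path / "hand.csv"
        rows = "\n".join(
            f"{0.1 * i:.6f},{0.2:.6f},{0.3:.6f},{0.4:.6f},{0.5:.6f},{0.6:.6f},{i % 2},0"
            for i in range(10))
        path.write_text("ch1,ch2,ch3,ch4,ch5,ch6,label,rep\n" + rows + "\n")
        sess = read_session(path)
        assert sess.signal.shape == (10, 6)
        np.testing.assert_array_equal(sess.labels, np.arange(10) % 2)
        np.testing.assert_allclose(sess.signal[:, 0], 0.1 * np.arange(10),
                                   atol=1e-9)
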