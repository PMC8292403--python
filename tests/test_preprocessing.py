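import numpy as np
import pytest
from hypothesis import given, strategies as st

from gravisyn import preprocessing as pp
from gravisyn import synthetic
from gravisyn.errors import (
    DegenerateChannelError,
    InsufficientDataError,
    InvalidArgumentError,
)


def _rec(x, fs=1000.0, labels=None):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    labels = labels or tuple(f"m{i}" for i in range(x.shape[0]))
    return pp.RawRecording(emg=x, fs=fs, muscle_labels=labels)


class TestConditionEmg:
    def test_zero_in_zero_out(self):
        env = pp.condition_emg(_rec(np.zeros((2, 4000))))
        assert np.all(env == 0)

    def test_dc_removed(self):
        env = pp.condition_emg(_rec(np.full((1, 8000), 3.7)))
        assert np.max(np.abs(env[0, 1000:-1000])) < 1e-6

    def test_sinusoid_envelope_is_rectified_mean(self):
        # oracle: rectified unit sine has mean 2/pi after low-pass
        fs = 1000.0
        t = np.arange(int(5 * fs)) / fs
        env = pp.condition_emg(_rec(np.sin(2 * np.pi * 150 * t), fs=fs))
        mid = env[0, int(fs):-int(fs)]
        assert abs(mid.mean() - 2 / np.pi) / (2 / np.pi) < 0.05

    def test_fs_too_low(self):
        with pytest.raises(InvalidArgumentError):
            pp.condition_emg(_rec(np.zeros((1, 1000)), fs=200.0))

    def test_nonfinite_rejected(self):
        x = np.zeros((1, 2000))
        x[0, 5] = np.nan
        with pytest.raises(InvalidArgumentError):
            pp.condition_emg(_rec(x))

    def test_nonnegative(self, rng):
        env = pp.condition_emg(_rec(rng.standard_normal((3, 5000))))
        assert np.all(env >= 0)


class TestFootContacts:
    def test_sine_maxima(self):
        t = np.arange(300) / 100.0
        events = pp.detect_contacts_from_angle(np.sin(2 * np.pi * t), fs=100.0)
        np.testing.assert_array_equal(events.contact_samples, [25, 125, 225])

    def test_constant_angle_insufficient(self):
        with pytest.raises(InsufficientDataError):
            pp.detect_contacts_from_angle(np.ones(1000), fs=100.0)

    def test_elevation_angle_roundtrip(self):
        # place the distal landmark on a circle around the proximal one
        theta = np.linspace(-30, 30, 500)
        L = 0.8
        gt_xy = np.zeros((500, 2))
        lm_xy = np.column_stack(
            [L * np.sin(np.radians(theta)), -L * np.cos(np.radians(theta))]
        )
        track = pp.LimbAxisTrack(gt_xy=gt_xy, lm_xy=lm_xy, fs=100.0)
        np.testing.assert_allclose(pp.elevation_angle(track), theta, atol=1e-9)

    def test_synthetic_trial_contacts(self, default_gt):
        trial = synthetic.generate_raw_trial(default_gt, 0, "1g", seed=2)
        events = pp.detect_contacts_from_angle(trial.limb_angle, trial.fs)
        assert events.contact_samples.size == trial.contact_samples_true.size
        assert np.max(np.abs(events.contact_samples - trial.contact_samples_true)) <= 5


class TestSegmentAndNormalize:
    def _events(self, n_contacts, spacing=1000):
        return pp.GaitEvents(contact_samples=np.arange(n_contacts) * spacing)

    def test_constant_envelope(self):
        env = np.full((1, 13000), 2.5)
        stack, mean, used = pp.segment_and_normalize(env, self._events(13))
        assert np.allclose(mean, 2.5)
        assert stack.shape == (10, 1, 200)

    def test_linear_envelope_linear_bins(self):
        # closed form: envelope(t)=t, bin j of cycle k = c_k + j/200 * spc
        env = np.arange(13000, dtype=float)[None, :]
        _, mean, used = pp.segment_and_normalize(env, self._events(13))
        starts = np.array([1000 * (k) for k in used], dtype=float)
        expected = starts.mean() + np.arange(200) / 200.0 * 1000.0
        np.testing.assert_allclose(mean[0], expected, atol=1e-9)

    def test_too_few_cycles(self):
        env = np.zeros((1, 10000))
        with pytest.raises(InsufficientDataError):
            pp.segment_and_normalize(env, self._events(10), n_cycles=10)


class TestNormalizeAmplitude:
    def _cm(self, values, cond="c1"):
        values = np.atleast_2d(np.asarray(values, dtype=float))
        return pp.CycleMatrix(
            values=values,
            muscle_labels=tuple(f"m{i}" for i in range(values.shape[0])),
            condition=cond,
        )

    def test_single_trace(self):
        out = pp.normalize_amplitude({"c1": self._cm([[2, 4, 6]])})
        np.testing.assert_allclose(out["c1"].values, [[0, 0.5, 1]])

    def test_max_across_conditions(self):
        out = pp.normalize_amplitude({
            "c1": self._cm([[0, 1]], "c1"),
            "c2": self._cm([[0, 2]], "c2"),
        })
        assert out["c1"].values[0, 1] == pytest.approx(0.5)
        assert out["c2"].values[0, 1] == pytest.approx(1.0)

    def test_constant_muscle_degenerate(self):
        with pytest.raises(DegenerateChannelError, match="m1"):
            pp.normalize_amplitude({"c1": self._cm([[0, 1], [3, 3]])})

    def test_idempotent(self, rng):
        mats = {
            c: self._cm(rng.uniform(0, 5, (3, 200)), c) for c in ("a", "b", "c")
        }
        once = pp.normalize_amplitude(mats)
        twice = pp.normalize_amplitude(once)
        for c in mats:
            np.testing.assert_allclose(twice[c].values, once[c].values, atol=1e-12)


class TestUnitVariance:
    def test_unit_variance(self):
        m = pp.CycleMatrix(values=np.tile([0.0, 1.0], 100)[None, :], muscle_labels=("a",))
        scaled, sd = pp.scale_unit_variance(m)
        assert scaled.values[0].std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_roundtrip(self, rng):
        m = pp.CycleMatrix(
            values=rng.uniform(0, 3, (4, 200)),
            muscle_labels=tuple("abcd"),
        )
        scaled, sd = pp.scale_unit_variance(m)
        back = pp.unscale_unit_variance(scaled, sd)
        np.testing.assert_allclose(back.values, m.values, rtol=1e-12)

    def test_zero_row_rejected(self):
        m = pp.CycleMatrix(values=np.zeros((1, 200)), muscle_labels=("a",))
        with pytest.raises(DegenerateChannelError):
            pp.scale_unit_variance(m)


class TestFroude:
    # printed mean speeds per gravity ratio (km/h, reference 5.05 at 1 g)
    TABLE = [(0.6, 3.91), (0.38, 3.11), (0.16, 2.02), (0.07, 1.34)]

    @pytest.mark.parametrize("ratio,expected", TABLE)
    def test_table_speeds(self, ratio, expected):
        v = pp.speed_at_gravity_ratio(5.05, ratio)
        assert pp.round_kmh(v) == expected

    def test_ratio_one_unchanged(self):
        assert pp.speed_at_gravity_ratio(5.05, 1.0) == pytest.approx(5.05)

    def test_inverse(self):
        v = pp.froude_speed(L=0.8, g_eff=9.81, Fr=0.25)
        assert pp.fr_number(v, 9.81, 0.8) == pytest.approx(0.25, abs=1e-12)

    @given(
        g=st.floats(0.5, 15.0),
        L=st.floats(0.5, 1.2),
        r=st.floats(0.01, 1.0),
    )
    def test_sqrt_scaling_law(self, g, L, r):
        v1 = pp.froude_speed(L, g)
        v2 = pp.froude_speed(L, r * g)
        assert v2 / v1 == pytest.approx(np.sqrt(r), rel=1e-12)

    def test_invalid_args(self):
        with pytest.raises(InvalidArgumentError):
            pp.froude_speed(-1.0, 9.81)
        with pytest.raises(InvalidArgumentError):
            pp.fr_number(1.0, 0.0, 0.8)


class TestNetLoad:
    def test_fr_quarter(self):
        v = pp.froude_speed(L=0.8, g_eff=9.81, Fr=0.25)
        p = pp.ProtocolParams(m=70.0, L=0.8, g_eff=9.81, v=v)
        assert pp.net_load_proxy(p) == pytest.approx(0.75 * 70.0 * 9.81, rel=1e-12)

    def test_zero_at_fr_one(self):
        v = np.sqrt(9.81 * 0.8)
        p = pp.ProtocolParams(m=70.0, L=0.8, g_eff=9.81, v=v)
        assert pp.net_load_proxy(p) == pytest.approx(0.0, abs=1e-9)

    def test_hand_evaluation(self):
        # 64.4 * (9.81 - 1.403^2 / 0.80) = 473.307...
        p = pp.ProtocolParams(m=64.4, L=0.80, g_eff=9.81, v=1.403)
        assert pp.net_load_proxy(p) == pytest.approx(473.307, abs=0.01)


def test_read_emg_csv_with_fs_comment(tmp_path):
    path = tmp_path / "emg.csv"
    path.write_text("# fs=1000\ntime,MG,LG\n0.0,0.1,0.2\n0.001,0.3,0.4\n")
    rec = pp.read_emg_csv(path)
    assert rec.fs == 1000
    assert rec.muscle_labels == ("MG", "LG")
    np.testing.assert_allclose(rec.emg, [[0.1, 0.3], [0.2, 0.4]])
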