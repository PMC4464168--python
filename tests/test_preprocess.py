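import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import b2t
from b2t.io_session import PipelineConfig, RawRecording, SegmentLabel, ValidationError
from b2t.preprocess import (
    _channel_band_energy,
    align_labels_to_frames,
    car_reference,
    detrend_downsample,
    frame_log_energy,
    gamma_band_filter,
    remove_noisy_channels,
    stack_context,
)


def _sine(freq, rate, dur, amp=1.0):
    t = np.arange(int(rate * dur)) / rate
    return amp * np.sin(2 * np.pi * freq * t)


def _rms(x):
    return float(np.sqrt(np.mean(x**2)))


class TestChannelRejection:
    def test_planted_line_noise_channels_removed_exactly(self):
        rng = np.random.default_rng(42)
        rate, dur = 600.0, 10.0
        n = int(rate * dur)
        signal = rng.normal(size=(10, n))
        for c in (2, 7):
            signal[c] += _sine(60.0, rate, dur, amp=20.0)
        rec = RawRecording(signal, rate, [f"ch{i}" for i in range(10)])
        cfg = PipelineConfig()
        out, removed = remove_noisy_channels(rec, cfg)
        assert removed == ["ch2", "ch7"]
        assert out.channel_names == [f"ch{i}" for i in range(10) if i not in (2, 7)]
        # cross-check with a direct band-energy computation
        energy = _channel_band_energy(rec, 58.0, 62.0, cfg)
        q1, q3 = np.percentile(energy, [25, 75])
        assert set(np.nonzero(energy > q3 + 2 * (q3 - q1))[0]) == {2, 7}

    def test_identical_channels_none_removed(self):
        rng = np.random.default_rng(1)
        row = rng.normal(size=3000)
        rec = RawRecording(np.tile(row, (6, 1)), 600.0, [f"c{i}" for i in range(6)])
        _, removed = remove_noisy_channels(rec, PipelineConfig())
        assert removed == []

    def test_fewer_than_four_channels_error(self):
        rec = RawRecording(np.random.default_rng(0).normal(size=(3, 3000)), 600.0, ["a", "b", "c"])
        with pytest.raises(ValidationError, match="4 channels"):
            remove_noisy_channels(rec, PipelineConfig())

    def test_survivor_order_preserved(self):
        rng = np.random.default_rng(5)
        signal = rng.normal(size=(8, 6000))
        signal[0] += _sine(60.0, 600.0, 10.0, amp=25.0)
        rec = RawRecording(signal, 600.0, [f"e{i}" for i in range(8)])
        out, removed = remove_noisy_channels(rec, PipelineConfig())
        assert removed == ["e0"]
        assert out.channel_names == [f"e{i}" for i in range(1, 8)]


class TestDetrendDownsample:
    def test_ramp_annihilated(self):
        ramp = np.linspace(0.0, 1000.0, 9600)[None, :]
        rec = RawRecording(ramp, 9600.0, ["a"])
        out = detrend_downsample(rec, 600.0)
        assert np.max(np.abs(out.signal)) < 1e-6 * 1000.0

    def test_9600_to_600_lengths(self):
        rec = RawRecording(np.random.default_rng(0).normal(size=(2, 9600)), 9600.0, ["a", "b"])
        out = detrend_downsample(rec, 600.0)
        assert out.n_samples == 600 and out.sampling_rate == 600.0

    def test_sine_preserved_below_cutoff(self):
        x = _sine(50.0, 9600.0, 4.0)
        rec = RawRecording(x[None, :], 9600.0, ["a"])
        out = detrend_downsample(rec, 600.0)
        expect = _sine(50.0, 600.0, 4.0)
        mid = slice(200, -200)  # avoid filter edge effects
        assert abs(_rms(out.signal[0, mid]) - _rms(expect[mid])) < 0.01 * _rms(expect[mid])

    def test_non_integer_ratio_rejected(self):
        rec = RawRecording(np.zeros((1, 100)) + 1.0, 1000.0, ["a"])
        with pytest.raises(ValidationError, match="divide"):
            detrend_downsample(rec, 600.0)


class TestCommonAverageReference:
    def test_antisymmetric_pair_unchanged(self):
        x = np.random.default_rng(0).normal(size=600)
        rec = RawRecording(np.vstack([x, -x]), 600.0, ["a", "b"])
        out = car_reference(rec)
        assert np.allclose(out.signal, rec.signal)

    def test_column_means_zero(self):
        rec = RawRecording(np.random.default_rng(1).normal(size=(5, 400)), 600.0, list("abcde"))
        out = car_reference(rec)
        assert np.max(np.abs(out.signal.mean(axis=0))) < 1e-10 * np.abs(out.signal).max()

    def test_common_offset_removed_exactly(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(4, 300))
        centered = base - base.mean(axis=0, keepdims=True)
        rec = RawRecording(centered + 5.0, 600.0, list("abcd"))
        out = car_reference(rec)
        assert np.allclose(out.signal, centered, atol=1e-12)

    def test_single_channel_error(self):
        with pytest.raises(ValidationError):
            car_reference(RawRecording(np.ones((1, 10)), 600.0, ["a"]))


class TestGammaBandFilter:
    rate = 600.0

    def _response_rms(self, freq):
        rec = RawRecording(_sine(freq, self.rate, 10.0)[None, :], self.rate, ["a"])
        out = gamma_band_filter(rec, PipelineConfig())
        steady = out.signal[0, out.n_samples // 2 :]
        return _rms(steady) / _rms(_sine(freq, self.rate, 10.0))

    def test_passband_100hz(self):
        assert abs(self._response_rms(100.0) - 1.0) < 0.12

    def test_notch_kills_120hz(self):
        assert self._response_rms(120.0) <= 0.01

    def test_stopband_30hz(self):
        assert self._response_rms(30.0) <= 0.01

    def test_stopband_above_band(self):
        assert self._response_rms(200.0) <= 0.01

    def test_rate_too_low_rejected(self):
        rec = RawRecording(np.ones((1, 100)), 300.0, ["a"])
        with pytest.raises(ValidationError):
            gamma_band_filter(rec, PipelineConfig())


class TestFrameLogEnergy:
    def test_constant_one_gives_zero(self):
        rec = RawRecording(np.ones((2, 300)), 600.0, ["a", "b"])
        fs = frame_log_energy(rec, PipelineConfig())
        assert np.allclose(fs.E, 0.0)

    def test_constant_e_gives_two(self):
        rec = RawRecording(np.full((1, 300), np.e), 600.0, ["a"])
        fs = frame_log_energy(rec, PipelineConfig())
        assert np.allclose(fs.E, 2.0)

    def test_one_second_at_600hz_gives_39_frames(self):
        rec = RawRecording(np.ones((1, 600)), 600.0, ["a"])
        fs = frame_log_energy(rec, PipelineConfig())
        assert fs.n_frames == 39

    def test_shorter_than_window_gives_empty(self):
        rec = RawRecording(np.ones((1, 20)), 600.0, ["a"])
        fs = frame_log_energy(rec, PipelineConfig())
        assert fs.n_frames == 0

    def test_zero_signal_floored_not_minus_inf(self):
        rec = RawRecording(np.zeros((1, 300)), 600.0, ["a"])
        fs = frame_log_energy(rec, PipelineConfig())
        assert np.isfinite(fs.E).all()
        assert np.allclose(fs.E, np.log(1e-12))

    @given(st.integers(30, 5000))
    def test_frame_count_formula(self, n):
        rec = RawRecording(np.ones((1, n)), 600.0, ["a"])
        fs = frame_log_energy(rec, PipelineConfig())
        assert fs.n_frames == (n - 30) // 15 + 1


class TestStackContext:
    def _fs(self, n=10, d=3):
        rng = np.random.default_rng(0)
        rec = RawRecording(rng.normal(size=(d, 30 + 15 * (n - 1))), 600.0, [f"c{i}" for i in range(d)])
        return frame_log_energy(rec, PipelineConfig())

    def test_k0_is_identity(self):
        fs = self._fs()
        st_ = stack_context(fs, 0)
        assert np.array_equal(st_.F, fs.E)

    def test_shape_10x27_for_k4(self):
        st_ = stack_context(self._fs(10, 3), 4)
        assert st_.F.shape == (10, 27)
        assert len(st_.feature_index_map) == 27

    def test_edge_replication(self):
        fs = self._fs(10, 3)
        st_ = stack_context(fs, 4)
        for off in range(4):  # offsets -4..-1 on row 0 equal E_0
            block = st_.F[0, off * 3 : (off + 1) * 3]
            assert np.array_equal(block, fs.E[0])

    def test_interior_row_is_concatenation(self):
        fs = self._fs(12, 2)
        st_ = stack_context(fs, 4)
        expect = np.concatenate([fs.E[5 + off] for off in range(-4, 5)])
        assert np.array_equal(st_.F[5], expect)


class TestLabelAlignment:
    def _fs(self, dur_s, rate=600.0):
        n = int(dur_s * rate)
        rec = RawRecording(np.ones((1, n)), rate, ["a"])
        return frame_log_energy(rec, PipelineConfig())

    def test_phone_spanning_half_second(self):
        fs = self._fs(0.5)
        labels = [SegmentLabel(0.0, 0.5, "t", "phone")]
        fl = align_labels_to_frames(labels, fs)
        assert fs.n_frames == 19
        assert fl.phone == ["t"] * 19

    def test_majority_overlap_wins(self):
        # frame 0 covers [0, 0.05): 30 ms of t, 20 ms of aa
        fs = self._fs(0.05 + 0.025)
        labels = [
            SegmentLabel(0.0, 0.03, "t", "phone"),
            SegmentLabel(0.03, 0.08, "aa", "phone"),
        ]
        fl = align_labels_to_frames(labels, fs)
        assert fl.phone[0] == "t"

    def test_gap_is_silence(self):
        fs = self._fs(1.0)
        labels = [SegmentLabel(0.0, 0.1, "t", "phone"), SegmentLabel(0.8, 0.95, "s", "phone")]
        fl = align_labels_to_frames(labels, fs)
        assert "sil" in fl.phone
        mid = fs.n_frames // 2
        assert fl.phone[mid] == "sil"

    def test_tie_goes_to_earlier_segment(self):
        fs = self._fs(0.1)
        labels = [
            SegmentLabel(0.0, 0.025, "t", "phone"),
            SegmentLabel(0.025, 0.05, "aa", "phone"),
        ]
        fl = align_labels_to_frames(labels, fs)
        assert fl.phone[0] == "t"

    def test_phrase_ids_assigned(self):
        fs = self._fs(1.0)
        labels = [
            SegmentLabel(0.0, 0.4, "one", "phrase"),
            SegmentLabel(0.6, 1.0, "two", "phrase"),
        ]
        fl = align_labels_to_frames(labels, fs)
        assert fl.phrase_id[0] == 0
        assert fl.phrase_id[-1] == 1


class TestPhoneGrouping:
    @pytest.mark.parametrize(
        "fine,expected",
        [("z", ("s",)), ("d", ("t",)), ("ay", ("aa", "ih")), ("oy", ("ow", "ih")), ("aw", ("aa", "ow"))],
    )
    def test_grouping_examples(self, fine, expected):
        assert b2t.group_phone(fine) == expected

    def test_unknown_phone_named(self):
        with pytest.raises(KeyError, match="qq"):
            b2t.group_phone("qq")

    def test_user_extension(self):
        custom = dict(b2t.DEFAULT_GROUPING)
        custom["q"] = ("k",)
        assert b2t.group_phone("q", custom) == ("k",)


class TestPipelineDeterminism:
    def test_identical_input_identical_features(self, small_session):
        sim, cfg = small_session["sim"], small_session["cfg"]
        again, _, removed = b2t.extract_features(sim.session.recording, sim.session.labels, cfg)
        assert np.array_equal(again.F, small_session["features"].F)
        assert removed == small_session["removed"]

    def test_features_all_finite(self, small_session):
        assert np.isfinite(small_session["features"].F).all()
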