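"""Recording containers, EDF round trips, channel selection and epoching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hhtsann as h
from hhtsann.exceptions import (
    ChannelLookupError,
    ConfigurationError,
    EmptyInputError,
    FormatError,
    UnsupportedDialectError,
)
from hhtsann.signal_io import load_epoch_set, save_epoch_set, save_matrix


def _recording(n_channels=3, n_samples=2560, fs=256.0, seed=0, **kw):
    rng = np.random.default_rng(seed)
    return h.EEGRecording(
        data=rng.standard_normal((n_channels, n_samples)) * 20,
        fs=fs,
        channel_names=[f"C{i}" for i in range(n_channels)],
        subject_id="s01",
        **kw,
    )


class TestEdf:
    def test_round_trip_preserves_geometry_and_signal(self, tmp_path):
        rec = _recording(3, 2560, 256.0)
        path = tmp_path / "rt.edf"
        h.write_edf(path, rec)
        back = h.read_edf(path)
        assert back.n_channels == 3
        assert back.n_samples == 2560
        assert back.fs == 256.0
        assert back.channel_names == rec.channel_names
        # 16-bit quantisation bounds the round-trip error
        span = np.abs(rec.data).max()
        assert np.abs(back.data - rec.data).max() < 2 * span / 32767

    def test_truncated_file_is_a_format_error(self, tmp_path):
        rec = _recording()
        path = tmp_path / "t.edf"
        h.write_edf(path, rec)
        blob = path.read_bytes()
        path.write_bytes(blob[: len(blob) // 2])
        with pytest.raises(FormatError):
            h.read_edf(path)

    def test_garbage_header_names_the_field(self, tmp_path):
        path = tmp_path / "g.edf"
        path.write_bytes(b"\xff" * 600)
        with pytest.raises(FormatError):
            h.read_edf(path)

    def test_mixed_sampling_rates_rejected(self, tmp_path):
        rec = _recording(2, 512, 256.0)
        path = tmp_path / "m.edf"
        h.write_edf(path, rec)
        blob = bytearray(path.read_bytes())
        # per-signal samples-per-record fields live after 7 fixed-width blocks
        spr_off = 256 + 2 * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
        blob[spr_off:spr_off + 8] = b"128     "
        path.write_bytes(bytes(blob))
        with pytest.raises(UnsupportedDialectError):
            h.read_edf(path)

    def test_non_integer_rate_unsupported_by_writer(self, tmp_path):
        rec = _recording(fs=250.5)
        with pytest.raises(ConfigurationError):
            h.write_edf(tmp_path / "x.edf", rec)


class TestMatrixIO:
    def test_csv_sidecar_round_trip(self, tmp_path):
        rec = _recording(2, 100, 128.0, label="MDD")
        save_matrix(tmp_path / "s01.csv", rec)
        back = h.load_matrix(tmp_path / "s01.csv")
        np.testing.assert_allclose(back.data, rec.data, rtol=0, atol=1e-9)
        assert back.fs == 128.0
        assert back.label == "MDD"

    def test_missing_sidecar_is_a_format_error(self, tmp_path):
        np.savetxt(tmp_path / "x.csv", np.zeros((4, 2)), delimiter=",", header="a,b")
        with pytest.raises(FormatError):
            h.load_matrix(tmp_path / "x.csv")


class TestSelectChannels:
    def test_scalp_selection_drops_ecg_and_keeps_order(self):
        names = list(h.SCALP_19) + ["ECG"]
        rng = np.random.default_rng(1)
        rec = h.EEGRecording(rng.standard_normal((20, 64)), 256.0, names)
        kept = h.select_channels(rec, list(h.SCALP_19))
        assert kept.n_channels == 19
        assert kept.channel_names == list(h.SCALP_19)
        assert h.drop_ecg(rec).channel_names == list(h.SCALP_19)

    def test_identity_and_case_insensitivity(self):
        rec = _recording(3, 64)
        same = h.select_channels(rec, [n.upper() for n in rec.channel_names])
        np.testing.assert_array_equal(same.data, rec.data)

    def test_unknown_label_lists_available(self):
        rec = _recording(2, 64)
        with pytest.raises(ChannelLookupError, match="C0"):
            h.select_channels(rec, ["XX"])


class TestExtractEpochs:
    @pytest.mark.parametrize(
        "n_samples,window,step,expected",
        [
            (30720, 1024, 1024, 30),  # 120 s at 256 Hz, 4-s non-overlapping
            (30720, 1024, 512, 59),   # half-window overlap
            (1024, 1024, 1024, 1),    # boundary: signal length == window
        ],
    )
    def test_epoch_counts(self, n_samples, window, step, expected):
        rec = _recording(2, n_samples)
        es = h.extract_epochs(rec, window, step)
        assert es.n_epochs == expected
        assert es.epochs.shape == (expected, 2, window)

    def test_window_longer_than_signal_is_empty_input(self):
        with pytest.raises(EmptyInputError):
            h.extract_epochs(_recording(1, 100), 101, 1)

    def test_epoch_positions_and_metadata(self):
        rec = _recording(1, 1000, label="MDD")
        es = h.extract_epochs(rec, 100, 50)
        np.testing.assert_array_equal(es.epochs[3, 0], rec.data[0, 150:250])
        assert set(es.subject_ids) == {"s01"}
        assert set(es.labels) == {1}

    @given(
        n_samples=st.integers(3, 400),
        window=st.integers(1, 400),
        step=st.integers(1, 80),
    )
    @settings(max_examples=60, deadline=None)
    def test_count_matches_brute_force_enumeration(self, n_samples, window, step):
        if window > n_samples:
            return
        rec = h.EEGRecording(np.zeros((1, n_samples)), 100.0, ["a"])
        es = h.extract_epochs(rec, window, step)
        brute = sum(
            1 for start in range(0, n_samples, step) if start + window <= n_samples
        )
        assert es.n_epochs == brute

    def test_nonoverlapping_concat_reconstructs_prefix(self):
        rec = _recording(2, 1050)
        es = h.extract_epochs(rec, 100, 100)
        rebuilt = np.concatenate(list(es.epochs), axis=1)
        np.testing.assert_array_equal(rebuilt, rec.data[:, :1000])


class TestNormalize:
    def test_zscore_moments_and_constant_channel(self):
        rng = np.random.default_rng(3)
        epochs = rng.standard_normal((4, 2, 256)) * 7 + 3
        epochs[1, 0] = 5.0  # constant trace
        es = h.EpochSet(epochs, ["a"] * 4, [0] * 4, 128.0, 256, 256)
        z = h.normalize_epochs(es, "zscore_per_channel")
        assert np.abs(z.epochs.mean(axis=2)).max() < 1e-10
        np.testing.assert_array_equal(z.epochs[1, 0], np.zeros(256))

    def test_none_is_bitwise_identity(self, tiny_epochs):
        out = h.normalize_epochs(tiny_epochs, "none")
        assert out.epochs is tiny_epochs.epochs

    def test_unknown_method_rejected(self, tiny_epochs):
        with pytest.raises(ConfigurationError):
            h.normalize_epochs(tiny_epochs, "minmax")


def test_epoch_set_round_trip(tmp_path, tiny_epochs):
    save_epoch_set(tmp_path / "e.npz", tiny_epochs)
    back = load_epoch_set(tmp_path / "e.npz")
    np.testing.assert_array_equal(back.epochs, tiny_epochs.epochs)
    assert back.subjects == tiny_epochs.subjects
    assert back.window_samples == tiny_epochs.window_samples


def test_label_constant_within_subject_enforced():
    with pytest.raises(FormatError):
        h.EpochSet(np.zeros((2, 1, 8)), ["a", "a"], [0, 1], 10.0, 8, 8)
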