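import numpy as np
import pytest

from ecgdx.exceptions import (
    EmptyInputError,
    FormatError,
    LeadNotFoundError,
    ParameterError,
)
from ecgdx.signal_io import (
    ECGRecord,
    FilterSpec,
    apply_filter,
    parse_smoking_label,
    read_csv_record,
    read_wfdb_record,
    write_csv_record,
    write_wfdb_record,
)


def _two_lead_fixture(tmp_path, lead_i, lead_ii=None, comments=None, gain=2000.0):
    if lead_ii is None:
        lead_ii = np.zeros_like(np.asarray(lead_i, dtype=float))
    return write_wfdb_record(
        tmp_path / "rec.hea",
        {"i": np.asarray(lead_i, float), "ii": np.asarray(lead_ii, float)},
        fs=1000.0,
        gain=gain,
        comments=comments,
    )


class TestWFDB:
    def test_gain_identity_constant_lead(self, tmp_path):
        # int16 value 2000 at gain 2000 units/mV decodes to exactly 1.0 mV
        hea = _two_lead_fixture(tmp_path, np.ones(50))
        rec = read_wfdb_record(hea, "i")
        assert rec.fs == 1000.0
        np.testing.assert_allclose(rec.samples, 1.0)

    def test_absent_lead_lists_available(self, tmp_path):
        hea = _two_lead_fixture(tmp_path, np.ones(10))
        with pytest.raises(LeadNotFoundError, match="(?s)v9.*i.*ii"):
            read_wfdb_record(hea, "v9")

    def test_ramp_decodes_via_gain(self, tmp_path):
        # oracle: hand-decoded int16 LE bytes [0, 2000, 4000] / gain 2000
        hea = tmp_path / "ramp.hea"
        hea.write_text("ramp 1 1000 3\nramp.dat 16 2000(0)/mV 16 0 0 0 0 i\n")
        np.array([0, 2000, 4000], dtype="<i2").tofile(tmp_path / "ramp.dat")
        rec = read_wfdb_record(hea, "i")
        np.testing.assert_allclose(rec.samples, [0.0, 1.0, 2.0])

    def test_round_trip_within_quantization_step(self, tmp_path, rng):
        x = rng.normal(0.0, 1.0, 500)
        hea = _two_lead_fixture(tmp_path, x)
        rec = read_wfdb_record(hea, "i")
        assert np.max(np.abs(rec.samples - x)) <= 32.768 / 2**16

    def test_unsupported_format_rejected(self, tmp_path):
        hea = tmp_path / "bad.hea"
        hea.write_text("bad 1 1000 3\nbad.dat 212 2000/mV 16 0 0 0 0 i\n")
        (tmp_path / "bad.dat").write_bytes(b"\x00" * 6)
        with pytest.raises(FormatError, match="format"):
            read_wfdb_record(hea, "i")

    def test_missing_header_is_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            read_wfdb_record(tmp_path / "nope.hea", "i")

    def test_comment_metadata_and_label(self, tmp_path):
        hea = _two_lead_fixture(
            tmp_path, np.ones(10), comments={"age": "54", "Smoker": "yes"}
        )
        rec = read_wfdb_record(hea, "i")
        assert rec.meta["Smoker"] == "yes"
        assert rec.label == "smoker"


@pytest.mark.parametrize(
    "meta,expected",
    [
        ({"Smoker": "yes"}, "smoker"),
        ({"Smoker": "n/a"}, "unknown"),
        ({"smoker": "NO"}, "nonsmoker"),
        ({"SMOKER": "Yes"}, "smoker"),
        ({}, "unknown"),
        ({"diagnosis": "healthy"}, "unknown"),
    ],
)
def test_parse_smoking_label(meta, expected):
    assert parse_smoking_label(meta) == expected


class TestCSV:
    def test_read_three_samples(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("0.0\n0.5\n-0.5\n")
        rec = read_csv_record(p, fs=500.0)
        assert rec.fs == 500.0
        np.testing.assert_allclose(rec.samples, [0.0, 0.5, -0.5])

    def test_non_numeric_cell_cites_line(self, tmp_path):
        p = tmp_path / "b.csv"
        p.write_text("0.1\nabc\n0.2\n")
        with pytest.raises(FormatError, match="line 2"):
            read_csv_record(p, fs=500.0)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("\n\n")
        with pytest.raises(EmptyInputError):
            read_csv_record(p, fs=500.0)

    def test_round_trip_preserves_samples(self, tmp_path, rng):
        rec = ECGRecord(samples=rng.normal(size=1000), fs=360.0)
        path = write_csv_record(tmp_path / "d.csv", rec)
        back = read_csv_record(path, fs=360.0)
        np.testing.assert_allclose(back.samples, rec.samples, atol=5e-7)


class TestFilter:
    def _sine(self, hz, fs=500.0, secs=5.0):
        t = np.arange(int(fs * secs)) / fs
        return ECGRecord(samples=np.sin(2 * np.pi * hz * t), fs=fs)

    def test_zero_record_stays_zero(self):
        rec = ECGRecord(samples=np.zeros(2000), fs=500.0)
        for spec in (FilterSpec(), FilterSpec(kind="wavelet_denoise"), FilterSpec(kind="none")):
            out = apply_filter(rec, spec)
            np.testing.assert_allclose(out.samples, 0.0)

    def test_stopband_attenuation_at_50hz(self):
        # oracle: the designed FIR's squared response at 50 Hz is far below -20 dB
        rec = self._sine(50.0)
        out = apply_filter(rec, FilterSpec(low_hz=0.5, high_hz=40.0, fir_order=256))
        core = slice(500, -500)  # ignore edge transients
        drop_db = 20 * np.log10(
            np.sqrt(np.mean(out.samples[core] ** 2))
            / np.sqrt(np.mean(rec.samples[core] ** 2))
        )
        assert drop_db <= -20.0

    def test_passband_flat_at_10hz(self):
        rec = self._sine(10.0)
        out = apply_filter(rec, FilterSpec(low_hz=0.5, high_hz=40.0, fir_order=256))
        core = slice(500, -500)
        ratio_db = 20 * np.log10(
            np.sqrt(np.mean(out.samples[core] ** 2))
            / np.sqrt(np.mean(rec.samples[core] ** 2))
        )
        assert abs(ratio_db) <= 1.0

    def test_cutoff_at_nyquist_rejected(self):
        rec = self._sine(10.0, fs=100.0)
        with pytest.raises(ParameterError, match="Nyquist"):
            apply_filter(rec, FilterSpec(low_hz=0.5, high_hz=50.0))

    @pytest.mark.parametrize(
        "spec",
        [FilterSpec(), FilterSpec(kind="wavelet_denoise"), FilterSpec(kind="none")],
        ids=["fir", "wavelet", "none"],
    )
    def test_length_and_fs_preserved(self, spec, rng):
        rec = ECGRecord(samples=rng.normal(size=3000), fs=360.0)
        out = apply_filter(rec, spec)
        assert out.samples.size == rec.samples.size
        assert out.fs == rec.fs

    def test_zero_lag_filtering_is_time_symmetric(self, rng):
        x = rng.normal(size=4000)
        spec = FilterSpec(low_hz=0.5, high_hz=40.0, fir_order=128)
        fwd = apply_filter(ECGRecord(samples=x, fs=500.0), spec).samples
        rev = apply_filter(ECGRecord(samples=x[::-1], fs=500.0), spec).samples
        np.testing.assert_allclose(rev[::-1], fwd, atol=1e-9)

    def test_wavelet_denoise_reduces_noise(self, clean_train, rng):
        clean, _ = clean_train
        noisy = ECGRecord(
            samples=clean.samples + rng.normal(0, 0.1, clean.samples.size),
            fs=clean.fs,
        )
        out = apply_filter(noisy, FilterSpec(kind="wavelet_denoise"))
        err_before = np.mean((noisy.samples - clean.samples) ** 2)
        err_after = np.mean((out.samples - clean.samples) ** 2)
        assert err_after < err_before
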