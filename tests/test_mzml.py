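"""Streaming reader/writer behaviour: event contract, filters, closure,
cross-format equivalence and error reporting."""

import gzip
import os
from dataclasses import replace

import numpy as np
import pytest

import mzaccess as mz
from mzaccess import fixtures
from mzaccess.consumers import TICConsumer
from mzaccess.errors import ParameterError, ParseError
from mzaccess.instrument import live_spectra
from mzaccess.mzml import StreamOptions, read_full, stream_mzml, stream_mzxml


class RecordingConsumer(TICConsumer):
    """Remembers the full event sequence for order-fidelity checks."""

    def __init__(self):
        super().__init__()
        self.events = []
        self.settings = None
        self.expected = None

    def set_experimental_settings(self, settings):
        self.settings = settings
        self.events.append("settings")

    def set_expected_size(self, n_spectra, n_chromatograms):
        self.expected = (n_spectra, n_chromatograms)
        self.events.append("expected_size")

    def consume_spectrum(self, s):
        super().consume_spectrum(s)
        self.events.append(("spectrum", s.native_id, s.ms_level))

    def consume_chromatogram(self, c):
        super().consume_chromatogram(c)
        self.events.append(("chromatogram", c.native_id))


def test_stream_event_contract(mixed_run):
    """Settings and expected sizes arrive before any record; records arrive
    once each, in file order."""
    path, spec, truth = mixed_run
    sink = RecordingConsumer()
    summary = stream_mzml(path, sink)
    assert summary.n_spectra == truth.n_spectra
    assert summary.n_chromatograms == truth.n_chromatograms
    assert sink.events[0] == "settings"
    assert sink.events[1] == "expected_size"
    assert sink.expected[0] == truth.n_spectra
    delivered_ids = [e[1] for e in sink.events if e[0] == "spectrum"]
    assert delivered_ids == truth.native_ids
    delivered_levels = [e[2] for e in sink.events if e[0] == "spectrum"]
    assert delivered_levels == truth.ms_levels


def test_stream_totals_match_ground_truth(constant_run):
    path, spec, truth = constant_run
    sink = TICConsumer()
    stream_mzml(path, sink)
    assert sink.total_peaks == truth.total_peaks == 5000
    assert sink.total_tic == truth.total_tic == 5000.0
    assert sink.per_spectrum_tic == truth.per_spectrum_tic


def test_gzip_wrapped_stream_is_equivalent(mixed_run, tmp_path):
    """Gzip wrapping (detected by magic bytes, not name) must not change
    the consumer event sequence."""
    path, spec, truth = mixed_run
    gz_path = tmp_path / "wrapped.bin"  # deliberately no .gz suffix
    with open(path, "rb") as src, gzip.open(gz_path, "wb") as dst:
        dst.write(src.read())
    plain, wrapped = RecordingConsumer(), RecordingConsumer()
    stream_mzml(path, plain)
    stream_mzml(gz_path, wrapped)
    assert plain.events == wrapped.events
    assert plain.total_tic == wrapped.total_tic


def test_empty_run_delivers_header_only(tmp_path):
    path, truth = fixtures.generate(
        fixtures.FixtureSpec(n_spectra=0, n_chromatograms=0),
        tmp_path / "empty.mzML")
    sink = RecordingConsumer()
    summary = stream_mzml(path, sink)
    assert summary.n_spectra == 0 and summary.n_chromatograms == 0
    assert sink.events == ["settings", "expected_size"]
    assert sink.expected == (0, 0)
    exp = read_full(path)
    assert len(exp.spectra) == 0


def test_read_full_matches_ground_truth(mixed_run):
    path, spec, truth = mixed_run
    exp = read_full(path)
    assert len(exp.spectra) == truth.n_spectra
    for i, s in enumerate(exp.spectra):
        assert s.native_id == truth.native_ids[i]
        assert s.index == i
        assert s.retention_time == truth.retention_times[i]
        assert np.array_equal(s.mz, truth.mz_arrays[i])
        assert np.array_equal(s.intensity, truth.intensity_arrays[i])
    assert exp.settings.spectrum_count_declared == truth.n_spectra


def test_write_read_roundtrip_closure(mixed_run, tmp_path):
    """read(write(read(f))) == read(f), indexed and plain."""
    path, spec, truth = mixed_run
    first = read_full(path)
    for indexed in (False, True):
        out = tmp_path / f"rt_{indexed}.mzML"
        mz.write_mzml(first, out, indexed=indexed)
        again = read_full(out)
        assert again == first


def test_writer_offsets_point_at_records(tmp_path):
    path, truth = fixtures.generate(
        fixtures.FixtureSpec(n_spectra=3, peaks_per_spectrum=5,
                             n_chromatograms=1, indexed=True),
        tmp_path / "t.mzML")
    exp = read_full(path)
    report = mz.write_mzml(exp, tmp_path / "w.mzML", indexed=True)
    with open(tmp_path / "w.mzML", "rb") as f:
        for off in report.spectrum_offsets.values():
            f.seek(off)
            assert f.read(9) == b"<spectrum"
        for off in report.chromatogram_offsets.values():
            f.seek(off)
            assert f.read(13) == b"<chromatogram"
    assert report.n_spectra == 3 and report.n_chromatograms == 1
    assert report.checksum is not None


def test_write_empty_experiment_valid(tmp_path):
    report = mz.write_mzml(mz.Experiment(), tmp_path / "e.mzML", indexed=True)
    assert report.n_spectra == 0
    exp = read_full(tmp_path / "e.mzML")
    assert len(exp.spectra) == 0
    assert mz.verify_checksum(tmp_path / "e.mzML") is True


def test_truncated_file_reports_partial_delivery(mixed_run, tmp_path):
    path, spec, truth = mixed_run
    data = open(path, "rb").read()
    bad = tmp_path / "trunc.mzML"
    bad.write_bytes(data[: int(len(data) * 0.5)])
    sink = TICConsumer()
    with pytest.raises(ParseError) as exc_info:
        stream_mzml(bad, sink)
    err = exc_info.value
    assert err.records_delivered is not None and err.records_delivered > 0
    # complete leading records were delivered before the failure
    assert sink.n_spectra == err.records_delivered
    assert sink.per_spectrum_tic == truth.per_spectrum_tic[: sink.n_spectra]


def test_declared_count_mismatch_warns_not_errors(mixed_run, tmp_path):
    path, spec, truth = mixed_run
    data = open(path, "rb").read()
    # lie in the header: declared count is padded fixed-width, patch digits
    import re
    m = re.search(rb'<spectrumList count="(\d+)"', data)
    fake = str(truth.n_spectra + 5).rjust(len(m.group(1)), b"0".decode())
    patched = data[: m.start(1)] + fake.encode() + data[m.end(1):]
    p = tmp_path / "miscount.mzML"
    p.write_bytes(patched)
    sink = TICConsumer()
    with pytest.warns(UserWarning, match="declares"):
        summary = stream_mzml(p, sink)
    assert summary.n_spectra == truth.n_spectra  # parsing is authoritative


class TestStreamOptions:
    def test_skip_binary_decode_delivers_metadata_only(self, mixed_run):
        path, spec, truth = mixed_run
        sink = RecordingConsumer()
        stream_mzml(path, sink, StreamOptions(skip_binary_decode=True))
        assert sink.n_spectra == truth.n_spectra
        assert sink.total_peaks == 0  # arrays were not decoded
        ids = [e[1] for e in sink.events if e[0] == "spectrum"]
        assert ids == truth.native_ids

    def test_ms_level_filter(self, mixed_run):
        path, spec, truth = mixed_run
        sink = TICConsumer()
        stream_mzml(path, sink, StreamOptions(ms_level_filter={1}))
        assert sink.n_spectra == truth.ms_levels.count(1)

    def test_rt_window_closed_bounds(self, tmp_path):
        path, truth = fixtures.generate(
            fixtures.FixtureSpec(n_spectra=10, peaks_per_spectrum=5,
                                 rt_start=1.0, rt_step=1.0),
            tmp_path / "rt.mzML")
        sink = TICConsumer()
        stream_mzml(path, sink, StreamOptions(rt_window=(3.0, 5.0)))
        assert sink.n_spectra == 3  # RT 3, 4, 5 — inclusive both ends
        sink2 = TICConsumer()
        stream_mzml(path, sink2, StreamOptions(rt_window=(5.0, 5.0)))
        assert sink2.n_spectra == 1

    def test_invalid_options_rejected(self):
        with pytest.raises(ParameterError):
            StreamOptions(workers=0)
        with pytest.raises(ParameterError):
            StreamOptions(rt_window=(5.0, 1.0))


class TestFilterRT:
    def test_window_counts(self, tmp_path):
        path, truth = fixtures.generate(
            fixtures.FixtureSpec(n_spectra=10, peaks_per_spectrum=5,
                                 rt_start=1.0, rt_step=1.0),
            tmp_path / "in.mzML")
        n = mz.filter_rt(path, tmp_path / "out.mzML", 3.0, 5.0)
        assert n == 3
        out = read_full(tmp_path / "out.mzML")
        assert [s.retention_time for s in out.spectra] == [3.0, 4.0, 5.0]

    def test_whole_range_is_identity(self, mixed_run, tmp_path):
        path, spec, truth = mixed_run
        n = mz.filter_rt(path, tmp_path / "all.mzML", -1.0, 1e9)
        assert n == truth.n_spectra
        assert read_full(tmp_path / "all.mzML") == read_full(path)

    def test_exact_boundary_spectrum_retained(self, tmp_path):
        path, truth = fixtures.generate(
            fixtures.FixtureSpec(n_spectra=3, peaks_per_spectrum=5,
                                 rt_start=99.0, rt_step=1.0),
            tmp_path / "b.mzML")
        assert mz.filter_rt(path, tmp_path / "bo.mzML", 100.0, 100.0) == 1

    def test_bad_window_rejected(self, tmp_path, mixed_run):
        with pytest.raises(ParameterError):
            mz.filter_rt(mixed_run[0], tmp_path / "x.mzML", 5.0, 1.0)


class TestMzXML:
    def test_scan_count_and_order(self, tmp_path):
        spec = fixtures.FixtureSpec(n_spectra=10, peaks_per_spectrum=8,
                                    ms_level_pattern=(1, 2, 2))
        path, truth = fixtures.generate_mzxml(spec, tmp_path / "t.mzXML")
        sink = RecordingConsumer()
        summary = stream_mzxml(path, sink)
        assert summary.n_spectra == 10
        ids = [e[1] for e in sink.events if e[0] == "spectrum"]
        assert ids == truth.native_ids  # document order incl. nested MS2
        levels = [e[2] for e in sink.events if e[0] == "spectrum"]
        assert levels == truth.ms_levels

    @pytest.mark.parametrize("precision, compression",
                             [(64, "none"), (32, "none"), (64, "zlib")])
    def test_cross_format_field_equivalence(self, tmp_path, precision,
                                            compression):
        """The same logical run written as mzML and mzXML yields field-wise
        equal Spectrum objects (network byte order, duration RT notation and
        interleaved peaks all normalized away)."""
        spec = fixtures.FixtureSpec(n_spectra=12, peaks_per_spectrum=(5, 20),
                                    ms_level_pattern=(1, 2, 2),
                                    intensity_model="uniform",
                                    precision=precision,
                                    compression=compression, seed=3)
        p_ml, _ = fixtures.generate(spec, tmp_path / "a.mzML")
        p_xl, _ = fixtures.generate_mzxml(spec, tmp_path / "a.mzXML")
        assert read_full(p_ml).spectra == read_full(p_xl).spectra

    def test_gzip_wrapped_mzxml(self, tmp_path):
        spec = fixtures.FixtureSpec(n_spectra=5, peaks_per_spectrum=5,
                                    gzip_wrapped=True)
        path, truth = fixtures.generate_mzxml(spec, tmp_path / "z.mzXML")
        exp = read_full(path)
        assert len(exp.spectra) == 5
        assert np.array_equal(exp.spectra[0].mz, truth.mz_arrays[0])


def test_retention_time_minutes_normalized_to_seconds(tmp_path):
    """A file declaring scan start time in minutes is converted on read."""
    path, truth = fixtures.generate(
        fixtures.FixtureSpec(n_spectra=1, peaks_per_spectrum=3,
                             rt_start=90.0), tmp_path / "m.mzML")
    data = open(path, "rb").read()
    patched = data.replace(
        b'value="90.0" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"',
        b'value="1.5" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"')
    assert patched != data
    p = tmp_path / "minutes.mzML"
    p.write_bytes(patched)
    exp = read_full(p)
    assert exp.spectra[0].retention_time == 90.0


def test_streaming_live_spectrum_bound(large_run):
    """During streaming no more than a couple of reader-produced spectra are
    alive at once, no matter how long the run is."""
    path, spec, truth = large_run
    base = live_spectra.current
    live_spectra.reset_high_water()
    sink = TICConsumer()
    stream_mzml(path, sink)
    assert sink.n_spectra == truth.n_spectra == 10_000
    assert live_spectra.high_water - base <= 2
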