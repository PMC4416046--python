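"""Consumer contract and the stock pipeline stages: chaining semantics,
transforms, the demo smoothing/peak-picking algorithms, and the
constant-memory property of a full 3-stage pipeline."""

import numpy as np
import pytest

import mzaccess as mz
from mzaccess import fixtures
from mzaccess.consumers import (
    ApplyFunctionConsumer,
    ChainConsumer,
    NoopConsumer,
    PeakPickerConsumer,
    RTFilterConsumer,
    SmoothingConsumer,
    TICConsumer,
    cache_writer_consumer,
    moving_average,
    pick_peaks,
    writer_consumer,
)
from mzaccess.errors import ParameterError
from mzaccess.instrument import live_spectra
from mzaccess.mzml import read_full, stream_mzml


def make_spectrum(intensities, mz_values=None, **kwargs):
    intensities = np.asarray(intensities, dtype=float)
    if mz_values is None:
        mz_values = np.arange(len(intensities), dtype=float) + 100.0
    defaults = dict(native_id="scan=1", index=0, ms_level=1, retention_time=1.0)
    defaults.update(kwargs)
    return mz.Spectrum(mz=mz_values, intensity=intensities, **defaults)


def test_noop_consumer_accepts_everything(mixed_run):
    path, spec, truth = mixed_run
    summary = stream_mzml(path, NoopConsumer())
    assert summary.n_spectra == truth.n_spectra
    assert summary.n_chromatograms == truth.n_chromatograms


def test_tic_consumer_equals_in_memory_computation(mixed_run):
    """The streaming TIC result must equal the same statistic computed over
    a full in-memory load with the model operations."""
    path, spec, truth = mixed_run
    sink = TICConsumer()
    stream_mzml(path, sink)
    exp = read_full(path)
    assert sink.total_peaks == sum(mz.peak_count(s) for s in exp.spectra)
    assert sink.total_tic == sum(mz.total_ion_current(s) for s in exp.spectra)
    assert sink.total_tic == truth.total_tic


def test_tic_consumer_constant_fixture(constant_run):
    path, spec, truth = constant_run
    sink = TICConsumer()
    stream_mzml(path, sink)
    assert sink.result[0] == 5000
    assert sink.result[1] == 5000.0


def test_tic_consumer_empty_run(tmp_path):
    path, _ = fixtures.generate(fixtures.FixtureSpec(n_spectra=0),
                                tmp_path / "e.mzML")
    sink = TICConsumer()
    stream_mzml(path, sink)
    assert sink.result[:2] == (0, 0.0)


class TestApplyFunction:
    def test_identity_leaves_stream_unchanged(self, mixed_run):
        path, spec, truth = mixed_run
        tic = TICConsumer()
        stream_mzml(path, ChainConsumer([ApplyFunctionConsumer(lambda s: s),
                                         tic]))
        assert tic.total_tic == truth.total_tic

    def test_doubling_intensities_doubles_tic(self, mixed_run):
        path, spec, truth = mixed_run

        def double(s):
            return mz.Spectrum(native_id=s.native_id, index=s.index,
                               ms_level=s.ms_level,
                               retention_time=s.retention_time,
                               mz=s.mz, intensity=s.intensity * 2.0)

        tic = TICConsumer()
        stream_mzml(path, ChainConsumer([ApplyFunctionConsumer(double), tic]))
        assert tic.total_tic == pytest.approx(2.0 * truth.total_tic, rel=1e-12)

    def test_failure_names_the_record(self, mixed_run):
        path, spec, truth = mixed_run

        def explode(s):
            if s.native_id == "scan=4":
                raise RuntimeError("boom")
            return s

        with pytest.raises(RuntimeError, match="scan=4"):
            stream_mzml(path, ApplyFunctionConsumer(explode))


class TestChain:
    def test_chained_tic_equals_lone_tic(self, mixed_run):
        path, spec, truth = mixed_run
        lone, chained = TICConsumer(), TICConsumer()
        stream_mzml(path, lone)
        stream_mzml(path, ChainConsumer([NoopConsumer(), chained]))
        assert chained.result == lone.result

    def test_chain_order_matters(self, mixed_run):
        """TIC after a x2 transform differs by exactly factor 2 from TIC
        before it."""
        path, spec, truth = mixed_run

        def double(s):
            return mz.Spectrum(native_id=s.native_id, index=s.index,
                               ms_level=s.ms_level,
                               retention_time=s.retention_time,
                               mz=s.mz, intensity=s.intensity * 2.0)

        before, after = TICConsumer(), TICConsumer()
        stream_mzml(path, ChainConsumer(
            [before, ApplyFunctionConsumer(double), after]))
        assert after.total_tic == pytest.approx(2.0 * before.total_tic,
                                                rel=1e-12)
        assert before.total_tic == truth.total_tic

    def test_filtering_transformer_drops_records_for_downstream(self, tmp_path):
        path, truth = fixtures.generate(
            fixtures.FixtureSpec(n_spectra=10, peaks_per_spectrum=5,
                                 rt_start=1.0, rt_step=1.0),
            tmp_path / "f.mzML")
        downstream = TICConsumer()
        stream_mzml(path, ChainConsumer(
            [RTFilterConsumer(3.0, 5.0), downstream]))
        assert downstream.n_spectra == 3


class TestSmoothing:
    def test_window_one_is_identity(self):
        values = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        assert np.array_equal(moving_average(values, 1), values)

    def test_window_three_centered_average(self):
        # brute-force expectation with edge truncation
        values = np.array([0.0, 3.0, 0.0, 3.0])
        expected = np.array([3.0 / 2, 3.0 / 3, 6.0 / 3, 3.0 / 2])
        assert np.allclose(moving_average(values, 3), expected)

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError, match="odd"):
            SmoothingConsumer(window=4)
        with pytest.raises(ParameterError, match="odd"):
            moving_average(np.ones(5), 2)

    def test_smoothing_preserves_total_signal_interior(self):
        # constant signal is a fixed point of the moving average
        s = make_spectrum(np.full(20, 7.0))
        sm = SmoothingConsumer(window=5)
        sm.consume_spectrum(s)
        assert np.allclose(sm.result_spectrum.intensity, 7.0)


class TestPeakPicking:
    def test_single_local_maximum(self):
        mzs, ints = pick_peaks(np.array([100.0, 200.0, 300.0]),
                               np.array([0.0, 1.0, 0.0]), threshold=0.0)
        assert mzs.tolist() == [200.0]
        assert ints.tolist() == [1.0]

    def test_threshold_suppresses_small_peaks(self):
        mzs, _ = pick_peaks(np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
                            np.array([0.0, 5.0, 0.0, 1.0, 0.0]),
                            threshold=2.0)
        assert mzs.tolist() == [2.0]

    def test_plateaus_are_not_strict_maxima(self):
        mzs, _ = pick_peaks(np.arange(4.0), np.array([0.0, 2.0, 2.0, 0.0]))
        assert mzs.tolist() == []

    def test_gaussian_peak_found_at_true_center(self, tmp_path):
        """On a synthetic Gaussian-bump spectrum the picked apex must match
        the brute-force argmax over the generated grid."""
        spec = fixtures.FixtureSpec(n_spectra=6, peaks_per_spectrum=200,
                                    intensity_model="gaussian", seed=21)
        exp, truth = fixtures.build_experiment(spec)
        picker = PeakPickerConsumer(threshold=0.0)
        for i, s in enumerate(exp.spectra):
            picker.consume_spectrum(s)
            picked = picker.result_spectrum
            apex = truth.peak_argmax[i]
            brute_force_mz = s.mz[int(np.argmax(s.intensity))]
            assert s.mz[apex] == brute_force_mz
            # apex is a strict local max of a smooth bump -> it is picked
            assert picked.centroided is True
            best = picked.mz[int(np.argmax(picked.intensity))]
            assert abs(best - brute_force_mz) <= np.max(np.diff(s.mz))

    def test_negative_threshold_rejected(self):
        with pytest.raises(ParameterError):
            PeakPickerConsumer(threshold=-1.0)


def test_writer_consumer_roundtrip(mixed_run, tmp_path):
    path, spec, truth = mixed_run
    writer = writer_consumer(tmp_path / "copy.mzML", indexed=True)
    stream_mzml(path, writer)
    assert read_full(tmp_path / "copy.mzML") == read_full(path)
    with mz.open_indexed(tmp_path / "copy.mzML") as handle:
        assert handle.counts() == (truth.n_spectra, truth.n_chromatograms)


def test_writer_consumer_empty_stream(tmp_path):
    src, _ = fixtures.generate(fixtures.FixtureSpec(n_spectra=0),
                               tmp_path / "e.mzML")
    writer = writer_consumer(tmp_path / "out.mzML", indexed=True)
    stream_mzml(src, writer)
    assert len(read_full(tmp_path / "out.mzML").spectra) == 0


def test_cache_writer_consumer_equals_write_cache(mixed_run, tmp_path):
    path, spec, truth = mixed_run
    stream_mzml(path, cache_writer_consumer(tmp_path / "a.cache"))
    mz.write_cache(path, tmp_path / "b.cache", store_source_checksum=False)
    with mz.open_cache(tmp_path / "a.cache") as a, \
            mz.open_cache(tmp_path / "b.cache") as b:
        assert a.counts() == b.counts()
        for i in range(a.n_spectra):
            sa, sb = a.read_spectrum(i), b.read_spectrum(i)
            assert sa.native_id == sb.native_id
            assert np.array_equal(sa.mz, sb.mz)
            assert np.array_equal(sa.intensity, sb.intensity)


def test_cache_writer_chainable_after_filter(tmp_path):
    path, truth = fixtures.generate(
        fixtures.FixtureSpec(n_spectra=10, peaks_per_spectrum=5,
                             rt_start=1.0, rt_step=1.0),
        tmp_path / "s.mzML")
    stream_mzml(path, ChainConsumer([
        RTFilterConsumer(3.0, 5.0),
        cache_writer_consumer(tmp_path / "f.cache")]))
    with mz.open_cache(tmp_path / "f.cache") as handle:
        assert handle.n_spectra == 3


def test_three_stage_pipeline_constant_memory(large_run, tmp_path):
    """Smoothing -> peak picking -> write to disk over a 10,000-spectrum
    run, with the reader-level live-spectrum counter staying at the
    streaming bound throughout."""
    path, spec, truth = large_run
    base = live_spectra.current
    live_spectra.reset_high_water()
    pipeline = ChainConsumer([
        SmoothingConsumer(window=5),
        PeakPickerConsumer(threshold=0.0),
        writer_consumer(tmp_path / "picked.mzML", indexed=True),
    ])
    summary = stream_mzml(path, pipeline)
    assert summary.n_spectra == truth.n_spectra
    assert live_spectra.high_water - base <= 2
    out = read_full(tmp_path / "picked.mzML")
    assert len(out.spectra) == truth.n_spectra
    assert all(s.centroided for s in out.spectra)
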