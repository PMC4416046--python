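"""Consumer contract and stock implementations for event-driven pipelines.

A consumer is an event sink with four required operations —
``set_experimental_settings``, ``set_expected_size``, ``consume_spectrum``,
``consume_chromatogram`` — called in that order by the streaming readers,
each record exactly once in file order.  ``finalize`` is a fifth, optional
lifecycle step added by this package so that file-writing consumers can
flush and close; readers call it when present.

Consumers come in two flavours, declared by the ``is_transformer`` flag:
*observers* watch the stream without producing records (TIC summary, no-op),
while *transformers* rewrite each record and pass the result onward inside a
:class:`ChainConsumer`.  Chaining lets whole pipelines — e.g. smoothing →
peak picking → write to disk — run off the read event with a single
spectrum in memory at any time.

The smoothing and peak-picking consumers are deliberately minimal
demonstration algorithms (moving average; strict local maxima over a
threshold), not scientific-grade signal processing.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError
from .model import (
    Chromatogram,
    ExperimentalSettings,
    Spectrum,
    peak_count,
    total_ion_current,
)

__all__ = [
    "Consumer",
    "NoopConsumer",
    "TICConsumer",
    "ApplyFunctionConsumer",
    "ChainConsumer",
    "SmoothingConsumer",
    "PeakPickerConsumer",
    "RTFilterConsumer",
    "writer_consumer",
    "cache_writer_consumer",
    "moving_average",
    "pick_peaks",
]


class Consumer:
    """Base class spelling out the event-sink contract.

    Subclasses override what they need; the base accepts everything and
    does nothing, so it doubles as the no-op consumer.
    """

    is_transformer = False

    def set_experimental_settings(self, settings: ExperimentalSettings) -> None:
        pass

    def set_expected_size(self, n_spectra: int, n_chromatograms: int) -> None:
        pass

    def consume_spectrum(self, s: Spectrum) -> None:
        pass

    def consume_chromatogram(self, c: Chromatogram) -> None:
        pass

    def finalize(self) -> None:
        pass


class NoopConsumer(Consumer):
    """Accepts all events and stores nothing — a placeholder where a
    consumer is required but no operation is desired."""


class TICConsumer(Consumer):
    """Accumulates run summary statistics: total peak count, total ion
    current, and the per-spectrum TIC trace."""

    def __init__(self):
        self.n_spectra = 0
        self.n_chromatograms = 0
        self.total_peaks = 0
        self.total_tic = 0.0
        self.per_spectrum_tic: list[float] = []

    def consume_spectrum(self, s: Spectrum) -> None:
        tic = total_ion_current(s)
        self.n_spectra += 1
        self.total_peaks += peak_count(s)
        self.total_tic += tic
        self.per_spectrum_tic.append(tic)

    def consume_chromatogram(self, c: Chromatogram) -> None:
        self.n_chromatograms += 1

    @property
    def result(self) -> tuple[int, float, list[float]]:
        return self.total_peaks, self.total_tic, self.per_spectrum_tic


class ApplyFunctionConsumer(Consumer):
    """Applies a function to every record; downstream observers in a chain
    see the transformed records.

    ``fn`` receives a Spectrum (or Chromatogram when ``on_chromatograms``)
    and returns the replacement record.  An exception inside ``fn`` is
    re-raised annotated with the record's native id.
    """

    is_transformer = True

    def __init__(self, fn, on_spectra: bool = True, on_chromatograms: bool = False):
        self.fn = fn
        self.on_spectra = on_spectra
        self.on_chromatograms = on_chromatograms
        self.result_spectrum: Spectrum | None = None
        self.result_chromatogram: Chromatogram | None = None

    def consume_spectrum(self, s: Spectrum) -> None:
        if self.on_spectra:
            try:
                s = self.fn(s)
            except Exception as exc:
                raise type(exc)(
                    f"transform failed on record {s.native_id!r}: {exc}"
                ) from exc
        self.result_spectrum = s

    def consume_chromatogram(self, c: Chromatogram) -> None:
        if self.on_chromatograms:
            try:
                c = self.fn(c)
            except Exception as exc:
                raise type(exc)(
                    f"transform failed on record {c.native_id!r}: {exc}"
                ) from exc
        self.result_chromatogram = c


class ChainConsumer(Consumer):
    """Forwards every event to its members in list order.

    A transforming member replaces the record seen by everything after it;
    observers receive the record and pass it on unchanged.
    """

    def __init__(self, members: list[Consumer]):
        self.members = list(members)

    def set_experimental_settings(self, settings) -> None:
        for m in self.members:
            m.set_experimental_settings(settings)

    def set_expected_size(self, n_spectra, n_chromatograms) -> None:
        for m in self.members:
            m.set_expected_size(n_spectra, n_chromatograms)

    def consume_spectrum(self, s: Spectrum) -> None:
        for m in self.members:
            m.consume_spectrum(s)
            if getattr(m, "is_transformer", False):
                out = getattr(m, "result_spectrum", None)
                if out is None:
                    return  # record dropped by a filtering transformer
                s = out

    def consume_chromatogram(self, c: Chromatogram) -> None:
        for m in self.members:
            m.consume_chromatogram(c)
            if getattr(m, "is_transformer", False):
                out = getattr(m, "result_chromatogram", None)
                if out is None:
                    return
                c = out

    def finalize(self) -> None:
        for m in self.members:
            fin = getattr(m, "finalize", None)
            if fin is not None:
                fin()


def moving_average(intensity: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation: near the boundaries the
    window shrinks to the available samples, so the mean stays unbiased."""
    if window % 2 == 0 or window < 1:
        raise ParameterError("smoothing window must be an odd integer >= 1")
    n = len(intensity)
    if window == 1 or n == 0:
        return np.asarray(intensity, dtype=np.float64).copy()
    kernel = np.ones(window)
    sums = np.convolve(intensity, kernel, mode="same")
    counts = np.convolve(np.ones(n), kernel, mode="same")
    return sums / counts


class SmoothingConsumer(ApplyFunctionConsumer):
    """Moving-average smoothing of each spectrum's intensity array."""

    def __init__(self, window: int = 5):
        if window % 2 == 0 or window < 1:
            raise ParameterError("smoothing window must be an odd integer >= 1")
        self.window = window
        super().__init__(self._smooth)

    def _smooth(self, s: Spectrum) -> Spectrum:
        return Spectrum(
            native_id=s.native_id, index=s.index, ms_level=s.ms_level,
            retention_time=s.retention_time, mz=s.mz,
            intensity=moving_average(s.intensity, self.window),
            precursor_mz=s.precursor_mz,
            precursor_isolation_lower=s.precursor_isolation_lower,
            precursor_isolation_upper=s.precursor_isolation_upper,
            centroided=s.centroided,
        )


def pick_peaks(mz: np.ndarray, intensity: np.ndarray,
               threshold: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Local-maximum peak picking: keep positions strictly greater than both
    neighbours with intensity >= threshold.  Array boundary points have only
    one neighbour and are never peaks."""
    if threshold < 0:
        raise ParameterError("peak-picking threshold must be >= 0")
    n = len(intensity)
    if n < 3:
        return np.empty(0), np.empty(0)
    inner = intensity[1:-1]
    mask = (inner > intensity[:-2]) & (inner > intensity[2:]) & (inner >= threshold)
    idx = np.flatnonzero(mask) + 1
    return np.asarray(mz)[idx].copy(), np.asarray(intensity)[idx].copy()


class PeakPickerConsumer(ApplyFunctionConsumer):
    """Centroids each spectrum by strict-local-maximum picking; emitted
    spectra are flagged ``centroided``."""

    def __init__(self, threshold: float = 0.0):
        if threshold < 0:
            raise ParameterError("peak-picking threshold must be >= 0")
        self.threshold = threshold
        super().__init__(self._pick)

    def _pick(self, s: Spectrum) -> Spectrum:
        mz, intensity = pick_peaks(s.mz, s.intensity, self.threshold)
        return Spectrum(
            native_id=s.native_id, index=s.index, ms_level=s.ms_level,
            retention_time=s.retention_time, mz=mz, intensity=intensity,
            precursor_mz=s.precursor_mz,
            precursor_isolation_lower=s.precursor_isolation_lower,
            precursor_isolation_upper=s.precursor_isolation_upper,
            centroided=True,
        )


class RTFilterConsumer(Consumer):
    """Transformer that drops spectra outside a closed retention-time
    window; within a chain, dropped spectra do not reach later members."""

    is_transformer = True

    def __init__(self, rt_start: float, rt_end: float):
        if rt_start > rt_end:
            raise ParameterError("rt_start must be <= rt_end")
        self.rt_start = rt_start
        self.rt_end = rt_end
        self.result_spectrum: Spectrum | None = None
        self.result_chromatogram: Chromatogram | None = None
        self.n_retained = 0

    def consume_spectrum(self, s: Spectrum) -> None:
        if self.rt_start <= s.retention_time <= self.rt_end:
            self.result_spectrum = s
            self.n_retained += 1
        else:
            self.result_spectrum = None

    def consume_chromatogram(self, c: Chromatogram) -> None:
        self.result_chromatogram = c


def writer_consumer(path, *, indexed: bool = False, precision: int = 64,
                    compression: str = "none"):
    """mzML-writing consumer (see :class:`mzaccess.mzml.MzMLWriter`)."""
    from .mzml import MzMLWriter
    return MzMLWriter(path, indexed=indexed, precision=precision,
                      compression=compression)


def cache_writer_consumer(path, source_checksum_hex: str | None = None):
    """Binary-cache-writing consumer (see
    :class:`mzaccess.cached.CachedFileWriter`)."""
    from .cached import CachedFileWriter
    return CachedFileWriter(path, source_checksum_hex)
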