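"""Binary spectrum/chromatogram cache for fast repeated random access.

Converting an mzML file to this sidecar format costs one streaming pass;
afterwards every random read is a seek plus a raw ``memcpy``-style array
load — no XML, no Base64, no decompression.  That makes it the fastest
access mode by a wide margin, at the price of an upfront conversion and of
carrying only a minimal metadata subset (full run metadata must come from
the companion mzML).  The cache is an intermediate working format, not an
archival one.

All multi-byte values are little-endian regardless of host architecture, so
cache files are portable between machines.  The full byte layout is
documented in ``docs/cache_format.md`` and is normative for this package.

Layout summary::

    header : magic "MZACCHE1" | u32 version | u64 n_spectra | u64 n_chroms
             | 40-byte source SHA-1 hex (spaces if absent) | u32 flags
    entry  : u8 kind (0 spectrum, 1 chromatogram) | u32 id_len | id utf-8
             | i32 ms_level (-1 n/a) | f64 retention_time | u8 has_precursor
             | f64 precursor_mz | u64 n_points | n f64 axis | n f64 intensity
    trailer: u64 offset per entry (file order) | u64 trailer_start
"""

from __future__ import annotations

import hashlib
import os
import struct
from dataclasses import dataclass

import numpy as np

from .errors import CacheFormatError, CacheVersionError
from .instrument import live_spectra
from .model import Chromatogram, Spectrum

__all__ = [
    "CACHE_MAGIC",
    "CACHE_VERSION",
    "CacheHeader",
    "CachedFileWriter",
    "CachedFile",
    "write_cache",
    "open_cache",
    "source_checksum",
]

CACHE_MAGIC = b"MZACCHE1"
CACHE_VERSION = 1

_HEADER = struct.Struct("<8sIQQ40sI")  # magic, version, n_spec, n_chrom, sha1 hex, flags
_ENTRY_FIXED = struct.Struct("<BI")    # kind, id length
_ENTRY_META = struct.Struct("<idBd")   # ms_level, rt, has_precursor, precursor_mz
_U64 = struct.Struct("<Q")

KIND_SPECTRUM = 0
KIND_CHROMATOGRAM = 1


@dataclass
class CacheHeader:
    n_spectra: int
    n_chromatograms: int
    version: int = CACHE_VERSION
    source_checksum: str | None = None
    flags: int = 0


def source_checksum(path) -> str:
    """SHA-1 of an entire file, used for cache staleness detection."""
    sha = hashlib.sha1()
    with open(path, "rb") as f:
        while chunk := f.read(1 << 20):
            sha.update(chunk)
    return sha.hexdigest()


class CachedFileWriter:
    """Streaming cache writer; also usable directly as a consumer."""

    def __init__(self, cache_path, source_checksum_hex: str | None = None):
        self.path = str(cache_path)
        self._f = open(cache_path, "w+b")
        self._offsets: list[int] = []
        self._n_spectra = 0
        self._n_chromatograms = 0
        self._checksum = source_checksum_hex
        # placeholder header, patched at finalization
        self._f.write(_HEADER.pack(CACHE_MAGIC, CACHE_VERSION, 0, 0,
                                   self._checksum_bytes(), 0))

    def _checksum_bytes(self) -> bytes:
        return (self._checksum or "").ljust(40).encode("ascii")[:40]

    # consumer contract
    def set_experimental_settings(self, settings):
        pass

    def set_expected_size(self, n_spectra, n_chromatograms):
        pass

    def _write_entry(self, kind: int, native_id: str, ms_level: int,
                     rt: float, precursor_mz: float | None,
                     axis: np.ndarray, intensity: np.ndarray) -> None:
        self._offsets.append(self._f.tell())
        ident = native_id.encode("utf-8")
        self._f.write(_ENTRY_FIXED.pack(kind, len(ident)))
        self._f.write(ident)
        self._f.write(_ENTRY_META.pack(
            ms_level, rt,
            1 if precursor_mz is not None else 0,
            precursor_mz if precursor_mz is not None else 0.0))
        axis64 = np.ascontiguousarray(axis, dtype="<f8")
        int64 = np.ascontiguousarray(intensity, dtype="<f8")
        self._f.write(_U64.pack(len(axis64)))
        self._f.write(axis64.tobytes())
        self._f.write(int64.tobytes())

    def consume_spectrum(self, s: Spectrum) -> None:
        self._write_entry(KIND_SPECTRUM, s.native_id, s.ms_level,
                          s.retention_time, s.precursor_mz, s.mz, s.intensity)
        self._n_spectra += 1

    def consume_chromatogram(self, c: Chromatogram) -> None:
        self._write_entry(KIND_CHROMATOGRAM, c.native_id, -1, float("nan"),
                          None, c.time, c.intensity)
        self._n_chromatograms += 1

    def finalize(self) -> CacheHeader:
        trailer_start = self._f.tell()
        for off in self._offsets:
            self._f.write(_U64.pack(off))
        self._f.write(_U64.pack(trailer_start))
        self._f.seek(0)
        self._f.write(_HEADER.pack(CACHE_MAGIC, CACHE_VERSION,
                                   self._n_spectra, self._n_chromatograms,
                                   self._checksum_bytes(), 0))
        self._f.close()
        return CacheHeader(self._n_spectra, self._n_chromatograms,
                           source_checksum=self._checksum)

    def abort(self) -> None:
        try:
            self._f.close()
        finally:
            if os.path.exists(self.path):
                os.unlink(self.path)


def write_cache(source_path, cache_path, *, store_source_checksum: bool = True,
                workers: int = 1) -> CacheHeader:
    """Convert an mzML/mzXML file into a binary cache in one streaming pass.

    A partial cache is removed on failure.  Returns the finalized header.
    """
    from .mzml import StreamOptions, _looks_like_mzxml, stream_mzml, stream_mzxml

    checksum = source_checksum(source_path) if store_source_checksum else None
    writer = CachedFileWriter(cache_path, checksum)
    try:
        options = StreamOptions(workers=workers)
        if _looks_like_mzxml(source_path):
            stream_mzxml(source_path, writer, options)
        else:
            stream_mzml(source_path, writer, options)
    except BaseException:
        writer.abort()
        raise
    # stream_* already called finalize() through the consumer contract
    return CacheHeader(writer._n_spectra, writer._n_chromatograms,
                       source_checksum=checksum)


class CachedFile:
    """Random-access reader over a binary cache file.

    Array payloads are returned exactly as stored; this path never invokes
    the Base64 codec, which is what makes cached access the fastest mode.
    """

    def __init__(self, path):
        self.path = str(path)
        self._f = open(path, "rb")
        size = os.path.getsize(path)
        if size < _HEADER.size + _U64.size:
            raise CacheFormatError(f"{path}: too small to be a cache file")
        magic, version, n_spec, n_chrom, checksum, flags = _HEADER.unpack(
            self._f.read(_HEADER.size))
        if magic != CACHE_MAGIC:
            raise CacheFormatError(f"{path}: not a cache file (bad magic)")
        if version > CACHE_VERSION:
            raise CacheVersionError(
                f"{path}: cache format version {version} is newer than this "
                f"reader (supports up to {CACHE_VERSION})")
        checksum = checksum.decode("ascii").strip() or None
        self.header = CacheHeader(n_spec, n_chrom, version=version,
                                  source_checksum=checksum, flags=flags)
        n_entries = n_spec + n_chrom
        self._f.seek(size - _U64.size)
        (trailer_start,) = _U64.unpack(self._f.read(_U64.size))
        expected = trailer_start + n_entries * _U64.size + _U64.size
        if not (_HEADER.size <= trailer_start < size) or expected != size:
            raise CacheFormatError(
                f"{path}: trailer corrupt (trailer offset {trailer_start}, "
                f"file size {size}, {n_entries} entries declared)")
        self._f.seek(trailer_start)
        raw = self._f.read(n_entries * _U64.size)
        self._offsets = list(struct.unpack(f"<{n_entries}Q", raw)) if n_entries else []
        if any(b <= a for a, b in zip(self._offsets, self._offsets[1:])):
            raise CacheFormatError(f"{path}: entry offsets not increasing")
        # map spectrum/chromatogram ordinals to entry positions
        self._spectrum_entries: list[int] = []
        self._chromatogram_entries: list[int] = []
        for pos, off in enumerate(self._offsets):
            self._f.seek(off)
            kind = self._f.read(1)
            if not kind:
                raise CacheFormatError(f"{path}: truncated entry {pos}")
            if kind[0] == KIND_SPECTRUM:
                self._spectrum_entries.append(pos)
            elif kind[0] == KIND_CHROMATOGRAM:
                self._chromatogram_entries.append(pos)
            else:
                raise CacheFormatError(
                    f"{path}: unknown record kind {kind[0]} at entry {pos}")
        if (len(self._spectrum_entries) != n_spec
                or len(self._chromatogram_entries) != n_chrom):
            raise CacheFormatError(
                f"{path}: header counts ({n_spec}, {n_chrom}) disagree with "
                f"entries found ({len(self._spectrum_entries)}, "
                f"{len(self._chromatogram_entries)})")

    @property
    def n_spectra(self) -> int:
        return self.header.n_spectra

    @property
    def n_chromatograms(self) -> int:
        return self.header.n_chromatograms

    def counts(self) -> tuple[int, int]:
        return self.n_spectra, self.n_chromatograms

    def is_stale(self, source_path) -> bool | None:
        """Compare the stored source checksum against the current source
        file; ``None`` when no checksum was stored (inapplicable)."""
        if self.header.source_checksum is None:
            return None
        return source_checksum(source_path) != self.header.source_checksum

    def _read_entry(self, entry_pos: int):
        off = self._offsets[entry_pos]
        self._f.seek(off)
        try:
            kind, id_len = _ENTRY_FIXED.unpack(self._f.read(_ENTRY_FIXED.size))
            native_id = self._f.read(id_len).decode("utf-8")
            ms_level, rt, has_prec, prec = _ENTRY_META.unpack(
                self._f.read(_ENTRY_META.size))
            (n_points,) = _U64.unpack(self._f.read(_U64.size))
            payload = self._f.read(2 * 8 * n_points)
            if len(payload) != 2 * 8 * n_points:
                raise struct.error("truncated array payload")
        except (struct.error, UnicodeDecodeError) as exc:
            raise CacheFormatError(
                f"{self.path}: corrupt entry at offset {off}: {exc}") from exc
        axis = np.frombuffer(payload, dtype="<f8", count=n_points)
        intensity = np.frombuffer(payload, dtype="<f8", count=n_points,
                                  offset=8 * n_points)
        return kind, native_id, ms_level, rt, (prec if has_prec else None), \
            axis.astype(np.float64), intensity.astype(np.float64)

    def read_spectrum(self, i: int) -> Spectrum:
        if not 0 <= i < self.n_spectra:
            raise IndexError(f"spectrum index {i} out of range [0, {self.n_spectra})")
        kind, native_id, ms_level, rt, prec, axis, intensity = \
            self._read_entry(self._spectrum_entries[i])
        s = Spectrum(native_id=native_id, index=i, ms_level=ms_level,
                     retention_time=rt, mz=axis, intensity=intensity,
                     precursor_mz=prec)
        live_spectra.track(s)
        return s

    def read_chromatogram(self, i: int) -> Chromatogram:
        if not 0 <= i < self.n_chromatograms:
            raise IndexError(
                f"chromatogram index {i} out of range [0, {self.n_chromatograms})")
        _, native_id, _, _, _, axis, intensity = \
            self._read_entry(self._chromatogram_entries[i])
        return Chromatogram(native_id=native_id, index=i, time=axis,
                            intensity=intensity)

    def __iter__(self):
        for i in range(self.n_spectra):
            yield self.read_spectrum(i)

    def close(self) -> None:
        self._f.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
        return False


def open_cache(cache_path) -> CachedFile:
    """Open a binary cache file for random access."""
    return CachedFile(cache_path)
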