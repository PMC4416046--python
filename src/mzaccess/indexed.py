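"""Lazy random access to indexed mzML files.

An indexed mzML file ends with a byte-offset index (one entry per spectrum
and chromatogram), the index's own offset, and a file checksum.  Opening a
file therefore costs only a header read plus a bounded backwards tail scan;
each subsequent access seeks straight to the requested element and parses
just that byte range.  No element cache is kept: every access re-reads the
file, so memory stays constant no matter how many spectra are fetched.

Gzip-wrapped files are refused here — the stored offsets address the
uncompressed stream — and there is no silent fallback to a full-file scan
when the index is missing; callers must opt into re-indexing explicitly.
"""

from __future__ import annotations

import difflib
import os
import re
from dataclasses import dataclass, field

from lxml import etree

from .errors import (
    CorruptionError,
    GzipRandomAccessError,
    IdLookupError,
    IndexMissingError,
)
from .instrument import CountingReader, live_spectra
from .model import Chromatogram, ExperimentalSettings, Spectrum
from .mzml import (
    is_gzip,
    localname,
    parse_chromatogram_element,
    parse_spectrum_element,
)

__all__ = ["ScanIndex", "OnDiskExperiment", "open_indexed", "verify_checksum"]

TAIL_SCAN_START = 1024
TAIL_SCAN_MAX = 1 << 20  # 1 MiB
RESYNC_WINDOW = 1024
HEADER_READ = 8192


@dataclass
class ScanIndex:
    """Byte-offset index of one indexed mzML file."""

    spectrum_offsets: dict[str, int] = field(default_factory=dict)
    chromatogram_offsets: dict[str, int] = field(default_factory=dict)
    index_list_offset: int = 0
    checksum_declared: str | None = None

    def validate(self) -> None:
        offs = list(self.spectrum_offsets.values())
        offs += list(self.chromatogram_offsets.values())
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise CorruptionError("index offsets are not strictly increasing")
        if offs and self.index_list_offset <= max(offs):
            raise CorruptionError("indexListOffset lies before the last record")


def _scan_tail(f: CountingReader, file_size: int) -> bytes:
    """Read a doubling tail window until ``<indexListOffset>`` appears."""
    window = TAIL_SCAN_START
    while True:
        window = min(window, file_size)
        f.seek(file_size - window)
        tail = f.read(window)
        if b"<indexListOffset>" in tail or window >= min(TAIL_SCAN_MAX, file_size):
            return tail
        window *= 2


def _parse_index_region(region: bytes) -> ScanIndex:
    m = re.search(rb"<indexList\b.*?</indexList>", region, re.DOTALL)
    if not m:
        raise IndexMissingError(
            "indexList element not found at the recorded offset")
    try:
        root = etree.fromstring(m.group(0))
    except etree.XMLSyntaxError as exc:
        raise IndexMissingError(f"unparsable indexList: {exc}") from exc
    index = ScanIndex()
    for idx in root:
        if localname(idx.tag) != "index":
            continue
        name = idx.get("name", "")
        target = (index.spectrum_offsets if name == "spectrum"
                  else index.chromatogram_offsets if name == "chromatogram"
                  else None)
        if target is None:
            continue
        for off in idx:
            if localname(off.tag) == "offset":
                target[off.get("idRef", "")] = int(off.text.strip())
    cs = re.search(rb"<fileChecksum>\s*([0-9a-fA-F]{40})\s*</fileChecksum>", region)
    if cs:
        index.checksum_declared = cs.group(1).decode("ascii").lower()
    return index


def _read_index(f: CountingReader, file_size: int) -> ScanIndex:
    tail = _scan_tail(f, file_size)
    pos = tail.rfind(b"<indexListOffset>")
    if pos < 0:
        raise IndexMissingError(
            "no <indexListOffset> found in the file tail; this is not an "
            "indexed mzML file — use streaming access or re-index it")
    end = tail.find(b"</indexListOffset>", pos)
    digits = tail[pos + len(b"<indexListOffset>"):end if end > 0 else None]
    try:
        index_list_offset = int(digits.strip())
        if not (0 < index_list_offset < file_size):
            raise ValueError
    except (ValueError, AttributeError):
        raise IndexMissingError(
            f"corrupt indexListOffset value {digits!r}; re-index the file or "
            "fall back to streaming access") from None
    tail_start = file_size - len(tail)
    if index_list_offset >= tail_start:
        region = tail[index_list_offset - tail_start:]
    else:
        f.seek(index_list_offset)
        region = f.read(file_size - index_list_offset)
    index = _parse_index_region(region)
    index.index_list_offset = index_list_offset
    index.validate()
    return index


def _read_header_settings(f: CountingReader, path: str) -> ExperimentalSettings:
    f.seek(0)
    head = f.read(HEADER_READ)
    settings = ExperimentalSettings(source_file_name=str(path))
    m = re.search(rb'<run\s[^>]*\bid="([^"]*)"', head)
    if m:
        settings.run_id = _unescape(m.group(1).decode("utf-8"))
    m = re.search(rb'<spectrumList\s[^>]*\bcount="(\d+)"', head)
    if m:
        settings.spectrum_count_declared = int(m.group(1))
    m = re.search(rb'<instrumentConfiguration\s[^>]*\bid="([^"]*)"', head)
    if m:
        settings.instrument_description = m.group(1).decode("utf-8")
    return settings


def _unescape(text: str) -> str:
    from xml.sax.saxutils import unescape
    return unescape(text, {"&quot;": '"', "&apos;": "'"})


class OnDiskExperiment:
    """Random-access handle to an indexed mzML file.

    Opening reads only the document head and the tail index; each
    ``get_*`` call reads only the byte range of the requested element.
    Fetched spectra are not cached — repeated access re-reads the file.
    """

    def __init__(self, path: str, index: ScanIndex,
                 settings: ExperimentalSettings, reader: CountingReader,
                 file_size: int):
        self.path = str(path)
        self.index = index
        self.settings = settings
        self._f = reader
        self._size = file_size
        self._spec_ids = list(index.spectrum_offsets)
        self._chrom_ids = list(index.chromatogram_offsets)
        # element byte ranges end at the next recorded offset (or the index)
        offs = ([index.spectrum_offsets[i] for i in self._spec_ids]
                + [index.chromatogram_offsets[i] for i in self._chrom_ids]
                + [index.index_list_offset])
        self._bounds = sorted(offs)

    # --- sizes -------------------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return len(self._spec_ids)

    @property
    def n_chromatograms(self) -> int:
        return len(self._chrom_ids)

    def counts(self) -> tuple[int, int]:
        return self.n_spectra, self.n_chromatograms

    @property
    def bytes_read(self) -> int:
        """Total bytes read through this handle since open (I/O accounting)."""
        return self._f.bytes_read

    @property
    def file_size(self) -> int:
        return self._size

    # --- element fetch -----------------------------------------------------
    def _element_bytes(self, offset: int, opening: bytes) -> bytes:
        import bisect
        i = bisect.bisect_right(self._bounds, offset)
        end = self._bounds[i] if i < len(self._bounds) else self.index.index_list_offset
        self._f.seek(offset)
        raw = self._f.read(end - offset)
        if not raw.startswith(opening):
            # tolerate writers whose offsets include leading whitespace
            pos = raw[:RESYNC_WINDOW].find(opening)
            if pos < 0:
                raise CorruptionError(
                    f"no {opening.decode()} element at byte offset {offset} "
                    f"of {self.path}")
            raw = raw[pos:]
        # the range runs to the next indexed offset, which may include
        # closing list/run tags after the element itself — cut at its end
        closing = b"</" + opening[1:] + b">"
        end = raw.find(closing)
        if end >= 0:
            raw = raw[:end + len(closing)]
        return raw.strip()

    def _parse_at(self, offset: int, kind: str, ordinal: int):
        opening = b"<spectrum" if kind == "spectrum" else b"<chromatogram"
        raw = self._element_bytes(offset, opening)
        try:
            elem = etree.fromstring(raw)
        except etree.XMLSyntaxError as exc:
            raise CorruptionError(
                f"malformed {kind} element at byte offset {offset} of "
                f"{self.path}: {exc}") from exc
        if kind == "spectrum":
            s = parse_spectrum_element(elem, ordinal)
            live_spectra.track(s)
            return s
        return parse_chromatogram_element(elem, ordinal)

    def get_spectrum_by_index(self, i: int) -> Spectrum:
        if not 0 <= i < self.n_spectra:
            raise IndexError(
                f"spectrum index {i} out of range [0, {self.n_spectra})")
        native_id = self._spec_ids[i]
        return self._parse_at(self.index.spectrum_offsets[native_id],
                              "spectrum", i)

    def get_spectrum_by_id(self, native_id: str) -> Spectrum:
        if native_id not in self.index.spectrum_offsets:
            candidates = difflib.get_close_matches(
                native_id, self._spec_ids, n=3)
            raise IdLookupError(native_id, candidates)
        return self._parse_at(self.index.spectrum_offsets[native_id],
                              "spectrum", self._spec_ids.index(native_id))

    def get_chromatogram_by_index(self, i: int) -> Chromatogram:
        if not 0 <= i < self.n_chromatograms:
            raise IndexError(
                f"chromatogram index {i} out of range [0, {self.n_chromatograms})")
        native_id = self._chrom_ids[i]
        return self._parse_at(self.index.chromatogram_offsets[native_id],
                              "chromatogram", i)

    def get_chromatogram_by_id(self, native_id: str) -> Chromatogram:
        if native_id not in self.index.chromatogram_offsets:
            candidates = difflib.get_close_matches(
                native_id, self._chrom_ids, n=3)
            raise IdLookupError(native_id, candidates)
        return self._parse_at(self.index.chromatogram_offsets[native_id],
                              "chromatogram", self._chrom_ids.index(native_id))

    def __iter__(self):
        for i in range(self.n_spectra):
            yield self.get_spectrum_by_index(i)

    def close(self) -> None:
        self._f.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
        return False


def open_indexed(path) -> OnDiskExperiment:
    """Open an indexed mzML file for lazy random access.

    Raises :class:`GzipRandomAccessError` for gzip-wrapped input (the index
    offsets do not address the compressed stream) and
    :class:`IndexMissingError` when no usable tail index exists; there is no
    automatic fallback to a full scan.
    """
    if is_gzip(path):
        raise GzipRandomAccessError(
            f"{path} is gzip-wrapped: index byte offsets do not address the "
            "compressed stream; decompress it or use streaming access")
    file_size = os.path.getsize(path)
    reader = CountingReader(open(path, "rb"))
    try:
        index = _read_index(reader, file_size)
        settings = _read_header_settings(reader, path)
    except BaseException:
        reader.close()
        raise
    return OnDiskExperiment(path, index, settings, reader, file_size)


def verify_checksum(path_or_experiment) -> bool | None:
    """Recompute the tail SHA-1 and compare with the declared value.

    The digest covers every byte from the start of the file up to and
    including the ``>`` of the opening ``<fileChecksum>`` tag.  Returns
    ``True``/``False``, or ``None`` when the file declares no checksum
    (inapplicable, distinct from a failed check).
    """
    import hashlib

    path = getattr(path_or_experiment, "path", path_or_experiment)
    file_size = os.path.getsize(path)
    with open(path, "rb") as f:
        window = min(TAIL_SCAN_MAX, file_size)
        f.seek(file_size - window)
        tail = f.read(window)
        pos = tail.rfind(b"<fileChecksum>")
        if pos < 0:
            return None
        m = re.search(rb"<fileChecksum>\s*([0-9a-fA-F]{40})", tail[pos:])
        if not m:
            return None
        declared = m.group(1).decode("ascii").lower()
        stop = file_size - window + pos + len(b"<fileChecksum>")
        f.seek(0)
        sha = hashlib.sha1()
        remaining = stop
        while remaining:
            chunk = f.read(min(1 << 20, remaining))
            if not chunk:
                break
            sha.update(chunk)
            remaining -= len(chunk)
    return sha.hexdigest() == declared
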