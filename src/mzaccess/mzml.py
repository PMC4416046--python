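"""Event-driven mzML/mzXML reading and mzML writing.

The streaming reader is the foundation of every access mode: the in-memory
loader is just this reader plus an accumulating consumer, the cache and
indexed writers are consumers attached to it, and retention-time filtering
is a consumer chain.  During streaming only the record currently being
parsed is materialized; parsed XML subtrees are cleared as soon as their
record has been delivered, which turns the linearly growing memory profile
of whole-file parsing into a constant one.

Byte-offset index and checksum conventions for indexed mzML output:

* each offset is the byte position, from the start of the (uncompressed)
  file, of the ``<`` opening the ``<spectrum``/``<chromatogram`` element;
* ``fileChecksum`` is the lowercase hex SHA-1 of every byte from the start
  of the file up to and including the final ``>`` of the opening
  ``<fileChecksum>`` tag.

Gzip-wrapped input is detected by magic bytes and decompressed on the fly;
random access into gzip files is refused elsewhere because the stored
offsets address the uncompressed stream.
"""

from __future__ import annotations

import gzip
import hashlib
import io
import re
from dataclasses import dataclass, field
from xml.sax.saxutils import escape, quoteattr

import numpy as np
from lxml import etree

from . import codec
from .codec import BinaryArrayDescriptor, decode_many
from .errors import (
    CorruptionError,
    ParameterError,
    ParseError,
    UnsupportedCompressionError,
)
from .instrument import live_spectra
from .model import (
    Chromatogram,
    Experiment,
    ExperimentalSettings,
    Spectrum,
)

__all__ = [
    "StreamOptions",
    "StreamSummary",
    "WriteReport",
    "MzMLWriter",
    "stream_mzml",
    "stream_mzxml",
    "read_full",
    "write_mzml",
    "filter_rt",
]

MZML_NS = "http://psi.hupo.org/ms/mzml"

# Controlled-vocabulary accessions actually interpreted by this reader.
ACC_MS_LEVEL = "MS:1000511"
ACC_CENTROID = "MS:1000127"
ACC_PROFILE = "MS:1000128"
ACC_SCAN_START_TIME = "MS:1000016"
ACC_ISOLATION_TARGET = "MS:1000827"
ACC_ISOLATION_LOWER = "MS:1000828"
ACC_ISOLATION_UPPER = "MS:1000829"
ACC_SELECTED_ION_MZ = "MS:1000744"
ACC_32BIT = "MS:1000521"
ACC_64BIT = "MS:1000523"
ACC_ZLIB = "MS:1000574"
ACC_NO_COMPRESSION = "MS:1000576"
ACC_MZ_ARRAY = "MS:1000514"
ACC_INTENSITY_ARRAY = "MS:1000515"
ACC_TIME_ARRAY = "MS:1000595"

# Known compression accessions that we explicitly do not support (numpress
# family); anything else unrecognized on a binaryDataArray is ignored.
UNSUPPORTED_COMPRESSION_ACCESSIONS = {
    "MS:1002312", "MS:1002313", "MS:1002314",
    "MS:1002746", "MS:1002747", "MS:1002748",
}

GZIP_MAGIC = b"\x1f\x8b"


@dataclass
class StreamOptions:
    """Options for the streaming readers.

    ``skip_binary_decode`` delivers metadata-only records (empty arrays);
    ``ms_level_filter`` and ``rt_window`` drop spectra before delivery;
    ``workers`` sets the thread count for binary-array decoding (the output
    is identical for every value).
    """

    skip_binary_decode: bool = False
    ms_level_filter: set[int] | None = None
    rt_window: tuple[float, float] | None = None
    workers: int = 1

    def __post_init__(self):
        if self.workers < 1:
            raise ParameterError("workers must be >= 1")
        if self.rt_window is not None and self.rt_window[0] > self.rt_window[1]:
            raise ParameterError("rt_window start must be <= end")


@dataclass
class StreamSummary:
    n_spectra: int = 0
    n_chromatograms: int = 0


def open_maybe_gzip(path):
    """Open a file for binary reading, transparently unwrapping gzip
    (detected by magic bytes, never by file name)."""
    f = open(path, "rb")
    magic = f.read(2)
    f.seek(0)
    if magic == GZIP_MAGIC:
        return gzip.GzipFile(fileobj=f)
    return f


def is_gzip(path) -> bool:
    with open(path, "rb") as f:
        return f.read(2) == GZIP_MAGIC


def localname(tag) -> str:
    if isinstance(tag, str) and tag.startswith("{"):
        return tag.rsplit("}", 1)[1]
    return tag if isinstance(tag, str) else ""


def _cv_params(elem):
    """Yield (accession, value, unit_name) for cvParam children of elem."""
    for child in elem:
        if localname(child.tag) == "cvParam":
            yield (
                child.get("accession", ""),
                child.get("value", ""),
                child.get("unitName", ""),
            )


def _find_child(elem, name):
    for child in elem:
        if localname(child.tag) == name:
            return child
    return None


def _iter_children(elem, name):
    for child in elem:
        if localname(child.tag) == name:
            yield child


def _rt_to_seconds(value: float, unit_name: str) -> float:
    if unit_name.lower() in ("minute", "minutes", "min"):
        return value * 60.0
    return value  # seconds, or unstated (mzML default for scan start time)


def _parse_binary_arrays(elem, source_id, workers, skip_decode):
    """Parse the binaryDataArrayList of a spectrum/chromatogram element into
    role → float64 array."""
    bdal = _find_child(elem, "binaryDataArrayList")
    declared_n = elem.get("defaultArrayLength")
    declared_n = int(declared_n) if declared_n is not None else None
    out: dict[str, np.ndarray] = {}
    if bdal is None or skip_decode:
        return out
    descriptors, roles = [], []
    for bda in _iter_children(bdal, "binaryDataArray"):
        precision, compression, role = 64, None, None
        for acc, _val, _unit in _cv_params(bda):
            if acc == ACC_32BIT:
                precision = 32
            elif acc == ACC_64BIT:
                precision = 64
            elif acc == ACC_ZLIB:
                compression = "zlib"
            elif acc == ACC_NO_COMPRESSION:
                compression = "none"
            elif acc in UNSUPPORTED_COMPRESSION_ACCESSIONS:
                raise UnsupportedCompressionError(
                    f"unsupported compression {acc} in {source_id!r}; "
                    "only none/zlib are handled"
                )
            elif acc == ACC_MZ_ARRAY:
                role = "mz"
            elif acc == ACC_INTENSITY_ARRAY:
                role = "intensity"
            elif acc == ACC_TIME_ARRAY:
                role = "time"
        binary = _find_child(bda, "binary")
        text = binary.text or "" if binary is not None else ""
        descriptors.append(BinaryArrayDescriptor(
            encoded_text=text,
            precision=precision,
            compression=compression if compression is not None else "none",
            declared_length=declared_n,
            array_role=role or "intensity",
            source_id=source_id,
        ))
        roles.append(role)
    arrays, errors = decode_many(descriptors, workers=workers)
    if errors:
        raise errors[0][1]
    for role, arr in zip(roles, arrays):
        if role is not None:
            out[role] = arr
    return out


def parse_spectrum_element(elem, index: int, *, workers: int = 1,
                           skip_decode: bool = False) -> Spectrum:
    """Build a :class:`Spectrum` from a parsed ``<spectrum>`` element."""
    native_id = elem.get("id", f"index={index}")
    ms_level, centroided, rt = 1, None, 0.0
    for acc, val, _unit in _cv_params(elem):
        if acc == ACC_MS_LEVEL:
            ms_level = int(val)
        elif acc == ACC_CENTROID:
            centroided = True
        elif acc == ACC_PROFILE:
            centroided = False

    scan_list = _find_child(elem, "scanList")
    if scan_list is not None:
        scan = _find_child(scan_list, "scan")
        if scan is not None:
            for acc, val, unit in _cv_params(scan):
                if acc == ACC_SCAN_START_TIME:
                    rt = _rt_to_seconds(float(val), unit)

    prec_mz = iso_lower = iso_upper = None
    plist = _find_child(elem, "precursorList")
    if plist is not None:
        prec = _find_child(plist, "precursor")
        if prec is not None:
            iso = _find_child(prec, "isolationWindow")
            iso_target = None
            if iso is not None:
                for acc, val, _unit in _cv_params(iso):
                    if acc == ACC_ISOLATION_TARGET:
                        iso_target = float(val)
                    elif acc == ACC_ISOLATION_LOWER:
                        iso_lower = float(val)
                    elif acc == ACC_ISOLATION_UPPER:
                        iso_upper = float(val)
            sil = _find_child(prec, "selectedIonList")
            if sil is not None:
                si = _find_child(sil, "selectedIon")
                if si is not None:
                    for acc, val, _unit in _cv_params(si):
                        if acc == ACC_SELECTED_ION_MZ:
                            prec_mz = float(val)
            if prec_mz is None:
                prec_mz = iso_target

    arrays = _parse_binary_arrays(elem, native_id, workers, skip_decode)
    mz = arrays.get("mz", np.empty(0))
    inten = arrays.get("intensity", np.empty(0))
    s = Spectrum(
        native_id=native_id,
        index=index,
        ms_level=ms_level,
        retention_time=rt,
        mz=mz,
        intensity=inten,
        precursor_mz=prec_mz,
        precursor_isolation_lower=iso_lower,
        precursor_isolation_upper=iso_upper,
        centroided=centroided,
    )
    if not skip_decode:
        s.validate()  # enforces sorted non-negative m/z after decode
    return s


def parse_chromatogram_element(elem, index: int, *, workers: int = 1,
                               skip_decode: bool = False) -> Chromatogram:
    native_id = elem.get("id", f"index={index}")
    arrays = _parse_binary_arrays(elem, native_id, workers, skip_decode)
    c = Chromatogram(
        native_id=native_id,
        index=index,
        time=arrays.get("time", np.empty(0)),
        intensity=arrays.get("intensity", np.empty(0)),
    )
    if not skip_decode:
        c.validate()
    return c


def _spectrum_passes(s: Spectrum, options: StreamOptions) -> bool:
    if options.ms_level_filter is not None and s.ms_level not in options.ms_level_filter:
        return False
    if options.rt_window is not None:
        lo, hi = options.rt_window
        if not (lo <= s.retention_time <= hi):  # closed on both ends
            return False
    return True


def _clear_element(elem):
    # Free the parsed subtree and any exhausted preceding siblings so the
    # in-memory XML footprint stays constant during streaming.
    elem.clear()
    parent = elem.getparent()
    if parent is not None:
        while elem.getprevious() is not None:
            del parent[0]


def stream_mzml(path, consumer, options: StreamOptions | None = None) -> StreamSummary:
    """Stream an mzML (or indexedmzML, optionally gzip-wrapped) file through
    a consumer.

    The consumer receives, in order: ``set_experimental_settings``,
    ``set_expected_size`` and then one ``consume_spectrum`` /
    ``consume_chromatogram`` call per record in file order.  The declared
    header counts are forwarded for pre-sizing but never trusted for
    termination; actual element parsing is authoritative.
    """
    options = options or StreamOptions()
    settings = ExperimentalSettings(source_file_name=str(path))
    summary = StreamSummary()
    header_sent = False
    declared_spec = None
    declared_chrom = None
    spec_i = 0
    chrom_i = 0

    def ensure_header():
        nonlocal header_sent
        if not header_sent:
            settings.spectrum_count_declared = declared_spec
            settings.chromatogram_count_declared = declared_chrom
            consumer.set_experimental_settings(settings)
            consumer.set_expected_size(declared_spec or 0, declared_chrom or 0)
            header_sent = True

    f = open_maybe_gzip(path)
    try:
        context = etree.iterparse(f, events=("start", "end"), huge_tree=True,
                                  recover=False)
        for event, elem in context:
            tag = localname(elem.tag)
            if event == "start":
                if tag == "run":
                    settings.run_id = elem.get("id", "")
                elif tag == "mzML" and not settings.run_id:
                    settings.run_id = elem.get("id", "")
                elif tag == "spectrumList":
                    c = elem.get("count")
                    declared_spec = int(c) if c is not None else None
                elif tag == "chromatogramList":
                    c = elem.get("count")
                    declared_chrom = int(c) if c is not None else None
                elif tag == "instrumentConfiguration":
                    if not settings.instrument_description:
                        settings.instrument_description = elem.get("id", "")
                elif tag == "indexList":
                    break  # run data is over; ignore the tail index
                continue
            # end events
            if tag == "spectrum":
                ensure_header()
                s = parse_spectrum_element(
                    elem, spec_i, workers=options.workers,
                    skip_decode=options.skip_binary_decode)
                spec_i += 1
                _clear_element(elem)
                if _spectrum_passes(s, options):
                    live_spectra.track(s)
                    consumer.consume_spectrum(s)
                    summary.n_spectra += 1
                del s
            elif tag == "chromatogram":
                ensure_header()
                c = parse_chromatogram_element(
                    elem, chrom_i, workers=options.workers,
                    skip_decode=options.skip_binary_decode)
                chrom_i += 1
                _clear_element(elem)
                consumer.consume_chromatogram(c)
                summary.n_chromatograms += 1
                del c
            elif tag in ("spectrumList", "chromatogramList", "run", "mzML"):
                _clear_element(elem)
    except etree.XMLSyntaxError as exc:
        pos = None
        try:
            pos = f.tell()
        except (OSError, ValueError):
            pass
        raise ParseError(
            f"XML error in {path} at line {exc.lineno}, column "
            f"{getattr(exc, 'offset', '?')}: {exc.msg} "
            f"({summary.n_spectra} spectra and {summary.n_chromatograms} "
            f"chromatograms delivered before the failure)",
            byte_position=pos,
            records_delivered=summary.n_spectra + summary.n_chromatograms,
        ) from exc
    finally:
        f.close()

    ensure_header()  # empty runs still see settings + expected size
    if declared_spec is not None and declared_spec != spec_i:
        import warnings
        warnings.warn(
            f"{path}: header declares {declared_spec} spectra but "
            f"{spec_i} were parsed", stacklevel=2)
    finalize = getattr(consumer, "finalize", None)
    if finalize is not None:
        finalize()
    return summary


_DURATION_RE = re.compile(
    r"^(?:PT)?(?:(?P<h>[\d.]+)H)?(?:(?P<m>[\d.]+)M)?(?:(?P<s>[\d.]+)S)?$"
)


def _parse_mzxml_rt(text: str) -> float:
    """Parse the mzXML retentionTime duration notation (e.g. ``PT360.5S``)
    into seconds."""
    if not text:
        return 0.0
    m = _DURATION_RE.match(text.strip())
    if not m:
        try:
            return float(text)
        except ValueError:
            raise ParseError(f"cannot parse retentionTime {text!r}") from None
    h = float(m.group("h") or 0)
    mi = float(m.group("m") or 0)
    s = float(m.group("s") or 0)
    return h * 3600.0 + mi * 60.0 + s


def _decode_mzxml_peaks(elem, native_id: str, skip_decode: bool):
    """Decode an mzXML ``<peaks>`` element: Base64, optional zlib, declared
    byte order (network/big-endian by default), interleaved m/z–intensity."""
    import base64
    import binascii
    import zlib as _zlib

    if skip_decode:
        return np.empty(0), np.empty(0)
    text = "".join((elem.text or "").split())
    try:
        raw = base64.b64decode(text.encode("ascii"), validate=True)
    except (binascii.Error, ValueError) as exc:
        raise CorruptionError(f"malformed Base64 in scan {native_id!r}: {exc}") from exc
    compression = (elem.get("compressionType") or "none").lower()
    if compression == "zlib":
        try:
            raw = _zlib.decompress(raw)
        except _zlib.error as exc:
            raise CorruptionError(
                f"zlib decompression failed in scan {native_id!r}: {exc}") from exc
    elif compression != "none":
        raise UnsupportedCompressionError(
            f"unsupported mzXML compressionType {compression!r} in scan {native_id!r}")
    precision = int(elem.get("precision", "32"))
    byte_order = elem.get("byteOrder", "network")
    order = ">" if byte_order in ("network", "big") else "<"
    values = codec._decode_raw(raw, precision, order)
    if len(values) % 2:
        raise CorruptionError(
            f"odd number of values in interleaved peak list of scan {native_id!r}")
    return values[0::2].copy(), values[1::2].copy()


def stream_mzxml(path, consumer, options: StreamOptions | None = None) -> StreamSummary:
    """Stream an mzXML 3.x file (optionally gzip-wrapped) through a consumer
    with the same event contract as :func:`stream_mzml`.

    mzXML nests fragment scans inside their parent scan, so records are
    emitted when each scan's ``<peaks>`` element completes — that is document
    order, parents before children.
    """
    options = options or StreamOptions()
    settings = ExperimentalSettings(source_file_name=str(path))
    summary = StreamSummary()
    header_sent = False
    declared = None
    spec_i = 0
    scan_stack: list[dict] = []

    def ensure_header():
        nonlocal header_sent
        if not header_sent:
            settings.spectrum_count_declared = declared
            consumer.set_experimental_settings(settings)
            consumer.set_expected_size(declared or 0, 0)
            header_sent = True

    f = open_maybe_gzip(path)
    try:
        context = etree.iterparse(f, events=("start", "end"), huge_tree=True)
        for event, elem in context:
            tag = localname(elem.tag)
            if event == "start":
                if tag == "msRun":
                    c = elem.get("scanCount")
                    declared = int(c) if c is not None else None
                elif tag == "scan":
                    scan_stack.append({
                        "num": elem.get("num", str(spec_i + 1)),
                        "ms_level": int(elem.get("msLevel", "1")),
                        "rt": _parse_mzxml_rt(elem.get("retentionTime", "")),
                        "centroided": {None: None, "1": True, "0": False}.get(
                            elem.get("centroided")),
                        "precursor": None,
                        "window": None,
                    })
                continue
            if tag == "precursorMz" and scan_stack:
                scan_stack[-1]["precursor"] = float(elem.text)
                ww = elem.get("windowWideness")
                scan_stack[-1]["window"] = float(ww) if ww is not None else None
            elif tag == "peaks" and scan_stack:
                ensure_header()
                meta = scan_stack[-1]
                native_id = f"scan={meta['num']}"
                mz, inten = _decode_mzxml_peaks(
                    elem, native_id, options.skip_binary_decode)
                half = meta["window"] / 2.0 if meta["window"] is not None else None
                s = Spectrum(
                    native_id=native_id,
                    index=spec_i,
                    ms_level=meta["ms_level"],
                    retention_time=meta["rt"],
                    mz=mz,
                    intensity=inten,
                    precursor_mz=meta["precursor"],
                    precursor_isolation_lower=half,
                    precursor_isolation_upper=half,
                    centroided=meta["centroided"],
                )
                if not options.skip_binary_decode:
                    s.validate()
                spec_i += 1
                if _spectrum_passes(s, options):
                    live_spectra.track(s)
                    consumer.consume_spectrum(s)
                    summary.n_spectra += 1
                del s
            elif tag == "scan":
                if scan_stack:
                    scan_stack.pop()
                _clear_element(elem)
            elif tag == "msRun":
                _clear_element(elem)
    except etree.XMLSyntaxError as exc:
        raise ParseError(
            f"XML error in {path} at line {exc.lineno}: {exc.msg} "
            f"({summary.n_spectra} spectra delivered before the failure)",
            records_delivered=summary.n_spectra,
        ) from exc
    finally:
        f.close()

    ensure_header()
    finalize = getattr(consumer, "finalize", None)
    if finalize is not None:
        finalize()
    return summary


class _Accumulator:
    """Consumer that materializes the whole run: the in-memory mode."""

    def __init__(self):
        self.experiment = Experiment()

    def set_experimental_settings(self, settings):
        self.experiment.settings = settings

    def set_expected_size(self, n_spectra, n_chromatograms):
        pass

    def consume_spectrum(self, s):
        self.experiment.spectra.append(s)

    def consume_chromatogram(self, c):
        self.experiment.chromatograms.append(c)


def _looks_like_mzxml(path) -> bool:
    with open_maybe_gzip(path) as f:
        head = f.read(4096)
    return b"<mzXML" in head or b"<msRun" in head


def read_full(path, options: StreamOptions | None = None) -> Experiment:
    """Load an entire mzML or mzXML file into memory (format sniffed from
    the document head).  A thin composition of the streaming reader with an
    accumulating consumer."""
    acc = _Accumulator()
    if _looks_like_mzxml(path):
        stream_mzxml(path, acc, options)
    else:
        stream_mzml(path, acc, options)
    # re-index after any option-driven filtering so Experiment invariants hold
    for i, s in enumerate(acc.experiment.spectra):
        s.index = i
    for i, c in enumerate(acc.experiment.chromatograms):
        c.index = i
    return acc.experiment


@dataclass
class WriteReport:
    """What the writer did: per-record byte offsets (for indexed output) and
    the SHA-1 file checksum it embedded."""

    path: str = ""
    n_spectra: int = 0
    n_chromatograms: int = 0
    spectrum_offsets: dict[str, int] = field(default_factory=dict)
    chromatogram_offsets: dict[str, int] = field(default_factory=dict)
    checksum: str | None = None
    indexed: bool = False


def _fmt(x: float) -> str:
    return repr(float(x))


_COUNT_WIDTH = 10  # zero-padded count attributes patched in at finalization


class MzMLWriter:
    """Streaming mzML writer usable as the tail of a consumer chain.

    Records are written as they arrive, so memory stays constant; the
    header's spectrum/chromatogram counts are zero-padded placeholders
    patched at finalization.  With ``indexed=True`` the document is wrapped
    in ``<indexedmzML>`` and finalization appends the byte-offset index,
    ``indexListOffset`` and the SHA-1 ``fileChecksum``.
    """

    def __init__(self, path, *, indexed: bool = False, precision: int = 64,
                 compression: str = "none", run_id: str | None = None):
        if precision not in (32, 64):
            raise ParameterError("precision must be 32 or 64")
        if compression not in ("none", "zlib"):
            raise UnsupportedCompressionError(
                f"unsupported compression {compression!r}")
        self.path = str(path)
        self.indexed = indexed
        self.precision = precision
        self.compression = compression
        self.run_id = run_id
        self.report = WriteReport(path=self.path, indexed=indexed)
        self._f = open(path, "w+b")
        self._state = "new"   # new -> spectra -> chromatograms -> done
        self._spec_count_pos = None
        self._chrom_count_pos = None
        self._settings = None

    # --- consumer contract -------------------------------------------------
    def set_experimental_settings(self, settings):
        self._settings = settings

    def set_expected_size(self, n_spectra, n_chromatograms):
        pass

    def _w(self, data: str | bytes) -> None:
        self._f.write(data.encode("utf-8") if isinstance(data, str) else data)

    def _begin_document(self):
        rid = self.run_id
        if rid is None:
            rid = (self._settings.run_id if self._settings and
                   self._settings.run_id else "run")
        self._run_id = rid
        self._w('<?xml version="1.0" encoding="utf-8"?>\n')
        if self.indexed:
            self._w(f'<indexedmzML xmlns="{MZML_NS}">\n')
        self._w(f'<mzML xmlns="{MZML_NS}" version="1.1.0" id={quoteattr(rid)}>\n')
        self._w('<cvList count="2">\n'
                '<cv id="MS" fullName="Proteomics Standards Initiative Mass '
                'Spectrometry Ontology" URI="https://raw.githubusercontent.com/'
                'HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>\n'
                '<cv id="UO" fullName="Unit Ontology" URI="https://raw.'
                'githubusercontent.com/bio-ontology-research-group/unit-ontology'
                '/master/unit.obo"/>\n</cvList>\n')
        self._w('<fileDescription><fileContent>'
                '<cvParam cvRef="MS" accession="MS:1000294" name="mass spectrum" value=""/>'
                '</fileContent></fileDescription>\n')
        self._w('<softwareList count="1">'
                '<software id="mzaccess" version="0.1.0"/></softwareList>\n')
        self._w('<instrumentConfigurationList count="1">'
                '<instrumentConfiguration id="IC1"/>'
                '</instrumentConfigurationList>\n')
        self._w('<dataProcessingList count="1"><dataProcessing id="dp1">'
                '<processingMethod order="0" softwareRef="mzaccess"/>'
                '</dataProcessing></dataProcessingList>\n')
        self._w(f'<run id={quoteattr(rid)} '
                'defaultInstrumentConfigurationRef="IC1">\n')
        self._w('<spectrumList count="')
        self._spec_count_pos = self._f.tell()
        self._w("0" * _COUNT_WIDTH)
        self._w('" defaultDataProcessingRef="dp1">\n')
        self._state = "spectra"

    def _ensure_spectra(self):
        if self._state == "new":
            self._begin_document()
        elif self._state != "spectra":
            raise ParseError("spectra must precede chromatograms in the stream")

    def _ensure_chromatograms(self):
        if self._state == "new":
            self._begin_document()
        if self._state == "spectra":
            self._w('</spectrumList>\n')
            self._w('<chromatogramList count="')
            self._chrom_count_pos = self._f.tell()
            self._w("0" * _COUNT_WIDTH)
            self._w('" defaultDataProcessingRef="dp1">\n')
            self._state = "chromatograms"

    def _binary_xml(self, values, role_acc: str, role_name: str,
                    unit: str = "") -> str:
        d = codec.encode_array(values, self.precision, self.compression)
        acc_prec = ACC_64BIT if self.precision == 64 else ACC_32BIT
        name_prec = ("64-bit float" if self.precision == 64 else "32-bit float")
        if self.compression == "zlib":
            acc_comp, name_comp = ACC_ZLIB, "zlib compression"
        else:
            acc_comp, name_comp = ACC_NO_COMPRESSION, "no compression"
        return (
            f'<binaryDataArray encodedLength="{len(d.encoded_text)}">'
            f'<cvParam cvRef="MS" accession="{acc_prec}" name="{name_prec}" value=""/>'
            f'<cvParam cvRef="MS" accession="{acc_comp}" name="{name_comp}" value=""/>'
            f'<cvParam cvRef="MS" accession="{role_acc}" name="{role_name}" value=""{unit}/>'
            f'<binary>{d.encoded_text}</binary></binaryDataArray>'
        )

    def consume_spectrum(self, s: Spectrum) -> None:
        self._ensure_spectra()
        i = self.report.n_spectra
        parts = [f'<spectrum index="{i}" id={quoteattr(s.native_id)} '
                 f'defaultArrayLength="{len(s.mz)}">\n']
        parts.append(f'<cvParam cvRef="MS" accession="{ACC_MS_LEVEL}" '
                     f'name="ms level" value="{s.ms_level}"/>\n')
        if s.centroided is True:
            parts.append(f'<cvParam cvRef="MS" accession="{ACC_CENTROID}" '
                         'name="centroid spectrum" value=""/>\n')
        elif s.centroided is False:
            parts.append(f'<cvParam cvRef="MS" accession="{ACC_PROFILE}" '
                         'name="profile spectrum" value=""/>\n')
        parts.append(
            '<scanList count="1"><scan>'
            f'<cvParam cvRef="MS" accession="{ACC_SCAN_START_TIME}" '
            f'name="scan start time" value="{_fmt(s.retention_time)}" '
            'unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>'
            '</scan></scanList>\n')
        if s.precursor_mz is not None or s.precursor_isolation_lower is not None:
            parts.append('<precursorList count="1"><precursor>')
            if s.precursor_mz is not None or s.precursor_isolation_lower is not None:
                parts.append('<isolationWindow>')
                if s.precursor_mz is not None:
                    parts.append(
                        f'<cvParam cvRef="MS" accession="{ACC_ISOLATION_TARGET}" '
                        f'name="isolation window target m/z" '
                        f'value="{_fmt(s.precursor_mz)}"/>')
                if s.precursor_isolation_lower is not None:
                    parts.append(
                        f'<cvParam cvRef="MS" accession="{ACC_ISOLATION_LOWER}" '
                        f'name="isolation window lower offset" '
                        f'value="{_fmt(s.precursor_isolation_lower)}"/>')
                if s.precursor_isolation_upper is not None:
                    parts.append(
                        f'<cvParam cvRef="MS" accession="{ACC_ISOLATION_UPPER}" '
                        f'name="isolation window upper offset" '
                        f'value="{_fmt(s.precursor_isolation_upper)}"/>')
                parts.append('</isolationWindow>')
            if s.precursor_mz is not None:
                parts.append(
                    '<selectedIonList count="1"><selectedIon>'
                    f'<cvParam cvRef="MS" accession="{ACC_SELECTED_ION_MZ}" '
                    f'name="selected ion m/z" value="{_fmt(s.precursor_mz)}"/>'
                    '</selectedIon></selectedIonList>')
            parts.append('</precursor></precursorList>\n')
        parts.append('<binaryDataArrayList count="2">\n')
        parts.append(self._binary_xml(
            s.mz, ACC_MZ_ARRAY, "m/z array",
            ' unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"'))
        parts.append("\n")
        parts.append(self._binary_xml(s.intensity, ACC_INTENSITY_ARRAY,
                                      "intensity array"))
        parts.append('\n</binaryDataArrayList>\n</spectrum>\n')

        offset = self._f.tell()
        self.report.spectrum_offsets[s.native_id] = offset
        self._w("".join(parts))
        self.report.n_spectra += 1

    def consume_chromatogram(self, c: Chromatogram) -> None:
        self._ensure_chromatograms()
        i = self.report.n_chromatograms
        parts = [f'<chromatogram index="{i}" id={quoteattr(c.native_id)} '
                 f'defaultArrayLength="{len(c.time)}">\n']
        parts.append('<binaryDataArrayList count="2">\n')
        parts.append(self._binary_xml(
            c.time, ACC_TIME_ARRAY, "time array",
            ' unitCvRef="UO" unitAccession="UO:0000010" unitName="second"'))
        parts.append("\n")
        parts.append(self._binary_xml(c.intensity, ACC_INTENSITY_ARRAY,
                                      "intensity array"))
        parts.append('\n</binaryDataArrayList>\n</chromatogram>\n')

        offset = self._f.tell()
        self.report.chromatogram_offsets[c.native_id] = offset
        self._w("".join(parts))
        self.report.n_chromatograms += 1

    def finalize(self) -> WriteReport:
        if self._state == "done":
            return self.report
        if self._state == "new":
            self._begin_document()
        if self._state == "spectra":
            self._w('</spectrumList>\n')
        elif self._state == "chromatograms":
            self._w('</chromatogramList>\n')
        self._w('</run>\n</mzML>\n')

        # patch the zero-padded count placeholders
        end = self._f.tell()
        self._f.seek(self._spec_count_pos)
        self._w(str(self.report.n_spectra).rjust(_COUNT_WIDTH, "0"))
        if self._chrom_count_pos is not None:
            self._f.seek(self._chrom_count_pos)
            self._w(str(self.report.n_chromatograms).rjust(_COUNT_WIDTH, "0"))
        self._f.seek(end)

        if self.indexed:
            index_list_offset = self._f.tell()
            n_indices = 1 + (1 if self.report.chromatogram_offsets else 0)
            self._w(f'<indexList count="{n_indices}">\n<index name="spectrum">\n')
            for native_id, off in self.report.spectrum_offsets.items():
                self._w(f'<offset idRef={quoteattr(native_id)}>{off}</offset>\n')
            self._w('</index>\n')
            if self.report.chromatogram_offsets:
                self._w('<index name="chromatogram">\n')
                for native_id, off in self.report.chromatogram_offsets.items():
                    self._w(f'<offset idRef={quoteattr(native_id)}>{off}</offset>\n')
                self._w('</index>\n')
            self._w('</indexList>\n')
            self._w(f'<indexListOffset>{index_list_offset}</indexListOffset>\n')
            self._w('<fileChecksum>')
            # SHA-1 over every byte up to and including the ">" just written
            self._f.flush()
            stop = self._f.tell()
            sha = hashlib.sha1()
            self._f.seek(0)
            remaining = stop
            while remaining:
                chunk = self._f.read(min(1 << 20, remaining))
                if not chunk:
                    break
                sha.update(chunk)
                remaining -= len(chunk)
            digest = sha.hexdigest()
            self._f.seek(stop)
            self._w(f'{digest}</fileChecksum>\n</indexedmzML>\n')
            self.report.checksum = digest

        self._f.close()
        self._state = "done"
        return self.report

    def abort(self) -> None:
        """Close and remove a partially written file after a failure."""
        import os
        try:
            self._f.close()
        finally:
            if os.path.exists(self.path):
                os.unlink(self.path)
        self._state = "done"


def write_mzml(source, path, *, indexed: bool = False, precision: int = 64,
               compression: str = "none", gzip_output: bool = False) -> WriteReport:
    """Write an :class:`Experiment` to (indexed) mzML.

    ``gzip_output`` post-compresses the finished document; the recorded
    offsets keep addressing the uncompressed stream, so such files support
    streaming but not random access.
    """
    writer = MzMLWriter(path, indexed=indexed, precision=precision,
                        compression=compression,
                        run_id=source.settings.run_id or None)
    try:
        writer.set_experimental_settings(source.settings)
        writer.set_expected_size(len(source.spectra), len(source.chromatograms))
        for s in source.spectra:
            writer.consume_spectrum(s)
        for c in source.chromatograms:
            writer.consume_chromatogram(c)
        report = writer.finalize()
    except BaseException:
        writer.abort()
        raise
    if gzip_output:
        gzip_in_place(path)
    return report


def gzip_in_place(path, mtime: int = 0) -> None:
    """Replace a file with its gzip-wrapped equivalent (deterministic:
    fixed mtime, no original-name header)."""
    import os
    import shutil
    tmp = str(path) + ".gz.tmp"
    with open(path, "rb") as src, open(tmp, "wb") as dst:
        with gzip.GzipFile(fileobj=dst, mode="wb", filename="", mtime=mtime) as gz:
            shutil.copyfileobj(src, gz)
    os.replace(tmp, path)


class _FilterWriter:
    """RT-filtering writer: the streaming reader drops out-of-window spectra
    via StreamOptions and this consumer forwards the rest to an MzMLWriter."""

    def __init__(self, writer: MzMLWriter):
        self.writer = writer
        self.n_retained = 0

    def set_experimental_settings(self, settings):
        self.writer.set_experimental_settings(settings)

    def set_expected_size(self, n_spectra, n_chromatograms):
        self.writer.set_expected_size(n_spectra, n_chromatograms)

    def consume_spectrum(self, s):
        s = Spectrum(
            native_id=s.native_id, index=self.n_retained, ms_level=s.ms_level,
            retention_time=s.retention_time, mz=s.mz, intensity=s.intensity,
            precursor_mz=s.precursor_mz,
            precursor_isolation_lower=s.precursor_isolation_lower,
            precursor_isolation_upper=s.precursor_isolation_upper,
            centroided=s.centroided,
        )
        self.n_retained += 1
        self.writer.consume_spectrum(s)

    def consume_chromatogram(self, c):
        self.writer.consume_chromatogram(c)

    def finalize(self):
        self.writer.finalize()


def filter_rt(path_in, path_out, rt_start: float, rt_end: float, *,
              indexed: bool = True, precision: int = 64,
              compression: str = "none") -> int:
    """Copy a file keeping only spectra whose retention time lies in the
    closed window ``[rt_start, rt_end]`` (both boundary scans retained);
    chromatograms pass through.  Runs as a memory-bounded consumer chain and
    returns the number of spectra retained."""
    if rt_start > rt_end:
        raise ParameterError("rt_start must be <= rt_end")
    writer = MzMLWriter(path_out, indexed=indexed, precision=precision,
                        compression=compression)
    sink = _FilterWriter(writer)
    try:
        options = StreamOptions(rt_window=(rt_start, rt_end))
        if _looks_like_mzxml(path_in):
            stream_mzxml(path_in, sink, options)
        else:
            stream_mzml(path_in, sink, options)
    except BaseException:
        writer.abort()
        raise
    return sink.n_retained
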