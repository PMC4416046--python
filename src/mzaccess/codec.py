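"""Base64 / IEEE-754 codec for mzML binary data arrays.

mzML stores each peak array as Base64 text wrapping a little-endian sequence
of 32- or 64-bit IEEE-754 floats, optionally zlib-deflated before encoding.
Decoding this text is the hot path of any mzML reader, so the codec is kept
free of per-value Python loops (``base64``/``zlib`` + ``numpy.frombuffer``)
and exposes a batch entry point whose output is bit-identical for any worker
count.

Only little-endian byte order is supported here, as required by mzML; the
mzXML reader byte-swaps its network-order payloads locally.  Compression
schemes outside {none, zlib} (e.g. numpress) are rejected explicitly.
"""

from __future__ import annotations

import base64
import binascii
import zlib
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np

from .errors import CorruptionError, DecodeError, UnsupportedCompressionError

__all__ = [
    "BinaryArrayDescriptor",
    "decode_array",
    "encode_array",
    "decode_many",
    "decode_invocations",
]

PRECISIONS = (32, 64)
COMPRESSIONS = ("none", "zlib")

# Instrumentation: how many times the Base64 text path has run.  The binary
# cache reader must never touch this path; tests assert the counter is flat
# across cache reads.
_decode_calls = 0


def decode_invocations() -> int:
    """Total number of ``decode_array`` calls made so far in this process."""
    return _decode_calls


@dataclass
class BinaryArrayDescriptor:
    """Encoding state of one binary data array.

    Parameters
    ----------
    encoded_text:
        Base64 text, possibly containing whitespace inserted by line-wrapping
        writers (stripped before decoding).
    precision:
        32 or 64 (bits per value).
    compression:
        ``"none"`` or ``"zlib"``.
    declared_length:
        Number of values the surrounding XML declares, or ``None`` when the
        file does not declare one.
    array_role:
        ``"mz"``, ``"intensity"`` or ``"time"`` — informational.
    source_id:
        Native id of the owning spectrum/chromatogram, used in error messages.
    """

    encoded_text: str
    precision: int = 64
    compression: str = "none"
    declared_length: int | None = None
    array_role: str = "intensity"
    source_id: str | None = None


def _where(d: BinaryArrayDescriptor) -> str:
    return f" (in {d.source_id!r})" if d.source_id else ""


def decode_array(d: BinaryArrayDescriptor) -> np.ndarray:
    """Decode one descriptor to a float64 array.

    32-bit payloads are widened to float64 without change of represented
    value.  Raises :class:`DecodeError` on malformed Base64,
    :class:`CorruptionError` on zlib failure, indivisible byte counts or a
    declared-length mismatch, and :class:`UnsupportedCompressionError` for
    unknown compression schemes.
    """
    global _decode_calls
    _decode_calls += 1

    if d.precision not in PRECISIONS:
        raise CorruptionError(f"unsupported precision {d.precision}{_where(d)}")
    if d.compression not in COMPRESSIONS:
        raise UnsupportedCompressionError(
            f"unsupported compression {d.compression!r}{_where(d)}; "
            "only 'none' and 'zlib' are handled"
        )

    text = "".join(d.encoded_text.split())  # some writers wrap lines
    try:
        raw = base64.b64decode(text.encode("ascii"), validate=True)
    except (binascii.Error, ValueError, UnicodeEncodeError) as exc:
        raise DecodeError(f"malformed Base64{_where(d)}: {exc}") from exc

    if d.compression == "zlib":
        try:
            raw = zlib.decompress(raw)
        except zlib.error as exc:
            raise CorruptionError(f"zlib decompression failed{_where(d)}: {exc}") from exc

    width = d.precision // 8
    if len(raw) % width:
        raise CorruptionError(
            f"payload of {len(raw)} bytes not divisible by value width {width}{_where(d)}"
        )
    dtype = np.dtype("<f4") if d.precision == 32 else np.dtype("<f8")
    values = np.frombuffer(raw, dtype=dtype).astype(np.float64)

    if d.declared_length is not None and len(values) != d.declared_length:
        raise CorruptionError(
            f"declared length {d.declared_length} but decoded {len(values)} "
            f"values{_where(d)}"
        )
    return values


def encode_array(
    values,
    precision: int = 64,
    compression: str = "none",
    *,
    array_role: str = "intensity",
    allow_non_finite: bool = False,
) -> BinaryArrayDescriptor:
    """Encode a float array into a :class:`BinaryArrayDescriptor`.

    Round-trip guarantee: ``decode_array(encode_array(v))`` reproduces ``v``
    bit-exactly at 64-bit precision, and after rounding each value to the
    nearest 32-bit float at 32-bit precision.
    """
    if precision not in PRECISIONS:
        raise ValueError(f"precision must be one of {PRECISIONS}")
    if compression not in COMPRESSIONS:
        raise UnsupportedCompressionError(f"unsupported compression {compression!r}")

    arr = np.asarray(values, dtype=np.float64)
    if arr.size and not allow_non_finite and not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in array; pass allow_non_finite=True to keep them")

    dtype = np.dtype("<f4") if precision == 32 else np.dtype("<f8")
    raw = arr.astype(dtype).tobytes()
    if compression == "zlib":
        raw = zlib.compress(raw)
    return BinaryArrayDescriptor(
        encoded_text=base64.b64encode(raw).decode("ascii"),
        precision=precision,
        compression=compression,
        declared_length=int(arr.size),
        array_role=array_role,
    )


def decode_many(
    descriptors: list[BinaryArrayDescriptor], workers: int = 1
) -> tuple[list[np.ndarray | None], list[tuple[int, Exception]]]:
    """Decode a batch of descriptors, optionally on several threads.

    Returns ``(arrays, errors)`` where ``arrays[i]`` is the decoded array for
    ``descriptors[i]`` or ``None`` if it failed, and ``errors`` lists
    ``(position, exception)`` pairs.  The output is identical — bit-exact and
    in input order — for every ``workers`` value; ``workers=1`` is the plain
    serial path.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")

    def attempt(d: BinaryArrayDescriptor):
        try:
            return decode_array(d), None
        except Exception as exc:  # error isolation: remaining elements proceed
            return None, exc

    if workers == 1 or len(descriptors) <= 1:
        results = [attempt(d) for d in descriptors]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(attempt, descriptors))

    arrays = [arr for arr, _ in results]
    errors = [(i, exc) for i, (_, exc) in enumerate(results) if exc is not None]
    return arrays, errors


def _decode_raw(raw: bytes, precision: int, byte_order: str = "<") -> np.ndarray:
    """Bytes → float64 array at a given byte order; helper for the mzXML
    reader (network order) and the cache reader."""
    width = precision // 8
    if len(raw) % width:
        raise CorruptionError(f"payload of {len(raw)} bytes not divisible by {width}")
    dtype = np.dtype(f"{byte_order}f{width}")
    return np.frombuffer(raw, dtype=dtype).astype(np.float64)
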