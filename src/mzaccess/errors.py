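"""Exception hierarchy for mzaccess.

Every failure mode of the readers, writers and the cache format maps to a
distinct class so that callers (and the CLI exit-code logic) can tell a
malformed file from a missing index from a usage error.
"""

from __future__ import annotations


class MzAccessError(Exception):
    """Base class for all mzaccess errors."""


class ParseError(MzAccessError):
    """XML well-formedness or structural error while reading a file.

    Carries ``byte_position`` when the underlying parser reports one, and
    ``records_delivered`` when the failure happened mid-stream after some
    complete records had already been handed to the consumer.
    """

    def __init__(self, message: str, *, byte_position: int | None = None,
                 records_delivered: int | None = None):
        super().__init__(message)
        self.byte_position = byte_position
        self.records_delivered = records_delivered


class CorruptionError(MzAccessError):
    """Binary payload is damaged: bad Base64, failed zlib inflate, byte
    count not divisible by the precision width, or a declared-length
    mismatch."""


class DecodeError(CorruptionError):
    """Malformed Base64 text; names the offending spectrum where known."""


class UnsupportedCompressionError(MzAccessError):
    """A compression scheme outside {none, zlib} was declared (e.g. numpress)."""


class IndexMissingError(MzAccessError):
    """No usable byte-offset index at the file tail; streaming access or
    re-indexing is required instead."""


class GzipRandomAccessError(MzAccessError):
    """Random access requested on a gzip-wrapped file, whose stored byte
    offsets do not address the compressed stream."""


class IntegrityError(MzAccessError):
    """Declared checksum does not match the file contents."""


class IdLookupError(MzAccessError, KeyError):
    """Native id not present in the index; carries nearest candidates."""

    def __init__(self, native_id: str, candidates: list[str] | None = None):
        self.native_id = native_id
        self.candidates = candidates or []
        hint = f"; nearest candidates: {self.candidates}" if self.candidates else ""
        super().__init__(f"native id {native_id!r} not found{hint}")


class CacheFormatError(MzAccessError):
    """File is not an mzaccess cache (bad magic) or its entries/trailer
    are damaged."""


class CacheVersionError(CacheFormatError):
    """Cache was written by a newer format version than this reader knows."""


class ParameterError(MzAccessError, ValueError):
    """Invalid user-supplied parameter (even smoothing window, bad RT range)."""
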