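"""Lightweight instrumentation used to verify the memory contract.

Every reader registers each :class:`~mzaccess.model.Spectrum` it materializes
with the process-wide :data:`live_spectra` tracker.  A weak-reference
finalizer decrements the count when the object is garbage collected, so the
tracker reports how many reader-produced spectra are alive at any moment.
Streaming paths must keep this at a small constant; the in-memory mode
legitimately holds the whole run.

CPython's reference counting collects unreferenced spectra immediately,
which makes the high-water mark deterministic in tests.
"""

from __future__ import annotations

import weakref


class LiveObjectTracker:
    """Counts currently-alive tracked objects and the high-water mark."""

    def __init__(self) -> None:
        self.current = 0
        self.high_water = 0

    def track(self, obj) -> None:
        self.current += 1
        if self.current > self.high_water:
            self.high_water = self.current
        weakref.finalize(obj, self._release)

    def _release(self) -> None:
        self.current -= 1

    def reset_high_water(self) -> None:
        """Start a fresh measurement window (alive objects keep counting)."""
        self.high_water = self.current


live_spectra = LiveObjectTracker()


class CountingReader:
    """Binary-file wrapper that accounts every byte read through it.

    Used to prove the lazy-access I/O bound: opening an indexed file plus a
    handful of random reads must touch only the header, the tail index and
    the requested element byte ranges.
    """

    def __init__(self, fileobj):
        self._f = fileobj
        self.bytes_read = 0

    def read(self, n: int = -1) -> bytes:
        data = self._f.read(n)
        self.bytes_read += len(data)
        return data

    def seek(self, pos: int, whence: int = 0) -> int:
        return self._f.seek(pos, whence)

    def tell(self) -> int:
        return self._f.tell()

    def close(self) -> None:
        self._f.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
        return False
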