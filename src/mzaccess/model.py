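"""Domain model shared by every access mode.

A :class:`Spectrum` is one mass-spectrometric scan: paired m/z and intensity
arrays plus acquisition metadata (MS level, retention time in seconds,
precursor selection window for tandem scans).  A :class:`Chromatogram` is an
intensity-versus-time trace.  Whichever access mode produced an object —
full in-memory load, lazy indexed read, binary cache or event-driven
streaming — the resulting objects compare equal field-wise, which is the
basis of all mode-equivalence tests in this package.

Conventions
-----------
* Retention time is always seconds; readers convert from minutes when the
  source file declares minutes.
* ``index`` is the 0-based position in file order, never a number parsed out
  of the vendor-dependent native id.
* Missing optional metadata is ``None``, never a sentinel number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Spectrum",
    "Chromatogram",
    "ExperimentalSettings",
    "Experiment",
    "total_ion_current",
    "peak_count",
]


def _as_f64(values) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 1:
        raise ValueError("peak arrays must be one-dimensional")
    return arr


def _arrays_equal(a: np.ndarray, b: np.ndarray) -> bool:
    # Exact equality including NaN positions; used by round-trip tests.
    return a.shape == b.shape and bool(np.array_equal(a, b, equal_nan=True))


def _opt_eq(a, b) -> bool:
    if a is None or b is None:
        return a is None and b is None
    if isinstance(a, float) and isinstance(b, float):
        if math.isnan(a) and math.isnan(b):
            return True
    return a == b


@dataclass(eq=False)
class Spectrum:
    """One scan of a mass-spectrometric run."""

    native_id: str
    index: int
    ms_level: int
    retention_time: float
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))
    precursor_mz: float | None = None
    precursor_isolation_lower: float | None = None
    precursor_isolation_upper: float | None = None
    centroided: bool | None = None

    def __post_init__(self):
        self.mz = _as_f64(self.mz)
        self.intensity = _as_f64(self.intensity)
        if len(self.mz) != len(self.intensity):
            raise ValueError(
                f"spectrum {self.native_id!r}: m/z and intensity lengths differ "
                f"({len(self.mz)} vs {len(self.intensity)})"
            )

    def validate(self) -> None:
        """Check the model invariants; raises ``ValueError`` on violation."""
        if self.index < 0:
            raise ValueError("index must be >= 0")
        if self.ms_level < 1:
            raise ValueError("ms_level must be >= 1")
        if self.retention_time < 0:
            raise ValueError("retention_time must be >= 0 seconds")
        if len(self.mz) and float(np.min(self.mz)) < 0:
            raise ValueError("m/z values must be non-negative")
        if len(self.mz) > 1 and np.any(np.diff(self.mz) < 0):
            raise ValueError(f"spectrum {self.native_id!r}: m/z array not sorted")

    def __eq__(self, other) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            self.native_id == other.native_id
            and self.index == other.index
            and self.ms_level == other.ms_level
            and self.retention_time == other.retention_time
            and _opt_eq(self.precursor_mz, other.precursor_mz)
            and _opt_eq(self.precursor_isolation_lower, other.precursor_isolation_lower)
            and _opt_eq(self.precursor_isolation_upper, other.precursor_isolation_upper)
            and _opt_eq(self.centroided, other.centroided)
            and _arrays_equal(self.mz, other.mz)
            and _arrays_equal(self.intensity, other.intensity)
        )


@dataclass(eq=False)
class Chromatogram:
    """A time/intensity trace (e.g. the total-ion-current chromatogram)."""

    native_id: str
    index: int
    time: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.time = _as_f64(self.time)
        self.intensity = _as_f64(self.intensity)
        if len(self.time) != len(self.intensity):
            raise ValueError(
                f"chromatogram {self.native_id!r}: time and intensity lengths differ"
            )

    def validate(self) -> None:
        if self.index < 0:
            raise ValueError("index must be >= 0")
        if len(self.time) > 1 and np.any(np.diff(self.time) < 0):
            raise ValueError(f"chromatogram {self.native_id!r}: time not non-decreasing")

    def __eq__(self, other) -> bool:
        if not isinstance(other, Chromatogram):
            return NotImplemented
        return (
            self.native_id == other.native_id
            and self.index == other.index
            and _arrays_equal(self.time, other.time)
            and _arrays_equal(self.intensity, other.intensity)
        )


@dataclass
class ExperimentalSettings:
    """Run-level metadata, delivered to consumers before the first spectrum."""

    run_id: str = ""
    instrument_description: str = ""
    source_file_name: str = ""
    spectrum_count_declared: int | None = None
    chromatogram_count_declared: int | None = None

    def validate(self) -> None:
        for n in (self.spectrum_count_declared, self.chromatogram_count_declared):
            if n is not None and n < 0:
                raise ValueError("declared counts must be non-negative")


@dataclass(eq=False)
class Experiment:
    """A fully materialized run: the "random access in memory" mode container."""

    settings: ExperimentalSettings = field(default_factory=ExperimentalSettings)
    spectra: list[Spectrum] = field(default_factory=list)
    chromatograms: list[Chromatogram] = field(default_factory=list)

    def validate(self) -> None:
        ids = [s.native_id for s in self.spectra]
        if len(set(ids)) != len(ids):
            raise ValueError("spectrum native_ids are not unique")
        for i, s in enumerate(self.spectra):
            if s.index != i:
                raise ValueError(f"spectrum {i} carries index {s.index}")

    def __len__(self) -> int:
        return len(self.spectra)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Experiment):
            return NotImplemented
        return (
            self.spectra == other.spectra
            and self.chromatograms == other.chromatograms
        )


def total_ion_current(s: Spectrum) -> float:
    """Sum of the intensity array of one spectrum; 0.0 for an empty scan."""
    return float(np.sum(s.intensity)) if len(s.intensity) else 0.0


def peak_count(s: Spectrum) -> int:
    """Number of (m/z, intensity) pairs recorded in the scan."""
    return int(len(s.mz))
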