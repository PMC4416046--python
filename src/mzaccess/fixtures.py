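"""Deterministic synthetic LC-MS/MS data generator.

Real next-generation acquisition runs (e.g. SWATH-MS) are tens of gigabytes
and unsuitable as test payloads, so every reader, writer and access mode in
this package is exercised against files produced here: desk-scale mzML and
mzXML documents in all dialect variants (32/64-bit, zlib/none, plain/indexed,
raw/gzip, with and without chromatograms), each paired with a
:class:`GroundTruth` computed from the in-memory arrays *before* any file is
written — a genuinely independent oracle for every reader path.

A fixed seed fully determines the output bytes: the random generator is
seeded per spec, the writer is deterministic, and gzip wrapping uses a zero
mtime.  The generator makes no attempt at realistic isotope envelopes,
noise models or chromatographic peak shapes; peak *positions* and simple
Gaussian bumps are enough to test data access machinery.
"""

from __future__ import annotations

import base64
import gzip as _gzip
import os
import zlib as _zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .model import Chromatogram, Experiment, ExperimentalSettings, Spectrum
from .mzml import gzip_in_place, write_mzml

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "build_experiment",
    "generate",
    "generate_mzxml",
    "generate_matrix",
    "generate_corrupted",
    "SMALL",
    "LARGE",
]


@dataclass
class FixtureSpec:
    """Recipe for one synthetic run.

    ``peaks_per_spectrum`` is either a fixed int or an inclusive
    ``(lo, hi)`` range sampled per spectrum; ``ms_level_pattern`` repeats
    over the run (e.g. ``[1, 2, 2]`` = one survey scan followed by two
    fragment scans); ``intensity_model`` is one of ``constant``,
    ``uniform`` or ``gaussian``.
    """

    n_spectra: int = 100
    peaks_per_spectrum: int | tuple[int, int] = 50
    ms_level_pattern: tuple[int, ...] = (1,)
    rt_start: float = 0.0
    rt_step: float = 1.0
    mz_range: tuple[float, float] = (100.0, 1500.0)
    intensity_model: str = "constant"
    constant_intensity: float = 1.0
    seed: int = 42
    precision: int = 64
    compression: str = "none"
    indexed: bool = True
    gzip_wrapped: bool = False
    n_chromatograms: int = 0

    def __post_init__(self):
        if self.intensity_model not in ("constant", "uniform", "gaussian"):
            raise ValueError(f"unknown intensity model {self.intensity_model!r}")


# Default desk-scale sizes: SMALL for unit tests, LARGE for memory-bound and
# scaling checks.
SMALL = FixtureSpec(n_spectra=100, peaks_per_spectrum=50)
LARGE = FixtureSpec(n_spectra=10_000, peaks_per_spectrum=50)


@dataclass
class GroundTruth:
    """What the generated run truly contains, computed from the in-memory
    arrays at generation time (never re-derived from the files)."""

    native_ids: list[str] = field(default_factory=list)
    ms_levels: list[int] = field(default_factory=list)
    retention_times: list[float] = field(default_factory=list)
    mz_arrays: list[np.ndarray] = field(default_factory=list)
    intensity_arrays: list[np.ndarray] = field(default_factory=list)
    per_spectrum_tic: list[float] = field(default_factory=list)
    per_spectrum_peaks: list[int] = field(default_factory=list)
    peak_argmax: list[int] = field(default_factory=list)  # gaussian model only
    total_tic: float = 0.0
    total_peaks: int = 0
    n_chromatograms: int = 0
    file_bytes: int = 0

    @property
    def n_spectra(self) -> int:
        return len(self.native_ids)


def _round_to_precision(arr: np.ndarray, precision: int) -> np.ndarray:
    if precision == 32:
        return arr.astype("<f4").astype(np.float64)
    return arr.astype(np.float64)


def build_experiment(spec: FixtureSpec) -> tuple[Experiment, GroundTruth]:
    """Materialize the run and its ground truth without touching disk.

    Arrays in the ground truth are pre-rounded to the spec's storage
    precision, so readers must reproduce them bit-exactly.
    """
    rng = np.random.default_rng(spec.seed)
    truth = GroundTruth()
    exp = Experiment(settings=ExperimentalSettings(run_id=f"synthetic_run_{spec.seed}"))
    lo_mz, hi_mz = spec.mz_range

    for i in range(spec.n_spectra):
        if isinstance(spec.peaks_per_spectrum, tuple):
            n_peaks = int(rng.integers(spec.peaks_per_spectrum[0],
                                       spec.peaks_per_spectrum[1] + 1))
        else:
            n_peaks = int(spec.peaks_per_spectrum)
        ms_level = spec.ms_level_pattern[i % len(spec.ms_level_pattern)]
        rt = spec.rt_start + i * spec.rt_step

        mz = np.sort(rng.uniform(lo_mz, hi_mz, n_peaks))
        argmax = -1
        if spec.intensity_model == "constant":
            intensity = np.full(n_peaks, spec.constant_intensity)
        elif spec.intensity_model == "uniform":
            intensity = rng.uniform(0.0, 1000.0, n_peaks)
        else:  # gaussian bump over the m/z grid
            center = rng.uniform(lo_mz + 0.1 * (hi_mz - lo_mz),
                                 hi_mz - 0.1 * (hi_mz - lo_mz))
            sigma = 0.05 * (hi_mz - lo_mz)
            intensity = 1000.0 * np.exp(-0.5 * ((mz - center) / sigma) ** 2)
            argmax = int(np.argmax(intensity)) if n_peaks else -1

        mz = _round_to_precision(mz, spec.precision)
        intensity = _round_to_precision(intensity, spec.precision)

        precursor = None
        iso_lower = iso_upper = None
        if ms_level >= 2:
            precursor = float(np.round(rng.uniform(400.0, 1000.0), 4))
            iso_lower = iso_upper = 1.0  # symmetric, representable in mzXML

        s = Spectrum(
            native_id=f"scan={i + 1}",
            index=i,
            ms_level=ms_level,
            retention_time=rt,
            mz=mz,
            intensity=intensity,
            precursor_mz=precursor,
            precursor_isolation_lower=iso_lower,
            precursor_isolation_upper=iso_upper,
        )
        exp.spectra.append(s)
        truth.native_ids.append(s.native_id)
        truth.ms_levels.append(ms_level)
        truth.retention_times.append(rt)
        truth.mz_arrays.append(mz)
        truth.intensity_arrays.append(intensity)
        tic = float(np.sum(intensity)) if n_peaks else 0.0
        truth.per_spectrum_tic.append(tic)
        truth.per_spectrum_peaks.append(n_peaks)
        truth.peak_argmax.append(argmax)
        truth.total_tic += tic
        truth.total_peaks += n_peaks

    rts = np.asarray(truth.retention_times, dtype=np.float64)
    tics = np.asarray(truth.per_spectrum_tic, dtype=np.float64)
    for j in range(spec.n_chromatograms):
        if j == 0:
            c = Chromatogram(native_id="TIC", index=0,
                             time=_round_to_precision(rts, spec.precision),
                             intensity=_round_to_precision(tics, spec.precision))
        else:
            trace = rng.uniform(0.0, 10.0, spec.n_spectra)
            c = Chromatogram(
                native_id=f"trace={j}", index=j,
                time=_round_to_precision(rts, spec.precision),
                intensity=_round_to_precision(trace, spec.precision))
        exp.chromatograms.append(c)
    truth.n_chromatograms = spec.n_chromatograms
    return exp, truth


def generate(spec: FixtureSpec, path) -> tuple[str, GroundTruth]:
    """Write the run described by ``spec`` to ``path`` as mzML.

    Identical spec (including seed) produces byte-identical files.
    """
    exp, truth = build_experiment(spec)
    write_mzml(exp, path, indexed=spec.indexed, precision=spec.precision,
               compression=spec.compression, gzip_output=spec.gzip_wrapped)
    truth.file_bytes = os.path.getsize(path)
    return str(path), truth


def _mzxml_peaks_b64(mz: np.ndarray, intensity: np.ndarray, precision: int,
                     compression: str) -> str:
    interleaved = np.empty(2 * len(mz))
    interleaved[0::2] = mz
    interleaved[1::2] = intensity
    raw = interleaved.astype(f">f{precision // 8}").tobytes()  # network order
    if compression == "zlib":
        raw = _zlib.compress(raw)
    return base64.b64encode(raw).decode("ascii")


def generate_mzxml(spec: FixtureSpec, path) -> tuple[str, GroundTruth]:
    """Write the same logical run as mzXML 3.x (nested-scan layout:
    fragment scans sit inside their parent survey scan)."""
    exp, truth = build_experiment(spec)
    lines = [
        '<?xml version="1.0" encoding="ISO-8859-1"?>',
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">',
        f'<msRun scanCount="{len(exp.spectra)}">',
    ]
    open_parent = False
    for s in exp.spectra:
        if s.ms_level == 1 and open_parent:
            lines.append('</scan>')
            open_parent = False
        num = s.native_id.split("=", 1)[1]
        attrs = (f'num="{num}" msLevel="{s.ms_level}" '
                 f'retentionTime="PT{s.retention_time!r}S" '
                 f'peaksCount="{len(s.mz)}"')
        lines.append(f'<scan {attrs}>')
        if s.precursor_mz is not None:
            ww = ''
            if s.precursor_isolation_lower is not None:
                ww = f' windowWideness="{2.0 * s.precursor_isolation_lower!r}"'
            lines.append(f'<precursorMz precursorIntensity="0"{ww}>'
                         f'{s.precursor_mz!r}</precursorMz>')
        b64 = _mzxml_peaks_b64(s.mz, s.intensity, spec.precision, spec.compression)
        comp = ('compressionType="zlib"' if spec.compression == "zlib"
                else 'compressionType="none"')
        lines.append(f'<peaks precision="{spec.precision}" byteOrder="network" '
                     f'contentType="m/z-int" {comp}>{b64}</peaks>')
        if s.ms_level == 1:
            open_parent = True  # nest following MS2 scans inside
        else:
            lines.append('</scan>')
    if open_parent:
        lines.append('</scan>')
    lines += ['</msRun>', '</mzXML>', '']
    with open(path, "wb") as f:
        f.write("\n".join(lines).encode("ascii"))
    if spec.gzip_wrapped:
        gzip_in_place(path)
    truth.file_bytes = os.path.getsize(path)
    return str(path), truth


def generate_matrix(outdir, base: FixtureSpec | None = None):
    """Generate the full dialect matrix — {32,64}-bit × {none,zlib} ×
    {plain,indexed} × {raw,gzip} × {without,with chromatograms} — plus a
    tab-separated manifest.  Returns ``{name: (path, spec, GroundTruth)}``.
    """
    os.makedirs(outdir, exist_ok=True)
    base = base or replace(SMALL, n_spectra=20, peaks_per_spectrum=25,
                           ms_level_pattern=(1, 2, 2),
                           intensity_model="uniform")
    suite: dict[str, tuple[str, FixtureSpec, GroundTruth]] = {}
    rows = ["name\tprecision\tcompression\tindexed\tgzip\tn_chromatograms"
            "\tn_spectra\ttotal_peaks\ttotal_tic"]
    for precision in (32, 64):
        for compression in ("none", "zlib"):
            for indexed in (False, True):
                for gz in (False, True):
                    for n_chrom in (0, 2):
                        name = (f"p{precision}_{compression}"
                                f"_{'idx' if indexed else 'plain'}"
                                f"_{'gz' if gz else 'raw'}_c{n_chrom}")
                        spec = replace(base, precision=precision,
                                       compression=compression,
                                       indexed=indexed, gzip_wrapped=gz,
                                       n_chromatograms=n_chrom)
                        path = os.path.join(outdir, name + ".mzML")
                        _, truth = generate(spec, path)
                        suite[name] = (path, spec, truth)
                        rows.append(
                            f"{name}\t{precision}\t{compression}\t{indexed}"
                            f"\t{gz}\t{n_chrom}\t{truth.n_spectra}"
                            f"\t{truth.total_peaks}\t{truth.total_tic!r}")
    with open(os.path.join(outdir, "manifest.tsv"), "w") as f:
        f.write("\n".join(rows) + "\n")
    return suite


def generate_corrupted(outdir, base: FixtureSpec | None = None) -> dict[str, str]:
    """Generate deliberately damaged siblings of a healthy indexed fixture,
    one per designated error path.

    Returns ``{kind: path}`` with kinds: ``flipped_payload_byte``,
    ``truncated_tail``, ``broken_index_digits``, ``gzip_indexed``,
    ``unsupported_compression``.
    """
    os.makedirs(outdir, exist_ok=True)
    base = base or replace(SMALL, n_spectra=10, peaks_per_spectrum=20)
    healthy = os.path.join(outdir, "healthy.mzML")
    generate(replace(base, indexed=True, gzip_wrapped=False), healthy)
    with open(healthy, "rb") as f:
        data = f.read()
    out: dict[str, str] = {}

    # flip one byte inside a Base64 payload ("A" and "B" decode differently)
    p = data.find(b"<binary>") + len(b"<binary>")
    flipped = bytearray(data)
    flipped[p + 5] = ord("!") if flipped[p + 5] != ord("!") else ord("?")
    out["flipped_payload_byte"] = _write(outdir, "flipped.mzML", bytes(flipped))

    out["truncated_tail"] = _write(outdir, "truncated.mzML",
                                   data[: int(len(data) * 0.6)])

    q = data.rfind(b"<indexListOffset>") + len(b"<indexListOffset>")
    broken = data[:q] + b"xx" + data[q + 2:]
    out["broken_index_digits"] = _write(outdir, "broken_index.mzML", broken)

    gz_path = os.path.join(outdir, "gzipped_indexed.mzML")
    with open(gz_path, "wb") as f:
        f.write(data)
    gzip_in_place(gz_path)
    out["gzip_indexed"] = gz_path

    # declare a numpress compression accession on the first binary array
    numpress = data.replace(
        b'accession="MS:1000576" name="no compression"',
        b'accession="MS:1002312" name="MS-Numpress linear prediction compression"',
        1)
    out["unsupported_compression"] = _write(outdir, "numpress.mzML", numpress)
    return out


def _write(outdir, name, payload: bytes) -> str:
    path = os.path.join(outdir, name)
    with open(path, "wb") as f:
        f.write(payload)
    return path
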