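"""Lazy random access with byte-level I/O accounting.

Opens an indexed mzML file — reading only the document head and the tail
index — then fetches a handful of spectra by position and by native id.
The handle counts every byte it reads, demonstrating that access cost is
proportional to what you fetch, not to file size.
"""

import tempfile
from pathlib import Path

import mzaccess as mz
from mzaccess import fixtures

workdir = Path(tempfile.mkdtemp())
path, truth = fixtures.generate(
    fixtures.FixtureSpec(n_spectra=1000, peaks_per_spectrum=50,
                         intensity_model="uniform", indexed=True,
                         n_chromatograms=2, seed=3),
    workdir / "big.mzML")

with mz.open_indexed(path) as handle:
    print(f"file size: {handle.file_size} bytes; "
          f"bytes read at open: {handle.bytes_read} "
          f"({100 * handle.bytes_read / handle.file_size:.1f}%)")
    print(f"counts: {handle.counts()[0]} spectra, "
          f"{handle.counts()[1]} chromatograms")

    s = handle.get_spectrum_by_index(500)
    print(f"spectrum 500: id={s.native_id!r}, RT={s.retention_time} s, "
          f"{mz.peak_count(s)} peaks, TIC={mz.total_ion_current(s):.1f}")
    s2 = handle.get_spectrum_by_id("scan=7")
    print(f"by id 'scan=7': index {s2.index}, MS level {s2.ms_level}")
    tic_trace = handle.get_chromatogram_by_id("TIC")
    print(f"TIC chromatogram: {len(tic_trace.time)} points")

    frac = handle.bytes_read / handle.file_size
    print(f"total bytes read after all fetches: {handle.bytes_read} "
          f"({100 * frac:.1f}% of the file)")

print("checksum verifies:", mz.verify_checksum(path))
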