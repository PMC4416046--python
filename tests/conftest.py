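"""Shared synthetic-data fixtures.

All test inputs are generated at session start by the package's own
deterministic generator; the paired GroundTruth objects are computed from
the in-memory arrays before any file is written, so they are independent of
every reader under test.
"""

from dataclasses import replace

import pytest

from mzaccess import fixtures


@pytest.fixture(scope="session")
def constant_run(tmp_path_factory):
    """100 spectra x 50 peaks, all intensities 1.0 -> run TIC 5000 by
    construction."""
    spec = fixtures.FixtureSpec(n_spectra=100, peaks_per_spectrum=50,
                                intensity_model="constant",
                                constant_intensity=1.0, indexed=True)
    path = tmp_path_factory.mktemp("constant") / "constant.mzML"
    _, truth = fixtures.generate(spec, path)
    return str(path), spec, truth


@pytest.fixture(scope="session")
def mixed_run(tmp_path_factory):
    """Interleaved MS1/MS2 run with random intensities and chromatograms —
    the workhorse fixture for equivalence tests."""
    spec = fixtures.FixtureSpec(n_spectra=60, peaks_per_spectrum=(10, 60),
                                ms_level_pattern=(1, 2, 2),
                                intensity_model="uniform",
                                n_chromatograms=2, indexed=True, seed=7)
    path = tmp_path_factory.mktemp("mixed") / "mixed.mzML"
    _, truth = fixtures.generate(spec, path)
    return str(path), spec, truth


@pytest.fixture(scope="session")
def matrix_suite(tmp_path_factory):
    """The full dialect matrix: {32,64}-bit x {none,zlib} x {plain,indexed}
    x {raw,gzip} x {0,2 chromatograms}."""
    outdir = tmp_path_factory.mktemp("matrix")
    return fixtures.generate_matrix(str(outdir))


@pytest.fixture(scope="session")
def corrupted_suite(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("corrupted")
    return fixtures.generate_corrupted(str(outdir))


@pytest.fixture(scope="session")
def large_run(tmp_path_factory):
    """10,000-spectrum run for memory-contract and scaling checks."""
    spec = replace(fixtures.LARGE, ms_level_pattern=(1, 2, 2),
                   intensity_model="uniform", indexed=True)
    path = tmp_path_factory.mktemp("large") / "large.mzML"
    _, truth = fixtures.generate(spec, path)
    return str(path), spec, truth


@pytest.fixture(scope="session")
def medium_run(tmp_path_factory):
    """1,000-spectrum indexed run for I/O-accounting checks."""
    spec = fixtures.FixtureSpec(n_spectra=1000, peaks_per_spectrum=50,
                                intensity_model="uniform", indexed=True,
                                n_chromatograms=2, seed=11)
    path = tmp_path_factory.mktemp("medium") / "medium.mzML"
    _, truth = fixtures.generate(spec, path)
    return str(path), spec, truth
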