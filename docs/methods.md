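# Methods and design notes

## The data model and its conventions

A `Spectrum` is one scan: a text native id (vendor-dependent, e.g.
`scan=17`), a 0-based `index` equal to its position in file order (never
derived from numbers inside the native id), an MS level ≥ 1, a retention
time, paired float64 `mz`/`intensity` arrays of equal length, an optional
precursor description (target m/z plus lower/upper isolation-window offsets,
in Th) and an optional centroided flag. A `Chromatogram` is a time/intensity
trace. Conventions that hold everywhere:

* **Retention time is seconds.** Files declaring minutes (mzML unit
  ontology, or the mzXML `PT…M…S` duration notation) are converted on read.
  A single internal unit removes mode-dependent discrepancies.
* **Missing metadata is `None`**, never a sentinel number.
* **Equality is field-wise and bit-exact** on arrays (NaN-aware). This is
  deliberate: the package's central claim is that all four access modes
  yield identical objects, and a tolerance-based comparison would weaken
  that claim into an approximation.
* After decoding, m/z arrays are checked non-negative and sorted
  non-decreasing; a violation is a data error, not a normalization step.

## Binary-array codec

mzML stores each peak array as Base64 text over a little-endian IEEE-754
sequence (32- or 64-bit), optionally zlib-deflated before encoding. The
codec is vectorized (`base64`/`zlib` plus `numpy.frombuffer`; no per-value
Python loop) and enforces, in order: valid Base64 (whitespace stripped
first, since some writers wrap lines), a valid zlib stream, a byte count
divisible by the value width, and agreement with the declared array length.
32-bit values are widened to float64 without change of represented value.
Only `none` and `zlib` are accepted; numpress-family accessions raise an
explicit unsupported-compression error rather than being skipped silently.
mzXML's network (big-endian) byte order is handled locally by the mzXML
reader; the codec itself is little-endian only, as mzML requires.

`decode_many(descriptors, workers)` decodes a batch on a thread pool.
Results are returned in input order and are bit-identical for every worker
count (`workers=1` is the plain serial path); a malformed element yields a
positioned error report while the remaining elements still decode. The
streaming readers decode each record's arrays through this entry point, so
thread count can never affect event order or numeric output.

## Streaming reader and writer

Both readers are incremental-parse loops (lxml `iterparse`) that clear each
record's XML subtree as soon as the record has been delivered, so the
parsed-tree footprint is constant in run length. Gzip wrapping is detected
by magic bytes, never by file name. The consumer receives run settings and
the header's declared sizes before the first record. The declared counts
are forwarded for pre-sizing only; element parsing is authoritative, and a
mismatch produces a warning, not an error. When a header field (e.g. the
chromatogram count, which mzML declares after all spectra) is unknown at
that point, 0 is sent. mzXML nests fragment scans inside their parent
survey scan; records are emitted when each scan's `<peaks>` element
completes, which reproduces document order with parents first.

A truncated or malformed file raises a parse error carrying the byte
position and the number of complete records already delivered — leading
records are always handed over before the failure surfaces.

The writer emits records as they arrive (usable as the tail of a consumer
chain). Two layout choices make single-pass writing compatible with the
header's count attributes and the tail checksum:

* counts are written as fixed-width zero-padded placeholders (valid
  `xs:nonNegativeInteger` lexical forms) and patched in place at
  finalization, so earlier bytes never move;
* for indexed output, finalization appends the offset index and
  `indexListOffset`, writes the opening `<fileChecksum>` tag, then re-reads
  the file from the start to compute the digest before appending it.

Index and checksum conventions (normative for this package, chosen for
interoperability with common readers): each offset is the byte position,
from the start of the uncompressed file, of the `<` opening the
`<spectrum`/`<chromatogram` element; the checksum is the lowercase-hex
SHA-1 of every byte up to and including the `>` of the opening
`<fileChecksum>` tag. The writer's output is read back bit-exactly by
Bioconductor's mzR (ProteoWizard), which the test suite checks.

## Indexed (lazy) access

Opening scans the file tail backwards for `<indexListOffset>` in a window
that starts at 1 KiB and doubles up to 1 MiB — robust against long footers
without ever reading the whole file — then parses the index region and the
first 8 KiB of header. Each fetch reads only the byte range between the
requested offset and the next recorded offset, truncated at the element's
closing tag. If an offset does not land on `<`, the reader resynchronizes
by scanning forward up to 1 KiB (tolerating writers that include leading
whitespace) before declaring corruption. By-id lookup is an exact text
match after XML unescaping; an unknown id reports the nearest candidate
ids. Fetched spectra are not cached: every access re-reads the file, which
keeps memory constant and semantics trivial — callers wanting cheap
repeated access should use the binary cache instead. Gzip-wrapped input is
refused with an explanation (stored offsets address the uncompressed
stream), and a missing index never triggers a silent full scan; the CLI's
`get --allow-full-scan` is the explicit opt-in.

## Binary cache

The cache trades one streaming conversion pass for random reads that do no
text decoding at all (the test suite asserts the Base64 codec is never
invoked on the cache read path). All values are stored at 64-bit
regardless of source precision — simplicity and exact mode-equivalence
were preferred over compactness. Byte order is fixed little-endian in the
format itself, so cache files are portable across architectures; the cost
is a byte swap on big-endian hosts, which are rare. The cache stores a
minimal metadata subset (id, MS level, retention time, precursor m/z,
arrays; chromatograms: id and arrays) — full run metadata must come from
the companion mzML, and the cache should be treated as an intermediate
working format, not archival storage. A stored SHA-1 of the source file
lets `is_stale()` flag a cache whose source has changed. The byte layout
is specified in `docs/cache_format.md`.

## Consumers and chaining

The consumer contract is four required operations plus an optional fifth,
`finalize()`, added so that file-writing consumers can flush, patch
headers and append indices; readers call it when present. Consumers
declare themselves *observers* (watch the stream: TIC summary, no-op) or
*transformers* (`is_transformer = True`: rewrite each record) so that chain
semantics are unambiguous: a chain forwards each event to its members in
list order, a transformer's output replaces the record for everything
after it, and a transformer producing no output (the RT filter) stops the
record's propagation.

The smoothing and peak-picking stages are deliberately minimal
demonstration algorithms: a centered moving average with edge truncation
(window shrinks near the boundaries, keeping the mean unbiased), and
strict-local-maximum picking (greater than both neighbours, at or above an
intensity threshold; boundary points are never peaks; picked spectra are
flagged centroided). They exist to demonstrate pipeline chaining under the
constant-memory bound and make no claim of scientific-grade signal
processing — no Savitzky–Golay, wavelet or fitted-centroid methods.

## Memory and I/O instrumentation

Two claims are tested directly rather than asserted. A process-wide
tracker counts reader-materialized spectra via weak-reference finalizers
(CPython's reference counting makes the high-water mark deterministic):
streaming, indexed and cached iteration over a 10,000-spectrum run stay at
≤ 2 live spectra while the in-memory mode holds all 10,000. A counting
file wrapper accounts every byte the indexed handle reads: opening a
1,000-spectrum file costs < 5% of its bytes, and ten random fetches keep
the total < 10%. Peak resident memory is compared across fresh child
interpreters (`resource.getrusage`), streaming a 10,000-spectrum file
within 2× of a 1,000-spectrum file.

## Synthetic data

The generator emulates the structural envelope of an LC-MS/MS run —
interleaved MS1/MS2 patterns, sorted m/z arrays, monotone retention times,
precursor windows, a TIC chromatogram — across every format dialect
({32,64}-bit × {none,zlib} × {plain,indexed} × {raw,gzip} × {with,without
chromatograms}; 32 variants plus a manifest), and deliberately nothing
else: no isotope envelopes, no noise model, no chromatographic peak
shapes, no vendor metadata quirks. Passing tests therefore demonstrate
correctness of data access, encoding and bookkeeping on well-formed and
deliberately damaged files; they say nothing about algorithmic performance
on real biological signal. Ground truth (arrays, per-spectrum TIC, run
totals, Gaussian-apex positions) is computed from the in-memory arrays at
generation time, pre-rounded to the target storage precision, and never
re-derived from files — readers must reproduce it bit-exactly. A fixed
seed determines output bytes exactly (deterministic writer, zero gzip
mtime). Intensity models: `constant` (exact expected totals by
construction), `uniform`, and `gaussian` (a smooth bump whose recorded
argmax anchors the peak-picker tests). Corrupted siblings — flipped
payload byte, truncated tail, broken index digits, gzip handed to the
indexed mode, a numpress compression accession — cover each designated
error path.

Problem sizes: unit tests use runs of 10–100 spectra; equivalence and
closure tests run the 32-variant matrix at 20 spectra × ~25 peaks; memory
and scaling checks use 10,000 spectra × 50 peaks (≈ 25 MB mzML). These
desk-scale sizes exercise the same asymptotic properties (constant live
records, sublinear open cost) that matter at the tens-of-gigabytes scale
the architecture targets.

## Other decisions and limitations

* The retention-time filter window is **closed on both ends**; a spectrum
  at exactly the boundary is retained. Stated prominently because
  conventions differ between tools.
* Numbers are serialized with Python's shortest round-trip `repr`, so
  write→read preserves float64 values exactly.
* Unknown CV params are not carried through rewrites; metadata fidelity
  beyond the `Spectrum` fields is best-effort and out of scope.
* mzXML is read-only; mzData and vendor formats are unsupported; no
  numpress; no partial-array (m/z-window) reads; no concurrent cache
  writers.
* Parallelism applies only to binary-array decoding (threads; the codec
  releases the work to zlib/base64/numpy), never to event ordering, so
  results are identical for any thread count by construction.
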