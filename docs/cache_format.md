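# Binary cache format (`.cache` / cached mzML), version 1

Normative byte layout of the mzaccess binary spectrum/chromatogram cache.
All multi-byte integers and floats are **little-endian** on every
architecture; files are portable. Producers must write, and readers must
verify, the magic and version before anything else.

## Header (fixed 68 bytes, at offset 0)

| offset | size | type | field |
|---|---|---|---|
| 0 | 8 | bytes | magic, exactly `MZACCHE1` |
| 8 | 4 | u32 | format version (this document: 1) |
| 12 | 8 | u64 | number of spectrum entries |
| 20 | 8 | u64 | number of chromatogram entries |
| 28 | 40 | ascii | SHA-1 hex of the source file, space-padded; all spaces when absent |
| 68 | 4 | u32 | flags (reserved, 0) |

The counts are written as placeholders during streaming conversion and
patched when the writer finalizes; a reader must treat them as
authoritative and cross-check them against the trailer.

## Entries (immediately after the header, in source file order)

Each entry:

| size | type | field |
|---|---|---|
| 1 | u8 | record kind: 0 = spectrum, 1 = chromatogram |
| 4 | u32 | native id byte length `L` |
| `L` | utf-8 | native id |
| 4 | i32 | MS level (−1 = not applicable, used for chromatograms) |
| 8 | f64 | retention time in seconds (NaN = not applicable) |
| 1 | u8 | precursor present flag (0/1) |
| 8 | f64 | precursor m/z (0.0 when flag is 0) |
| 8 | u64 | point count `n` |
| 8·`n` | f64[] | axis values (m/z for spectra, seconds for chromatograms) |
| 8·`n` | f64[] | intensity values |

All array values are stored at 64-bit regardless of the source file's
precision. An entry's total length is computable from its own fields, so a
sequential scan needs no index.

## Trailer

After the last entry: one u64 byte offset per entry (in file order),
followed by a final u64 holding the byte offset of the trailer's first
entry-offset. A reader locates the trailer from the last 8 bytes of the
file and must verify

```
trailer_offset + 8 * (n_spectra + n_chromatograms) + 8 == file size
```

before trusting it; any mismatch (truncation, overwrite) is a format
error. Entry offsets must be strictly increasing.

## Error handling requirements

* wrong magic → "not a cache file" error;
* version greater than supported → explicit version error (never a guess);
* trailer arithmetic mismatch or truncated entry → corruption error;
* stored source checksum ≠ current source file checksum → stale-cache
  signal (informational, access still permitted).
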