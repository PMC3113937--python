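# Methods

## The model and its assumptions

A chip definition is a grid of `rows × cols` features plus an ordered list
of probe sets, each an ordered list of PM/MM probe pairs.  Coordinates are
0-based with `x` indexing columns and `y` rows; the linear cell index is
`y * cols + x`, matching the INDEX field convention of both CDF dialects.
Validation enforces: positive grid, unique set names, coordinates inside the
grid, no coordinate shared by two probes, non-empty sets, strictly ascending
atom indices, PM ≠ MM coordinates, and (when sequences are present) PM/MM
sequences of equal length differing at exactly one offset.  The common
vendor layout — MM directly below its PM (`mm.y = pm.y + 1`) — is *not*
required, because custom specs may rearrange pairs; `validate_spec`
reports departures only as informational notes.

**PM/MM classification.**  When reading a CDF, a cell is classified PM when
its probe base is the Watson-Crick complement of its target base and MM when
the two are equal.  This is the standard interpretation of the vendor
format's PBASE/TBASE fields; a cell satisfying neither (or a pair where both
cells classify the same way) is a hard parse error rather than a guess.

**MM sequence generation.**  The MM 25-mer is the PM with its central
(13th, 1-based) base complemented.  This is the standard convention for
these arrays; it matters beyond bookkeeping because motif filters search
*both* sequences of a pair, and the MM is usually not present in vendor
sequence files.  The function is an involution (applying it twice returns
the PM), which the tests exploit.  No reverse-complementing is performed
anywhere: motifs are matched on the stored strand only, and the search
scope (PM, MM or both) is a parameter with "both" the default.

**Model equality.**  Two specs are model-equal when chip name, grid,
probe-set names/order, pair membership, coordinates, PBASE/TBASE, atom
order, expos values, interrogation positions and QC blocks agree.
Provenance (dialect, version, custom/parent flags, preserved unknown
headers) is excluded, as are probe sequences by default — neither CDF
dialect stores sequences, so demanding them would make file round-trips
trivially unequal.  `model_equal(..., include_sequences=True)` is available
when annotation state is the point.

## File-format choices

Both writers recompute every declared count (atoms, cells, units) from the
model; nothing is copied through stale.  Round-tripping is a model-level
contract, not byte-identity, for the ASCII dialect (whitespace and key order
are not preserved); the XDA writer *is* byte-deterministic: the same model
always serializes to identical bytes.

* ASCII: the parser binds cell values to fields by the declared
  `CellHeader` column names, never by position, and tolerates LF/CRLF and
  trailing blank lines.  Accepted version tags are GC3.0/GC4.0/GC5.0;
  anything else fails fast with the tag echoed.  Unknown `[Chip]` keys are
  preserved and re-emitted.  Output uses CRLF by default (the vendor
  convention) with an LF option.
* XDA: little-endian throughout, regardless of host; 64-byte NUL-padded
  name table; per-unit file-position table.  Readers accept versions 1-3;
  the writer emits version 1, the layout that fully describes expression
  units (the later versions only extend resequencing payloads, which are
  out of scope).  Two dialect facts shape the API: XDA stores no chip name
  (it is conventionally taken from the file name, so `read_cdf_xda`
  defaults to the path stem and accepts an explicit name) and no per-cell
  interrogation position (set to 13, the central base of a 25-mer, on
  read).  An ASCII file with nonstandard POS values would lose them across
  an XDA round trip — a documented limitation that does not arise on the
  supported arrays.
* QC units are modeled structurally (type plus cells with coordinate,
  probe length and PM/background flags) so they survive cross-dialect
  conversion, but they are opaque to every filter and editor: writers copy
  them verbatim, filters never touch them.

## Filters and reports

A pair's canonical identity is (probe-set name, PM x, PM y).  PM
coordinates anchor all resolution — custom-spec rows carry probe IDs, but
those are labels only, because keep-list inputs typically list only PM
probes and coordinates are the one universal key.

The G-run motif is matched as any occurrence of the substring `GGGG`
(runs of ≥ 4 match trivially); the primer spacer as `CCTCC`.  Matching is
binary — no position weighting — and whole pairs are flagged, never single
probes.  `min_pairs_remaining` defaults to 4 everywhere (filtering,
algebra, CLI) and is overridable; a set falling below the floor is removed
entirely and its surviving pairs count as effective removals in the
conservation accounting (pairs out + removals + pruning losses = pairs in).

`diff_specs` classifies each default set as removed (absent from the
custom spec), modified (present with different pair membership) or
unmodified, and histograms sets by k = pairs removed.  `standard_size`
restricts the universe to sets of exactly that size (16 on the supported
arrays) instead of hard-coding it, since published summaries are sometimes
computed over the standard sets only and sometimes over all sets; overlap
(Venn) counts are likewise exposed at both pair and set granularity rather
than resolving that ambiguity for the caller.

`set_algebra` merges sibling specs per set name by pair-key set operations.
Intersection is provably equivalent to a single removal pass with the union
of both removal sets (same floor), and the test suite checks this
equivalence on generated inputs — it is the identity that justifies
building a joint filter spec either way.

## Delta analysis

Percent change is `100 · (E_c − E_d) / E_d` per (array, probe set), with
the default-definition value as the anchor (the quantity is deliberately
asymmetric).  Observations are pooled over all arrays and sets per k by
default; a per-array-mean option averages per-array means instead — the two
agree whenever every array contributes the same sets.  k runs 0..12 by
default: with 16-pair sets and a 4-pair floor, at most 12 pairs can be
removed.  Summarization itself (MAS 5.0, dChip, RMA) is out of scope; the
module consumes delimited tables from any external tool.

## Synthetic data

The generator emulates the supported array class: 16 pairs per set by
default, 25-mers, interrogation position 13, MM directly below PM, grid
sized to hold all probes without collision.  Background sequences are drawn
uniformly over ACGT and rejection-sampled so that *neither* motif occurs in
either the PM or its derived MM; planted pairs then get `GGGG` or `CCTCC`
spliced at a random offset of the PM.  Because the splice cannot create the
other motif (neither motif is a substring of text containing the other's
characters at the junction — `CCTCC` contains no G and `GGGG` no C), the
flagged set equals the planted set exactly, so recovery tests assert
precision = recall = 1 rather than a band.  Generation is a pure function
of the config (Python's seeded `random`), and every generated spec passes
validation.

Expression tables are a stand-in for real summarization: baselines are
log-normal (log-mean 5.5, log-sd 1.0, i.e. typical few-hundred-unit
intensities), and the custom value is the default times `1 + 0.10·k`
(configurable) times optional multiplicative log-normal noise.  What
passing tests show is therefore that the *pipeline arithmetic* (pair
bookkeeping, k assignment, pooling, percent change) is exact — not that any
particular biological effect size is realistic.  Real arrays add
probe-level correlation structure, saturation, background and
summarization nonlinearity that the generator does not attempt.

Problem sizes used by the test suite and the acceptance script — specs of
1-13 sets × up to 16 pairs on 40×40 grids, 50 round-trip configurations,
20 arrays for the noisy-recovery check — are chosen to exercise every code
path and boundary (single-pair sets, floor-pruned sets, k = 0..12) while
keeping each run well under a minute.

## Known limitations

* Only 3' IVT expression units are modeled; SNP/exon/genotyping unit types
  and per-feature intensity (CEL) data are out of scope.
* Only full custom specifications are accepted (every probe set stated
  explicitly); difference specifications are not implemented.
* The custom-spec XML schema is this package's own (documented in
  `docs/formats.md`), not a vendor schema.
* Corrupt-file repair and streaming partial parses are non-goals; readers
  fail fast with located diagnostics instead.
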