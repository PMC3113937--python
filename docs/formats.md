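# File formats

## ASCII CDF dialect

INI-like sections of `Key=Value` lines.  Layout written by `io_ascii` (the
reader additionally accepts permuted/extended cell columns, since binding is
by column name):

```
[CDF]
Version=GC3.0                      ; GC3.0 / GC4.0 / GC5.0 accepted

[Chip]
Name=<chip name>
Rows=<grid height>
Cols=<grid width>
NumberOfUnits=<n expression units>
MaxUnit=<n>
NumQCUnits=<n QC sections>
<unknown keys preserved verbatim>

[QC1]
Type=<int>
NumberCells=<n>
CellHeader=X	Y	PROBE	PLEN	ATOM	INDEX	MATCH	BG
Cell1=<tab-separated values bound to the header names>

[Unit1]
Name=NONE
Direction=<0 unknown | 1 sense | 2 antisense>
NumAtoms=<pairs>
NumCells=<2 x pairs>
UnitNumber=<int>
UnitType=3                         ; expression
NumberBlocks=1

[Unit1_Block1]
Name=<probe set name>
BlockNumber=1
NumAtoms=... NumCells=... StartPosition=0 StopPosition=<pairs-1>
CellHeader=X	Y	PROBE	FEAT	QUAL	EXPOS	POS	CBASE	PBASE	TBASE	ATOM	INDEX	CODONIND	CODON	REGIONTYPE	REGION
Cell1=...
```

Columns the reader requires: `X`, `Y`, `PBASE`, `TBASE`, `ATOM`; `EXPOS`
and `POS` default to 0 and 13.  Cells are grouped by `ATOM` into pairs and
classified PM/MM from PBASE/TBASE.  CRLF line endings by default.

## XDA CDF dialect (binary, little-endian)

```
offset  type        field
0       int32       magic = 67
4       int32       version (writer emits 1; readers accept 1-3)
8       uint16      cols
10      uint16      rows
12      int32       n_units
16      int32       n_qc_units
20      int32       L = reference-sequence length (0 when absent)
24      char[L]     reference sequence
...     char[64]    probe-set name, NUL-padded, x n_units
...     int32       QC-unit file position, x n_qc_units
...     int32       unit file position, x n_units
```

QC unit record: `uint16 type`, `int32 n_cells`, then per cell
`uint16 x, uint16 y, uint8 probe_length, uint8 pm_flag, uint8 bg_flag`.

Expression unit record: `uint16 unit_type(=3)`, `uint8 direction`,
`int32 n_atoms`, `int32 n_blocks(=1)`, `int32 n_cells`,
`int32 unit_number`, `uint8 cells_per_atom(=2)`; block header:
`int32 n_atoms`, `int32 n_cells`, `uint8 cells_per_atom`,
`uint8 direction`, `int32 first_atom`, `int32 reserved`,
`char[64] block name`; then per cell
`int32 atom, uint16 x, uint16 y, int32 expos, char pbase, char tbase`.

The writer is byte-deterministic.  `detect_format` distinguishes the two
dialects from a ≤256-byte prefix (XDA magic vs. `[CDF]` text header).

## Custom-specification interchange

Delimited (comma or tab, auto-detected; header optional), exactly seven
columns per row, one row per probe pair:

```
probe_set_id,pm_probe_id,pm_x,pm_y,mm_probe_id,mm_x,mm_y
```

Probe IDs are carried as labels; resolution against the parent default spec
uses PM coordinates (and checks the stated MM coordinate agrees).

Equivalent XML (this package's own schema):

```xml
<custom_spec name="..." parent="...">
  <probe_set id="new_at">
    <probe_pair pm_id="p1" pm_x="0" pm_y="0" mm_id="m1" mm_x="0" mm_y="1"/>
  </probe_set>
</custom_spec>
```

## Probe-sequence files

Tab-delimited with named columns (vendor aliases accepted): `Probe Set
Name`, `Probe X`, `Probe Y`, `Probe Interrogation Position`, `Probe
Sequence`.  FASTA headers follow the vendor pattern

```
>probe:<chip>:<set>:<x>:<y>; Interrogation_Position=<pos>; ...
```

and the pattern is pluggable (`read_probe_sequences(header_pattern=...)`)
for other header dialects.  Sequence exports (`fasta`, `xml`, `delimited`)
emit one record per sequence-bearing probe, PM and MM alike, and are
re-importable losslessly.

## Keep-lists

Delimited lines of `probe_set_name, pm_x, pm_y` (comma or tab; header
auto-detected).  A pair survives iff its PM coordinate is listed.

## Expression tables

CSV with a header row: first column the probe-set name, remaining columns
one per array, values positive summarized intensities.
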