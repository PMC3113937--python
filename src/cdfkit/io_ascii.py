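"""Reader/writer for the ASCII (text, INI-like) CDF dialect.

The ASCII chip definition file is a sequence of ``[Section]`` blocks of
``Key=Value`` lines.  A ``[Chip]`` section declares the grid and unit counts;
each expression unit contributes a ``[UnitN]`` section plus one
``[UnitN_BlockM]`` section whose ``CellHeader`` line names the columns of the
tab-separated ``CellK=...`` records that follow.  The parser binds cell values
to fields via those declared column names, never by fixed position, so vendor
files with permuted or extended columns parse identically.

Version tags ``GC3.0``, ``GC4.0`` and ``GC5.0`` are accepted; anything else
fails fast with the tag echoed.  Round-tripping is a *model-level* contract:
whitespace, key order and cell order within a pair are not preserved
byte-for-byte, but reading a written file always reproduces an equal model.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

from cdfkit.model import (
    COMPLEMENT,
    ArraySpec,
    Dialect,
    Direction,
    Probe,
    ProbePair,
    ProbeSet,
    QCCell,
    QCUnit,
    cell_index,
    require_valid,
)

SUPPORTED_VERSION_TAGS = ("GC3.0", "GC4.0", "GC5.0")

#: Keys the reader binds to model fields; everything else in [Chip] is
#: preserved verbatim in ``extra_headers`` and re-emitted on write.
_CHIP_KEYS = {"Name", "Rows", "Cols", "NumberOfUnits", "NumQCUnits", "MaxUnit"}

_DIRECTION_CODE = {Direction.SENSE: 1, Direction.ANTISENSE: 2,
                   Direction.UNKNOWN: 0}
_CODE_DIRECTION = {v: k for k, v in _DIRECTION_CODE.items()}

_UNIT_TYPE_CODE = {"expression": 3}
_CODE_UNIT_TYPE = {v: k for k, v in _UNIT_TYPE_CODE.items()}

PathOrTextStream = Union[str, Path, IO[str]]


class AsciiCdfError(ValueError):
    """Malformed or unsupported ASCII CDF input."""


@dataclass
class _Section:
    name: str
    keys: dict[str, str] = field(default_factory=dict)
    cells: list[tuple[int, str]] = field(default_factory=list)  # (ordinal, raw)
    cell_header: list[str] = field(default_factory=list)


_CELL_RE = re.compile(r"^Cell(\d+)$")
_SECTION_RE = re.compile(r"^\[(.+)\]$")


def _read_sections(lines: Iterable[str]) -> list[_Section]:
    sections: list[_Section] = []
    current: _Section | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        m = _SECTION_RE.match(line.strip())
        if m:
            current = _Section(m.group(1))
            sections.append(current)
            continue
        if current is None:
            raise AsciiCdfError(
                f"line {lineno}: content before any [section] header")
        if "=" not in line:
            raise AsciiCdfError(f"line {lineno}: expected Key=Value, got "
                                f"{line[:60]!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        cm = _CELL_RE.match(key)
        if cm:
            current.cells.append((int(cm.group(1)), value))
        elif key == "CellHeader":
            current.cell_header = value.rstrip().split("\t")
        else:
            current.keys[key] = value
    return sections


def _require(section: _Section, key: str) -> str:
    if key not in section.keys:
        raise AsciiCdfError(
            f"section [{section.name}] missing mandatory key {key!r}")
    return section.keys[key]


def _parse_cells(section: _Section) -> list[dict[str, str]]:
    """Bind each cell line's values to the declared column names."""
    if not section.cell_header:
        raise AsciiCdfError(f"section [{section.name}] has cells but no "
                            "CellHeader line")
    ncols = len(section.cell_header)
    rows = []
    for ordinal, raw in sorted(section.cells):
        values = raw.split("\t")
        # vendor files sometimes drop the tab before a trailing empty field
        if len(values) == ncols - 1:
            values.append("")
        if len(values) != ncols:
            raise AsciiCdfError(
                f"section [{section.name}] Cell{ordinal}: {len(values)} "
                f"values for {ncols} declared columns")
        rows.append(dict(zip(section.cell_header, values)))
    return rows


def _classify_pair(set_name: str, atom: int,
                   cells: list[Probe]) -> tuple[Probe, Probe]:
    if len(cells) != 2:
        raise AsciiCdfError(
            f"probe set {set_name!r} atom {atom}: {len(cells)} cells "
            "(a pair has exactly 2)")
    a, b = cells
    if a.is_pm and not b.is_pm:
        return a, b
    if b.is_pm and not a.is_pm:
        return b, a
    raise AsciiCdfError(
        f"probe set {set_name!r} atom {atom}: cannot classify PM/MM from "
        f"pbase/tbase ({a.pbase}/{a.tbase} and {b.pbase}/{b.tbase})")


def read_cdf_ascii(source: PathOrTextStream) -> ArraySpec:
    """Parse an ASCII CDF into a validated :class:`ArraySpec`.

    Probe sets appear in file order; QC sections are preserved; unknown
    ``[Chip]`` keys are carried in ``extra_headers``.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", newline="") as fh:
            sections = _read_sections(fh)
    else:
        sections = _read_sections(source)
    if not sections:
        raise AsciiCdfError("empty stream: no [CDF] header found")

    by_name = {s.name: s for s in sections}
    if sections[0].name != "CDF":
        raise AsciiCdfError(
            f"first section is [{sections[0].name}], expected [CDF]")
    version = _require(by_name["CDF"], "Version")
    if version not in SUPPORTED_VERSION_TAGS:
        raise AsciiCdfError(
            f"unsupported ASCII CDF version tag {version!r} "
            f"(supported: {', '.join(SUPPORTED_VERSION_TAGS)})")

    if "Chip" not in by_name:
        raise AsciiCdfError("missing [Chip] section")
    chip = by_name["Chip"]
    name = _require(chip, "Name")
    rows = int(_require(chip, "Rows"))
    cols = int(_require(chip, "Cols"))
    n_units = int(_require(chip, "NumberOfUnits"))
    n_qc = int(chip.keys.get("NumQCUnits", "0"))
    extra = {k: v for k, v in chip.keys.items() if k not in _CHIP_KEYS}

    qc_blocks: list[QCUnit] = []
    for i in range(1, n_qc + 1):
        sec = by_name.get(f"QC{i}")
        if sec is None:
            raise AsciiCdfError(f"[Chip] declares {n_qc} QC units but "
                                f"[QC{i}] is missing")
        cells = []
        for row in _parse_cells(sec):
            cells.append(QCCell(
                x=int(row["X"]), y=int(row["Y"]),
                probe_length=int(row.get("PLEN", 25) or 25),
                pm_flag=int(row.get("MATCH", 0) or 0),
                background_flag=int(row.get("BG", 0) or 0)))
        declared = int(sec.keys.get("NumberCells", len(cells)))
        if declared != len(cells):
            raise AsciiCdfError(f"[QC{i}]: NumberCells={declared} but "
                                f"{len(cells)} cell lines present")
        qc_blocks.append(QCUnit(qc_type=int(_require(sec, "Type")),
                                cells=cells))

    probe_sets: list[ProbeSet] = []
    for i in range(1, n_units + 1):
        unit = by_name.get(f"Unit{i}")
        if unit is None:
            raise AsciiCdfError(f"[Chip] declares {n_units} units but "
                                f"[Unit{i}] is missing")
        n_blocks = int(unit.keys.get("NumberBlocks", "1"))
        unit_number = int(unit.keys.get("UnitNumber", str(i)))
        unit_type = _CODE_UNIT_TYPE.get(
            int(unit.keys.get("UnitType", "3")), "expression")
        direction = _CODE_DIRECTION.get(
            int(unit.keys.get("Direction", "0")), Direction.UNKNOWN)
        for b in range(1, n_blocks + 1):
            block = by_name.get(f"Unit{i}_Block{b}")
            if block is None:
                raise AsciiCdfError(f"[Unit{i}] declares {n_blocks} blocks "
                                    f"but [Unit{i}_Block{b}] is missing")
            probe_sets.append(
                _block_to_probe_set(block, unit_number, unit_type, direction))

    spec = ArraySpec(
        chip_name=name, rows=rows, cols=cols, probe_sets=probe_sets,
        qc_blocks=qc_blocks, source_dialect=Dialect.ASCII,
        dialect_version=SUPPORTED_VERSION_TAGS.index(version) + 3,
        extra_headers=extra)
    spec.extra_headers.setdefault("_ascii_version_tag", version)
    require_valid(spec, "read_cdf_ascii")
    return spec


def _block_to_probe_set(block: _Section, unit_number: int, unit_type: str,
                        direction: Direction) -> ProbeSet:
    set_name = _require(block, "Name")
    rows = _parse_cells(block)
    by_atom: dict[int, list[tuple[Probe, int]]] = {}
    for row in rows:
        try:
            probe = Probe(x=int(row["X"]), y=int(row["Y"]),
                          pbase=row["PBASE"].upper(),
                          tbase=row["TBASE"].upper(),
                          expos=int(row.get("EXPOS", 0) or 0))
            atom = int(row["ATOM"])
            pos = int(row.get("POS", 13) or 13)
        except KeyError as exc:
            raise AsciiCdfError(
                f"block {set_name!r}: CellHeader lacks required column "
                f"{exc.args[0]}") from exc
        by_atom.setdefault(atom, []).append((probe, pos))

    pairs = []
    for atom in sorted(by_atom):
        entries = by_atom[atom]
        pm, mm = _classify_pair(set_name, atom, [p for p, _ in entries])
        pairs.append(ProbePair(atom_index=atom, pm=pm, mm=mm,
                               interrogation_position=entries[0][1]))

    declared_atoms = int(block.keys.get("NumAtoms", len(pairs)))
    declared_cells = int(block.keys.get("NumCells", 2 * len(pairs)))
    if declared_atoms != len(pairs) or declared_cells != 2 * len(pairs):
        raise AsciiCdfError(
            f"block {set_name!r}: declared NumAtoms={declared_atoms}/"
            f"NumCells={declared_cells} disagree with {len(pairs)} parsed "
            "pairs")
    return ProbeSet(name=set_name, pairs=pairs, unit_number=unit_number,
                    unit_type=unit_type, direction=direction)


# ---------------------------------------------------------------------------
# writer

_CELL_COLUMNS = ["X", "Y", "PROBE", "FEAT", "QUAL", "EXPOS", "POS", "CBASE",
                 "PBASE", "TBASE", "ATOM", "INDEX", "CODONIND", "CODON",
                 "REGIONTYPE", "REGION"]

_QC_COLUMNS = ["X", "Y", "PROBE", "PLEN", "ATOM", "INDEX", "MATCH", "BG"]


def write_cdf_ascii(spec: ArraySpec, dest: PathOrTextStream,
                    crlf: bool = True, version_tag: str | None = None) -> None:
    """Serialize a validated spec as an ASCII CDF.

    Declared atom/cell counts are recomputed from the model.  Output uses
    CRLF line endings by default (the vendor convention); pass
    ``crlf=False`` for LF.
    """
    require_valid(spec, "write_cdf_ascii")
    if version_tag is None:
        version_tag = spec.extra_headers.get("_ascii_version_tag", "GC3.0")
    if version_tag not in SUPPORTED_VERSION_TAGS:
        raise AsciiCdfError(f"cannot write unsupported version tag "
                            f"{version_tag!r}")

    if isinstance(dest, (str, Path)):
        with open(dest, "w", newline="") as fh:
            _write(spec, fh, "\r\n" if crlf else "\n", version_tag)
    else:
        _write(spec, dest, "\r\n" if crlf else "\n", version_tag)


def _write(spec: ArraySpec, fh: IO[str], eol: str, version_tag: str) -> None:
    def line(text: str = "") -> None:
        fh.write(text + eol)

    line("[CDF]")
    line(f"Version={version_tag}")
    line()
    line("[Chip]")
    line(f"Name={spec.chip_name}")
    line(f"Rows={spec.rows}")
    line(f"Cols={spec.cols}")
    line(f"NumberOfUnits={len(spec.probe_sets)}")
    line(f"MaxUnit={len(spec.probe_sets)}")
    line(f"NumQCUnits={len(spec.qc_blocks)}")
    for key, value in spec.extra_headers.items():
        if not key.startswith("_"):
            line(f"{key}={value}")
    line()

    for qi, qc in enumerate(spec.qc_blocks, start=1):
        line(f"[QC{qi}]")
        line(f"Type={qc.qc_type}")
        line(f"NumberCells={len(qc.cells)}")
        line("CellHeader=" + "\t".join(_QC_COLUMNS))
        for ci, cell in enumerate(qc.cells, start=1):
            idx = cell_index(cell.x, cell.y, spec.cols)
            line(f"Cell{ci}=" + "\t".join(map(str, [
                cell.x, cell.y, "N", cell.probe_length, ci - 1, idx,
                cell.pm_flag, cell.background_flag])))
        line()

    for ui, ps in enumerate(spec.probe_sets, start=1):
        n_atoms, n_cells = len(ps.pairs), ps.n_cells
        line(f"[Unit{ui}]")
        line("Name=NONE")
        line(f"Direction={_DIRECTION_CODE[ps.direction]}")
        line(f"NumAtoms={n_atoms}")
        line(f"NumCells={n_cells}")
        line(f"UnitNumber={ps.unit_number}")
        line(f"UnitType={_UNIT_TYPE_CODE.get(ps.unit_type, 3)}")
        line("NumberBlocks=1")
        line()
        line(f"[Unit{ui}_Block1]")
        line(f"Name={ps.name}")
        line("BlockNumber=1")
        line(f"NumAtoms={n_atoms}")
        line(f"NumCells={n_cells}")
        line("StartPosition=0")
        line(f"StopPosition={max(n_atoms - 1, 0)}")
        line("CellHeader=" + "\t".join(_CELL_COLUMNS))
        ci = 0
        for pair in ps.pairs:
            for probe in (pair.pm, pair.mm):
                ci += 1
                idx = cell_index(probe.x, probe.y, spec.cols)
                line(f"Cell{ci}=" + "\t".join(map(str, [
                    probe.x, probe.y, "N", "control", ps.name, probe.expos,
                    pair.interrogation_position, probe.pbase, probe.pbase,
                    probe.tbase, pair.atom_index, idx, -1, -1, 99, ""])))
        line()


def dumps(spec: ArraySpec, **kwargs) -> str:
    """Serialize to an in-memory string (mostly for tests and diffing)."""
    buf = io.StringIO()
    write_cdf_ascii(spec, buf, **kwargs)
    return buf.getvalue()


def loads(text: str) -> ArraySpec:
    """Parse an ASCII CDF from an in-memory string."""
    return read_cdf_ascii(io.StringIO(text))
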