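"""Custom array specifications from simple delimited/XML definition files.

A custom specification re-groups probe pairs of a parent (default) spec into
user-defined probe sets.  The interchange format is deliberately minimal:
one row per probe pair with seven columns —

    probe set ID, PM probe ID, PM x, PM y, MM probe ID, MM x, MM y

— or the equivalent XML (schema in ``docs/formats.md``).  Pair identity is
anchored on the PM coordinate, the one key present in every input; the probe
IDs in columns 2 and 5 are carried as labels but never used for resolution.
Pairs are atomic: a row pulls the *whole* PM+MM pair (with any attached
sequences) out of the parent — there is no way to add just one probe.
"""

from __future__ import annotations

import csv
import xml.etree.ElementTree as ET
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Union

from cdfkit.model import (
    ArraySpec,
    Dialect,
    ProbePair,
    ProbeSet,
    copy_spec,
    require_valid,
)

PathOrTextStream = Union[str, Path, IO[str]]


class CustomSpecError(ValueError):
    """Malformed custom-specification input or unresolvable reference."""


@dataclass(frozen=True)
class CustomSpecRow:
    probe_set_id: str
    pm_probe_id: str
    pm_x: int
    pm_y: int
    mm_probe_id: str
    mm_x: int
    mm_y: int

    def __post_init__(self):
        if min(self.pm_x, self.pm_y, self.mm_x, self.mm_y) < 0:
            raise CustomSpecError(
                f"negative coordinate in row for {self.probe_set_id!r}")
        if (self.pm_x, self.pm_y) == (self.mm_x, self.mm_y):
            raise CustomSpecError(
                f"PM and MM share ({self.pm_x},{self.pm_y}) in row for "
                f"{self.probe_set_id!r}")


_N_COLUMNS = 7


def _sniff_delimiter(first_line: str) -> str:
    # comma and tab are auto-detected; anything else needs an explicit flag
    if first_line.count("\t") >= _N_COLUMNS - 1:
        return "\t"
    return ","


def _looks_like_header(fields: list[str]) -> bool:
    try:
        for idx in (2, 3, 5, 6):
            int(fields[idx])
        return False
    except (ValueError, IndexError):
        return True


def read_custom_rows(source: PathOrTextStream, format: str = "delimited",
                     delimiter: str | None = None) -> list[CustomSpecRow]:
    """Parse a custom-specification file into rows, file order preserved.

    Delimited input must have exactly seven columns; a header row is
    auto-detected and skipped.  Duplicate (probe set, PM x, PM y) triples
    are rejected — the same pair cannot appear twice in one set.
    """
    if isinstance(source, (str, Path)):
        with open(source, newline="") as fh:
            return read_custom_rows(fh, format, delimiter)
    if format == "xml":
        return _read_xml_rows(source)
    if format != "delimited":
        raise ValueError(f"unknown custom-spec format {format!r}")

    text_lines = [ln for ln in source]
    rows: list[CustomSpecRow] = []
    seen: set[tuple[str, int, int]] = set()
    reader_delim = delimiter
    for lineno, raw in enumerate(text_lines, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        if reader_delim is None:
            reader_delim = _sniff_delimiter(line)
        fields = next(csv.reader([line], delimiter=reader_delim))
        if lineno == 1 and _looks_like_header(fields):
            continue
        if len(fields) != _N_COLUMNS:
            raise CustomSpecError(
                f"line {lineno}: {len(fields)} columns, expected "
                f"{_N_COLUMNS}")
        try:
            row = CustomSpecRow(
                probe_set_id=fields[0], pm_probe_id=fields[1],
                pm_x=int(fields[2]), pm_y=int(fields[3]),
                mm_probe_id=fields[4], mm_x=int(fields[5]),
                mm_y=int(fields[6]))
        except ValueError as exc:
            if isinstance(exc, CustomSpecError):
                raise
            raise CustomSpecError(
                f"line {lineno}: non-integer coordinate in {fields!r}"
            ) from exc
        _check_duplicate(row, seen, f"line {lineno}")
        rows.append(row)
    return rows


def _check_duplicate(row: CustomSpecRow, seen: set, where: str) -> None:
    triple = (row.probe_set_id, row.pm_x, row.pm_y)
    if triple in seen:
        raise CustomSpecError(
            f"{where}: duplicate pair {triple} in custom specification")
    seen.add(triple)


def _read_xml_rows(handle: IO[str]) -> list[CustomSpecRow]:
    try:
        root = ET.parse(handle).getroot()
    except ET.ParseError as exc:
        raise CustomSpecError(f"XML parse failure: {exc}") from exc
    if root.tag != "custom_spec":
        raise CustomSpecError(
            f"root element is <{root.tag}>, expected <custom_spec>")
    rows: list[CustomSpecRow] = []
    seen: set[tuple[str, int, int]] = set()
    for ps_el in root.iter("probe_set"):
        set_id = ps_el.get("id")
        if set_id is None:
            raise CustomSpecError("<probe_set> element lacks an id attribute")
        for pair_el in ps_el.iter("probe_pair"):
            try:
                row = CustomSpecRow(
                    probe_set_id=set_id,
                    pm_probe_id=pair_el.get("pm_id", ""),
                    pm_x=int(pair_el.get("pm_x")),
                    pm_y=int(pair_el.get("pm_y")),
                    mm_probe_id=pair_el.get("mm_id", ""),
                    mm_x=int(pair_el.get("mm_x")),
                    mm_y=int(pair_el.get("mm_y")))
            except (TypeError, ValueError) as exc:
                raise CustomSpecError(
                    f"bad <probe_pair> in set {set_id!r}: {exc}") from exc
            _check_duplicate(row, seen, f"set {set_id!r}")
            rows.append(row)
    return rows


def build_custom_spec(rows: Iterable[CustomSpecRow], default_spec: ArraySpec,
                      name: str) -> ArraySpec:
    """Resolve rows against a parent default spec into a custom spec.

    Each row must name the PM coordinate of a pair in the default; the whole
    pair is copied (sequences included).  Probe sets are assembled in row
    order, atom indices and unit numbers renumbered sequentially.  The
    default spec is never mutated; grid dimensions, QC blocks and the source
    dialect are inherited.
    """
    require_valid(default_spec, "build_custom_spec")
    pair_at: dict[tuple[int, int], tuple[ProbeSet, ProbePair]] = {}
    for ps in default_spec.probe_sets:
        for pair in ps.pairs:
            pair_at[(pair.pm.x, pair.pm.y)] = (ps, pair)

    sets: dict[str, ProbeSet] = {}
    for row in rows:
        hit = pair_at.get((row.pm_x, row.pm_y))
        if hit is None:
            raise CustomSpecError(
                f"no PM probe at ({row.pm_x},{row.pm_y}) in default spec "
                f"{default_spec.chip_name!r} (row for {row.probe_set_id!r})")
        src_set, src_pair = hit
        if (src_pair.mm.x, src_pair.mm.y) != (row.mm_x, row.mm_y):
            raise CustomSpecError(
                f"row for {row.probe_set_id!r}: MM coordinate "
                f"({row.mm_x},{row.mm_y}) disagrees with the default pair's "
                f"MM at ({src_pair.mm.x},{src_pair.mm.y})")
        target = sets.get(row.probe_set_id)
        if target is None:
            target = ProbeSet(name=row.probe_set_id, pairs=[],
                              unit_type=src_set.unit_type,
                              direction=src_set.direction)
            sets[row.probe_set_id] = target
        target.pairs.append(ProbePair(
            atom_index=len(target.pairs),
            pm=replace(src_pair.pm),
            mm=replace(src_pair.mm),
            interrogation_position=src_pair.interrogation_position))

    if not sets:
        raise CustomSpecError("custom specification resolves to no probe "
                              "sets")
    probe_sets = list(sets.values())
    for i, ps in enumerate(probe_sets, start=1):
        ps.unit_number = i

    spec = ArraySpec(
        chip_name=name,
        rows=default_spec.rows,
        cols=default_spec.cols,
        probe_sets=probe_sets,
        qc_blocks=copy_spec(default_spec).qc_blocks,
        source_dialect=default_spec.source_dialect,
        dialect_version=default_spec.dialect_version,
        is_custom=True,
        parent_name=default_spec.chip_name)
    require_valid(spec, "build_custom_spec (result)")
    return spec


def spec_to_rows(spec: ArraySpec) -> list[CustomSpecRow]:
    """One row per probe pair, in spec order; probe IDs are cell indices."""
    rows = []
    for ps in spec.probe_sets:
        for pair in ps.pairs:
            rows.append(CustomSpecRow(
                probe_set_id=ps.name,
                pm_probe_id=str(pair.pm.cell_index(spec.cols)),
                pm_x=pair.pm.x, pm_y=pair.pm.y,
                mm_probe_id=str(pair.mm.cell_index(spec.cols)),
                mm_x=pair.mm.x, mm_y=pair.mm.y))
    return rows


_HEADER = ["probe_set_id", "pm_probe_id", "pm_x", "pm_y",
           "mm_probe_id", "mm_x", "mm_y"]


def export_spec(spec: ArraySpec, format: str, dest,
                dialect: Dialect | None = None) -> None:
    """Write a spec as a CDF, XML or 7-column delimited file.

    For ``format="cdf"`` the dialect is the spec's own (for a custom spec
    that is the parent default's dialect, inherited at build time) unless
    overridden explicitly; a spec with no known dialect is refused.
    Delimited output is accepted unchanged by :func:`read_custom_rows`.
    """
    require_valid(spec, "export_spec")
    if format == "cdf":
        chosen = dialect or spec.source_dialect
        if chosen is None:
            raise CustomSpecError(
                f"spec {spec.chip_name!r} has no known CDF dialect; pass "
                "one explicitly")
        if chosen is Dialect.ASCII:
            from cdfkit.io_ascii import write_cdf_ascii
            write_cdf_ascii(spec, dest)
        else:
            from cdfkit.io_xda import write_cdf_xda
            write_cdf_xda(spec, dest)
        return

    if isinstance(dest, (str, Path)):
        with open(dest, "w", newline="") as fh:
            export_spec(spec, format, fh, dialect)
        return

    rows = spec_to_rows(spec)
    if format == "delimited":
        writer = csv.writer(dest, lineterminator="\n")
        writer.writerow(_HEADER)
        for row in rows:
            writer.writerow([row.probe_set_id, row.pm_probe_id, row.pm_x,
                             row.pm_y, row.mm_probe_id, row.mm_x, row.mm_y])
    elif format == "xml":
        root = ET.Element("custom_spec", name=spec.chip_name)
        if spec.parent_name:
            root.set("parent", spec.parent_name)
        current: ET.Element | None = None
        for row in rows:
            if current is None or current.get("id") != row.probe_set_id:
                current = ET.SubElement(root, "probe_set", id=row.probe_set_id)
            ET.SubElement(current, "probe_pair", pm_id=row.pm_probe_id,
                          pm_x=str(row.pm_x), pm_y=str(row.pm_y),
                          mm_id=row.mm_probe_id, mm_x=str(row.mm_x),
                          mm_y=str(row.mm_y))
        ET.indent(root)
        dest.write(ET.tostring(root, encoding="unicode") + "\n")
    else:
        raise ValueError(f"unknown spec export format {format!r}")
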