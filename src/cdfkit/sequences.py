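"""Probe-sequence import/export and mismatch-sequence generation.

Vendor probe-sequence files list only the perfect-match (PM) 25-mers; the
mismatch (MM) partner differs from its PM solely at the central base, which
carries the Watson-Crick complement.  This module reads the vendor FASTA and
tab-delimited layouts, attaches sequences to the probes of a spec (keyed by
grid coordinate), generates the missing MM sequences, and exports sequences
as FASTA, XML or a delimited table.

Sequences are stored directly on :class:`~cdfkit.model.Probe` objects, so an
export from a custom spec automatically covers exactly the surviving probes.
"""

from __future__ import annotations

import csv
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

from Bio import SeqIO

from cdfkit.model import COMPLEMENT, ArraySpec, Probe, require_valid

PathOrTextStream = Union[str, Path, IO[str]]

#: Header pattern for vendor probe FASTA records, e.g.
#: ``>probe:HG-U95Av2:1000_at:358:306; Interrogation_Position=518; Antisense;``
DEFAULT_FASTA_HEADER = re.compile(
    r"probe:(?P<chip>[^:]*):(?P<set>[^:;]+):(?P<x>\d+):(?P<y>\d+);\s*"
    r"Interrogation_Position=(?P<pos>-?\d+)")


class SequenceFileError(ValueError):
    """Unparseable probe-sequence input."""


@dataclass(frozen=True)
class ProbeSequenceRecord:
    probe_set_name: str
    x: int
    y: int
    interrogation_position: int
    sequence: str
    offset_in_target: int | None = None


@dataclass
class AttachReport:
    """Outcome of :func:`attach_sequences`."""

    annotated: int = 0        # total probes annotated (PM + generated MM)
    pm_annotated: int = 0
    mm_generated: int = 0
    mm_direct: int = 0        # records that landed on an MM probe (lenient)
    unmatched: list[tuple[int, int]] = field(default_factory=list)


def _normalize(seq: str, where: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise SequenceFileError(
            f"{where}: non-ACGT character(s) {sorted(bad)} after "
            "normalization")
    return s


def read_probe_sequences(source: PathOrTextStream, format: str,
                         header_pattern: re.Pattern = DEFAULT_FASTA_HEADER,
                         ) -> list[ProbeSequenceRecord]:
    """Parse a probe-sequence file into records.

    ``format`` is ``"fasta"`` (vendor headers carrying probe-set name, x, y
    and interrogation position; the pattern is pluggable because vendor
    header dialects vary) or ``"tab"`` (named columns).  Sequences are
    upper-cased and U is mapped to T.  An empty file yields an empty list.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_probe_sequences(fh, format, header_pattern)
    if format == "fasta":
        return _read_fasta(source, header_pattern)
    if format == "tab":
        return _read_tab(source)
    raise ValueError(f"unknown sequence file format {format!r}")


def _read_fasta(handle: IO[str],
                pattern: re.Pattern) -> list[ProbeSequenceRecord]:
    records = []
    for i, rec in enumerate(SeqIO.parse(handle, "fasta"), start=1):
        m = pattern.search(rec.description)
        if not m:
            raise SequenceFileError(
                f"FASTA record {i}: header {rec.description!r} does not "
                "match the probe header pattern")
        records.append(ProbeSequenceRecord(
            probe_set_name=m.group("set"),
            x=int(m.group("x")),
            y=int(m.group("y")),
            interrogation_position=int(m.group("pos")),
            sequence=_normalize(str(rec.seq), f"FASTA record {i}")))
    return records


#: Aliases for the tab-delimited column names (lower-cased, spaces collapsed).
_TAB_ALIASES = {
    "probe set name": "set", "probe set id": "set", "probeset": "set",
    "probe x": "x", "x": "x",
    "probe y": "y", "y": "y",
    "probe interrogation position": "pos", "interrogation position": "pos",
    "probe sequence": "seq", "sequence": "seq",
}


def _read_tab(handle: IO[str]) -> list[ProbeSequenceRecord]:
    reader = csv.reader(handle, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        return []
    colmap: dict[str, int] = {}
    for idx, name in enumerate(header):
        canon = _TAB_ALIASES.get(" ".join(name.lower().split()))
        if canon and canon not in colmap:
            colmap[canon] = idx
    missing = {"set", "x", "y", "pos", "seq"} - set(colmap)
    if missing:
        raise SequenceFileError(
            f"tab file header lacks required column(s): {sorted(missing)} "
            f"(saw {header})")
    records = []
    for lineno, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        try:
            records.append(ProbeSequenceRecord(
                probe_set_name=row[colmap["set"]],
                x=int(row[colmap["x"]]),
                y=int(row[colmap["y"]]),
                interrogation_position=int(row[colmap["pos"]]),
                sequence=_normalize(row[colmap["seq"]], f"line {lineno}")))
        except (IndexError, ValueError) as exc:
            if isinstance(exc, SequenceFileError):
                raise
            raise SequenceFileError(
                f"line {lineno}: cannot parse row {row!r}: {exc}") from exc
    return records


def mm_from_pm(pm_sequence: str) -> str:
    """Derive the mismatch sequence: complement the central base of the PM.

    For a sequence of odd length L the base at 1-based position (L+1)/2 is
    replaced by its Watson-Crick complement; all other positions are
    unchanged.  The function is its own inverse.
    """
    seq = pm_sequence.upper()
    n = len(seq)
    if n % 2 == 0:
        raise ValueError(
            f"PM sequence length {n} is even; the central base is undefined")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT base(s) {sorted(bad)} in PM sequence")
    mid = n // 2
    return seq[:mid] + COMPLEMENT[seq[mid]] + seq[mid + 1:]


def attach_sequences(spec: ArraySpec,
                     records: Iterable[ProbeSequenceRecord],
                     generate_mm: bool = True,
                     strict: bool = True) -> AttachReport:
    """Attach imported sequences to the probes of a spec, keyed by (x, y).

    Each record is matched to the probe at its coordinate.  Records are
    expected to describe PM probes (vendor files list only those); when
    ``generate_mm`` is set the paired MM probe additionally receives
    :func:`mm_from_pm` of the PM sequence unless it already has one.  In
    strict mode a record that matches no PM probe raises; in lenient mode a
    record landing on an MM probe annotates it directly (so re-importing an
    exported file that includes MM records is lossless) and a record
    matching nothing is reported in the returned :class:`AttachReport`.
    """
    require_valid(spec, "attach_sequences")
    pm_at: dict[tuple[int, int], tuple[Probe, Probe]] = {}
    mm_at: dict[tuple[int, int], Probe] = {}
    for ps in spec.probe_sets:
        for pair in ps.pairs:
            pm_at[(pair.pm.x, pair.pm.y)] = (pair.pm, pair.mm)
            mm_at[(pair.mm.x, pair.mm.y)] = pair.mm

    report = AttachReport()
    for rec in records:
        coord = (rec.x, rec.y)
        if coord in pm_at:
            pm, mm = pm_at[coord]
            pm.sequence = rec.sequence
            report.pm_annotated += 1
            report.annotated += 1
            if generate_mm and mm.sequence is None:
                mm.sequence = mm_from_pm(rec.sequence)
                report.mm_generated += 1
                report.annotated += 1
        elif coord in mm_at:
            if strict:
                raise ValueError(
                    f"sequence record at {coord} matches an MM probe, not a "
                    "PM probe (strict mode)")
            mm_at[coord].sequence = rec.sequence
            report.mm_direct += 1
            report.annotated += 1
        else:
            if strict:
                raise ValueError(
                    f"sequence record at {coord} matches no probe in spec "
                    f"{spec.chip_name!r}")
            report.unmatched.append(coord)
    return report


def _sequence_entries(spec: ArraySpec):
    """Yield (set name, pair, probe, kind) for every sequence-bearing probe."""
    for ps in spec.probe_sets:
        for pair in ps.pairs:
            for probe, kind in ((pair.pm, "pm"), (pair.mm, "mm")):
                if probe.sequence is not None:
                    yield ps.name, pair, probe, kind


def export_sequences(spec: ArraySpec, format: str,
                     dest: PathOrTextStream) -> int:
    """Write one record per sequence-bearing probe; returns the count.

    ``format`` is ``"fasta"`` (headers re-readable by
    :func:`read_probe_sequences`), ``"xml"`` or ``"delimited"``
    (tab-separated with vendor-compatible column names).
    """
    if isinstance(dest, (str, Path)):
        with open(dest, "w", newline="") as fh:
            return export_sequences(spec, format, fh)

    entries = list(_sequence_entries(spec))
    if not entries:
        raise ValueError(f"spec {spec.chip_name!r} has no probe sequences "
                         "to export")
    if format == "fasta":
        for set_name, pair, probe, kind in entries:
            dest.write(
                f">probe:{spec.chip_name}:{set_name}:{probe.x}:{probe.y}; "
                f"Interrogation_Position={pair.interrogation_position}; "
                f"{kind.upper()};\n{probe.sequence}\n")
    elif format == "delimited":
        writer = csv.writer(dest, delimiter="\t", lineterminator="\n")
        writer.writerow(["Probe Set Name", "Probe X", "Probe Y",
                         "Probe Interrogation Position", "Probe Sequence",
                         "Probe Kind"])
        for set_name, pair, probe, kind in entries:
            writer.writerow([set_name, probe.x, probe.y,
                             pair.interrogation_position, probe.sequence,
                             kind])
    elif format == "xml":
        root = ET.Element("probe_sequences", chip=spec.chip_name)
        for set_name, pair, probe, kind in entries:
            el = ET.SubElement(
                root, "probe", probe_set=set_name, x=str(probe.x),
                y=str(probe.y),
                interrogation_position=str(pair.interrogation_position),
                kind=kind)
            el.text = probe.sequence
        ET.indent(root)
        dest.write(ET.tostring(root, encoding="unicode") + "\n")
    else:
        raise ValueError(f"unknown sequence export format {format!r}")
    return len(entries)
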