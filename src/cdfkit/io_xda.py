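"""Reader/writer for the XDA (binary) CDF dialect, plus dialect detection.

The XDA chip definition file is a little-endian binary container: a fixed
header (magic, version, grid size, unit counts), a table of 64-byte
NUL-padded probe-set names, file-position tables for QC and expression
units, then the unit payloads.  Each expression unit holds one block of
cell records ``(atom: i32, x: u16, y: u16, expos: i32, pbase: char,
tbase: char)``.  Integer widths, string encodings and record shapes follow
the published GCOS data-file layout; the byte layout is documented in
``docs/formats.md`` and frozen by golden-byte fixtures in the test suite.

Two facts about the dialect shape this module's contracts:

* XDA stores no chip name — consumers conventionally take it from the file
  name.  ``read_cdf_xda`` accepts an explicit ``chip_name`` and otherwise
  falls back to the path stem (or ``""`` for anonymous streams).
* XDA stores no per-cell interrogation position; on read it is set to 13,
  the central base of a 25-mer, which is what every supported expression
  array uses.
"""

from __future__ import annotations

import io
import struct
from pathlib import Path
from typing import IO, Union

from cdfkit.model import (
    ArraySpec,
    Dialect,
    Direction,
    Probe,
    ProbePair,
    ProbeSet,
    QCCell,
    QCUnit,
    require_valid,
)

XDA_MAGIC = 67
SUPPORTED_XDA_VERSIONS = (1, 2, 3)
#: Version emitted by the writer: the base expression-array layout.  The
#: higher versions only extend resequencing payloads, which are out of scope.
WRITE_VERSION = 1

_NAME_WIDTH = 64
_CENTRAL_POS = 13

_DIRECTION_CODE = {Direction.UNKNOWN: 0, Direction.SENSE: 1,
                   Direction.ANTISENSE: 2}
_CODE_DIRECTION = {v: k for k, v in _DIRECTION_CODE.items()}
_UNIT_TYPE_CODE = {"expression": 3}
_CODE_UNIT_TYPE = {v: k for k, v in _UNIT_TYPE_CODE.items()}

PathOrByteStream = Union[str, Path, IO[bytes]]


class XdaCdfError(ValueError):
    """Malformed, truncated or unsupported XDA CDF input."""


class FormatDetectionError(ValueError):
    """Stream matches neither CDF dialect signature."""


def detect_format(source: PathOrByteStream) -> tuple[Dialect, int]:
    """Identify the CDF dialect of a byte stream from a bounded prefix.

    Returns ``(Dialect.XDA, version)`` when the leading little-endian int32
    is the XDA magic, or ``(Dialect.ASCII, version)`` when the prefix is text
    opening with the ``[CDF]`` section.  Never reads more than 256 bytes.
    """
    if isinstance(source, (str, Path)):
        with open(source, "rb") as fh:
            prefix = fh.read(256)
    else:
        prefix = source.read(256)
    if len(prefix) < 8:
        raise FormatDetectionError(
            f"stream too short to carry a CDF signature ({len(prefix)} bytes)")
    magic, version = struct.unpack_from("<ii", prefix)
    if magic == XDA_MAGIC:
        return Dialect.XDA, version
    try:
        text = prefix.decode("ascii", errors="strict")
    except UnicodeDecodeError:
        raise FormatDetectionError(
            "unrecognized format: not XDA magic and prefix is not ASCII text"
        ) from None
    stripped = text.lstrip("﻿ \t\r\n")
    if stripped.startswith("[CDF]"):
        for line in stripped.splitlines():
            if line.strip().startswith("Version=GC"):
                tag = line.strip().removeprefix("Version=GC")
                try:
                    return Dialect.ASCII, int(float(tag))
                except ValueError:
                    break
        return Dialect.ASCII, 3
    raise FormatDetectionError(
        "unrecognized format: no XDA magic and no [CDF] text header")


class _Cursor:
    """Bounds-checked little-endian reader over an in-memory buffer."""

    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0

    def take(self, fmt: str, context: str):
        size = struct.calcsize(fmt)
        if self.pos + size > len(self.data):
            raise XdaCdfError(
                f"truncated stream while reading {context} at byte "
                f"{self.pos} (need {size}, have {len(self.data) - self.pos})")
        out = struct.unpack_from(fmt, self.data, self.pos)
        self.pos += size
        return out if len(out) > 1 else out[0]

    def take_bytes(self, n: int, context: str) -> bytes:
        if self.pos + n > len(self.data):
            raise XdaCdfError(f"truncated stream while reading {context}")
        out = self.data[self.pos:self.pos + n]
        self.pos += n
        return out

    def seek(self, pos: int) -> None:
        self.pos = pos


def _fixed_name(raw: bytes) -> str:
    return raw.split(b"\x00", 1)[0].decode("ascii")


def read_cdf_xda(source: PathOrByteStream,
                 chip_name: str | None = None) -> ArraySpec:
    """Decode an XDA CDF into a validated :class:`ArraySpec`."""
    if isinstance(source, (str, Path)):
        data = Path(source).read_bytes()
        if chip_name is None:
            chip_name = Path(source).stem
    else:
        data = source.read()
    if chip_name is None:
        chip_name = ""

    cur = _Cursor(data)
    magic = cur.take("<i", "magic")
    if magic != XDA_MAGIC:
        raise XdaCdfError(f"bad magic {magic} (expected {XDA_MAGIC}); "
                          "not an XDA CDF")
    version = cur.take("<i", "version")
    if version not in SUPPORTED_XDA_VERSIONS:
        raise XdaCdfError(f"unsupported XDA version {version} "
                          f"(supported: {SUPPORTED_XDA_VERSIONS})")
    cols, rows = cur.take("<HH", "grid size")
    n_units = cur.take("<i", "unit count")
    n_qc = cur.take("<i", "QC unit count")
    ref_len = cur.take("<i", "reference-sequence length")
    ref = cur.take_bytes(ref_len, "reference sequence").decode("ascii")

    names = [_fixed_name(cur.take_bytes(_NAME_WIDTH, f"name of unit {i}"))
             for i in range(n_units)]
    qc_positions = [cur.take("<i", f"QC unit {i} position")
                    for i in range(n_qc)]
    unit_positions = [cur.take("<i", f"unit {i} position")
                      for i in range(n_units)]

    qc_blocks = []
    for i, pos in enumerate(qc_positions):
        cur.seek(pos)
        qc_type = cur.take("<H", f"QC unit {i} type")
        n_cells = cur.take("<i", f"QC unit {i} cell count")
        cells = []
        for c in range(n_cells):
            x, y, plen, pm, bg = cur.take("<HHBBB", f"QC unit {i} cell {c}")
            cells.append(QCCell(x, y, plen, pm, bg))
        qc_blocks.append(QCUnit(qc_type, cells))

    probe_sets = []
    for i, pos in enumerate(unit_positions):
        cur.seek(pos)
        probe_sets.append(_read_unit(cur, i, names[i]))

    spec = ArraySpec(
        chip_name=chip_name, rows=rows, cols=cols, probe_sets=probe_sets,
        qc_blocks=qc_blocks, source_dialect=Dialect.XDA,
        dialect_version=version)
    if ref:
        spec.extra_headers["_xda_reference"] = ref
    require_valid(spec, "read_cdf_xda")
    return spec


def _read_unit(cur: _Cursor, ordinal: int, name: str) -> ProbeSet:
    ctx = f"unit {ordinal + 1}"
    unit_type = cur.take("<H", f"{ctx} type")
    cur.take("<B", f"{ctx} direction")  # authoritative copy is per block
    n_atoms = cur.take("<i", f"{ctx} atom count")
    n_blocks = cur.take("<i", f"{ctx} block count")
    n_cells = cur.take("<i", f"{ctx} cell count")
    unit_number = cur.take("<i", f"{ctx} unit number")
    cur.take("<B", f"{ctx} cells per atom")
    if n_blocks != 1:
        raise XdaCdfError(f"{ctx}: {n_blocks} blocks (expression units "
                          "carry exactly 1)")

    b_atoms = cur.take("<i", f"{ctx} block atom count")
    b_cells = cur.take("<i", f"{ctx} block cell count")
    cur.take("<B", f"{ctx} block cells per atom")
    b_dir = cur.take("<B", f"{ctx} block direction")
    cur.take("<i", f"{ctx} block first atom")
    cur.take("<i", f"{ctx} block reserved")
    block_name = _fixed_name(cur.take_bytes(_NAME_WIDTH, f"{ctx} block name"))
    if b_atoms != n_atoms or b_cells != n_cells:
        raise XdaCdfError(f"{ctx}: unit counts ({n_atoms}/{n_cells}) disagree "
                          f"with block counts ({b_atoms}/{b_cells})")

    by_atom: dict[int, list[Probe]] = {}
    for c in range(n_cells):
        atom = cur.take("<i", f"{ctx} cell {c} atom")
        x, y = cur.take("<HH", f"{ctx} cell {c} coords")
        expos = cur.take("<i", f"{ctx} cell {c} expos")
        pbase, tbase = cur.take("<cc", f"{ctx} cell {c} bases")
        probe = Probe(x=x, y=y, pbase=pbase.decode().upper(),
                      tbase=tbase.decode().upper(), expos=expos)
        by_atom.setdefault(atom, []).append(probe)

    pairs = []
    for atom in sorted(by_atom):
        cells = by_atom[atom]
        if len(cells) != 2:
            raise XdaCdfError(f"{ctx} ({block_name!r}): atom {atom} has "
                              f"{len(cells)} cells, expected a PM/MM pair")
        a, b = cells
        if a.is_pm and not b.is_pm:
            pm, mm = a, b
        elif b.is_pm and not a.is_pm:
            pm, mm = b, a
        else:
            raise XdaCdfError(f"{ctx} ({block_name!r}): atom {atom} PM/MM "
                              "classification ambiguous from pbase/tbase")
        pairs.append(ProbePair(atom_index=atom, pm=pm, mm=mm,
                               interrogation_position=_CENTRAL_POS))

    return ProbeSet(
        name=block_name or name,
        pairs=pairs,
        unit_number=unit_number,
        unit_type=_CODE_UNIT_TYPE.get(unit_type, "expression"),
        direction=_CODE_DIRECTION.get(b_dir, Direction.UNKNOWN))


def write_cdf_xda(spec: ArraySpec, dest: PathOrByteStream) -> None:
    """Serialize a validated spec as an XDA CDF.

    Deterministic: an identical model always yields identical bytes.  All
    counts and file positions are recomputed from the model.
    """
    require_valid(spec, "write_cdf_xda")
    payload = _serialize(spec)
    if isinstance(dest, (str, Path)):
        Path(dest).write_bytes(payload)
    else:
        dest.write(payload)


def _serialize(spec: ArraySpec) -> bytes:
    ref = spec.extra_headers.get("_xda_reference", "").encode("ascii")
    n_units = len(spec.probe_sets)
    n_qc = len(spec.qc_blocks)

    qc_payloads = [_serialize_qc(qc) for qc in spec.qc_blocks]
    unit_payloads = [_serialize_unit(ps) for ps in spec.probe_sets]

    header_size = (4 + 4 + 2 + 2 + 4 + 4 + 4 + len(ref)
                   + _NAME_WIDTH * n_units + 4 * n_qc + 4 * n_units)
    positions: list[int] = []
    offset = header_size
    for blob in qc_payloads + unit_payloads:
        positions.append(offset)
        offset += len(blob)

    out = io.BytesIO()
    out.write(struct.pack("<iiHHii", XDA_MAGIC, WRITE_VERSION,
                          spec.cols, spec.rows, n_units, n_qc))
    out.write(struct.pack("<i", len(ref)))
    out.write(ref)
    for ps in spec.probe_sets:
        out.write(_pack_name(ps.name))
    for pos in positions[:n_qc]:
        out.write(struct.pack("<i", pos))
    for pos in positions[n_qc:]:
        out.write(struct.pack("<i", pos))
    for blob in qc_payloads + unit_payloads:
        out.write(blob)
    return out.getvalue()


def _pack_name(name: str) -> bytes:
    raw = name.encode("ascii")
    if len(raw) >= _NAME_WIDTH:
        raise XdaCdfError(f"probe set name {name!r} exceeds "
                          f"{_NAME_WIDTH - 1} bytes")
    return raw.ljust(_NAME_WIDTH, b"\x00")


def _serialize_qc(qc: QCUnit) -> bytes:
    out = io.BytesIO()
    out.write(struct.pack("<Hi", qc.qc_type, len(qc.cells)))
    for c in qc.cells:
        out.write(struct.pack("<HHBBB", c.x, c.y, c.probe_length,
                              c.pm_flag, c.background_flag))
    return out.getvalue()


def _serialize_unit(ps: ProbeSet) -> bytes:
    n_atoms, n_cells = len(ps.pairs), ps.n_cells
    direction = _DIRECTION_CODE[ps.direction]
    first_atom = ps.pairs[0].atom_index if ps.pairs else 0
    out = io.BytesIO()
    out.write(struct.pack("<HBiiiiB", _UNIT_TYPE_CODE.get(ps.unit_type, 3),
                          direction, n_atoms, 1, n_cells, ps.unit_number, 2))
    out.write(struct.pack("<iiBBii", n_atoms, n_cells, 2, direction,
                          first_atom, 0))
    out.write(_pack_name(ps.name))
    for pair in ps.pairs:
        for probe in (pair.pm, pair.mm):
            out.write(struct.pack("<iHHicc", pair.atom_index, probe.x,
                                  probe.y, probe.expos,
                                  probe.pbase.encode("ascii"),
                                  probe.tbase.encode("ascii")))
    return out.getvalue()


def dumps(spec: ArraySpec) -> bytes:
    """Serialize to bytes in memory."""
    require_valid(spec, "write_cdf_xda")
    return _serialize(spec)


def loads(data: bytes, chip_name: str = "") -> ArraySpec:
    """Parse an XDA CDF from an in-memory byte string."""
    return read_cdf_xda(io.BytesIO(data), chip_name=chip_name)
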