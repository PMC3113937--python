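"""In-memory model of an Affymetrix-style array specification.

An array specification describes a rectangular grid of features (probes) and
the grouping of those features into probe sets.  On 3' IVT expression arrays
the atomic unit of membership is the probe *pair*: a perfect-match (PM) probe
and its mismatch (MM) partner, which differs from the PM only at the central
base.  Every reader, writer, filter and editor in this package targets the
types defined here.

Conventions fixed by this module:

* Coordinates are 0-based; ``x`` indexes columns, ``y`` indexes rows.
* ``cell_index = y * cols + x`` (the CDF cell INDEX convention).
* A cell read from a CDF is classified PM when its probe base is the
  Watson-Crick complement of its target base, and MM when the two are equal.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Uniform probe length on the supported 3' IVT expression arrays.
PROBE_LENGTH = 25


class Direction(enum.Enum):
    SENSE = "sense"
    ANTISENSE = "antisense"
    UNKNOWN = "unknown"


class Dialect(enum.Enum):
    ASCII = "ascii"
    XDA = "xda"


@dataclass
class Probe:
    """One feature on the grid: a coordinate plus base annotations.

    ``pbase`` is the base the probe carries at the interrogation position and
    ``tbase`` the base of the target there; ``expos`` is the expression
    position ordinal carried through from the source file.  ``sequence`` is
    optional and, when present, must have the array's uniform probe length.
    """

    x: int
    y: int
    pbase: str = "N"
    tbase: str = "N"
    expos: int = 0
    sequence: Optional[str] = None

    def cell_index(self, cols: int) -> int:
        return cell_index(self.x, self.y, cols)

    @property
    def is_pm(self) -> bool:
        """PM iff the probe base complements the target base."""
        return COMPLEMENT.get(self.tbase) == self.pbase


@dataclass
class ProbePair:
    """Atomic PM+MM unit; membership editing never splits a pair."""

    atom_index: int
    pm: Probe
    mm: Probe
    interrogation_position: int = 0


@dataclass
class ProbeSet:
    """Named, ordered group of probe pairs interrogating one target."""

    name: str
    pairs: list[ProbePair] = field(default_factory=list)
    unit_number: int = 1
    unit_type: str = "expression"
    direction: Direction = Direction.ANTISENSE

    @property
    def n_cells(self) -> int:
        return 2 * len(self.pairs)

    def probes(self) -> Iterator[Probe]:
        for pair in self.pairs:
            yield pair.pm
            yield pair.mm


@dataclass
class QCCell:
    x: int
    y: int
    probe_length: int = PROBE_LENGTH
    pm_flag: int = 0
    background_flag: int = 0


@dataclass
class QCUnit:
    """Non-expression control block, preserved but never filtered."""

    qc_type: int
    cells: list[QCCell] = field(default_factory=list)


@dataclass
class ArraySpec:
    """A full chip definition.

    ``rows``/``cols`` give the grid size in features.  ``probe_sets`` are kept
    in file order.  ``qc_blocks`` are opaque to every operation except the
    writers, which copy them verbatim.  Provenance fields (``source_dialect``,
    ``dialect_version``, ``is_custom``, ``parent_name``) record where the spec
    came from and never participate in model equality.
    """

    chip_name: str
    rows: int
    cols: int
    probe_sets: list[ProbeSet] = field(default_factory=list)
    qc_blocks: list[QCUnit] = field(default_factory=list)
    source_dialect: Optional[Dialect] = None
    dialect_version: Optional[int] = None
    is_custom: bool = False
    parent_name: Optional[str] = None
    extra_headers: dict[str, str] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return sum(len(ps.pairs) for ps in self.probe_sets)

    @property
    def n_probes(self) -> int:
        return 2 * self.n_pairs

    def probe_set(self, name: str) -> ProbeSet:
        for ps in self.probe_sets:
            if ps.name == name:
                return ps
        raise KeyError(f"no probe set named {name!r}")

    def set_names(self) -> list[str]:
        return [ps.name for ps in self.probe_sets]


class ViolationCode(enum.Enum):
    """Closed set of validation failure codes."""

    BAD_GRID = "bad_grid"                    # rows or cols not positive
    DUPLICATE_SET_NAME = "duplicate_set_name"
    COORD_OUT_OF_GRID = "coord_out_of_grid"
    DUPLICATE_COORD = "duplicate_coord"      # (x, y) used by >1 probe
    EMPTY_SET = "empty_set"
    ATOM_ORDER = "atom_order"                # atom indices not unique/ascending
    PAIR_SAME_COORD = "pair_same_coord"      # PM and MM share a coordinate
    SEQ_LENGTH = "seq_length"                # PM/MM sequences unequal length
    SEQ_MISMATCH_COUNT = "seq_mismatch_count"  # PM/MM differ at != 1 offset
    MISSING_PARENT = "missing_parent"        # custom spec without parent name
    MM_NOT_BELOW_PM = "mm_not_below_pm"      # informational: vendor layout


#: Codes reported only when informational notes are requested.
INFO_CODES = frozenset({ViolationCode.MM_NOT_BELOW_PM})


@dataclass(frozen=True)
class Violation:
    code: ViolationCode
    message: str
    locus: str = ""

    @property
    def is_info(self) -> bool:
        return self.code in INFO_CODES


def cell_index(x: int, y: int, cols: int) -> int:
    """Map a 0-based (x, y) coordinate to its linear cell index.

    The mapping is ``y * cols + x`` and is a bijection with (x, y) for a
    given number of columns.
    """
    if cols <= 0:
        raise ValueError(f"cols must be positive, got {cols}")
    if not (0 <= x < cols):
        raise ValueError(f"x={x} out of range [0, {cols})")
    if y < 0:
        raise ValueError(f"y={y} must be non-negative")
    return y * cols + x


def cell_coords(index: int, cols: int) -> tuple[int, int]:
    """Inverse of :func:`cell_index`: linear index back to (x, y)."""
    if cols <= 0:
        raise ValueError(f"cols must be positive, got {cols}")
    if index < 0:
        raise ValueError(f"index={index} must be non-negative")
    return index % cols, index // cols


def validate_spec(spec: ArraySpec, include_info: bool = False) -> list[Violation]:
    """Check every structural invariant of a spec; violations are data.

    Returns an empty list iff all invariants hold (ignoring informational
    notes unless ``include_info`` is set).  Never mutates the input.
    """
    out: list[Violation] = []

    if spec.rows <= 0 or spec.cols <= 0:
        out.append(Violation(ViolationCode.BAD_GRID,
                             f"grid {spec.rows}x{spec.cols} not positive"))

    seen_names: set[str] = set()
    coord_owner: dict[tuple[int, int], str] = {}

    for ps in spec.probe_sets:
        if ps.name in seen_names:
            out.append(Violation(ViolationCode.DUPLICATE_SET_NAME,
                                 f"probe set name {ps.name!r} repeated", ps.name))
        seen_names.add(ps.name)

        if not ps.pairs:
            out.append(Violation(ViolationCode.EMPTY_SET,
                                 f"probe set {ps.name!r} has no pairs", ps.name))

        prev_atom = None
        for pair in ps.pairs:
            if prev_atom is not None and pair.atom_index <= prev_atom:
                out.append(Violation(
                    ViolationCode.ATOM_ORDER,
                    f"atom index {pair.atom_index} not ascending in {ps.name!r}",
                    ps.name))
            prev_atom = pair.atom_index

            pm, mm = pair.pm, pair.mm
            if (pm.x, pm.y) == (mm.x, mm.y):
                out.append(Violation(
                    ViolationCode.PAIR_SAME_COORD,
                    f"PM and MM share ({pm.x},{pm.y}) in {ps.name!r}", ps.name))
            if include_info and (mm.x, mm.y) != (pm.x, pm.y + 1):
                out.append(Violation(
                    ViolationCode.MM_NOT_BELOW_PM,
                    f"MM at ({mm.x},{mm.y}) not directly below PM "
                    f"({pm.x},{pm.y}) in {ps.name!r}", ps.name))

            for probe in (pm, mm):
                coord = (probe.x, probe.y)
                if not (0 <= probe.x < spec.cols and 0 <= probe.y < spec.rows):
                    out.append(Violation(
                        ViolationCode.COORD_OUT_OF_GRID,
                        f"probe at ({probe.x},{probe.y}) outside "
                        f"{spec.cols}x{spec.rows} grid in {ps.name!r}",
                        f"{ps.name}@{coord}"))
                if coord in coord_owner:
                    out.append(Violation(
                        ViolationCode.DUPLICATE_COORD,
                        f"coordinate {coord} used by both "
                        f"{coord_owner[coord]!r} and {ps.name!r}",
                        f"{ps.name}@{coord}"))
                else:
                    coord_owner[coord] = ps.name

            if pm.sequence is not None and mm.sequence is not None:
                if len(pm.sequence) != len(mm.sequence):
                    out.append(Violation(
                        ViolationCode.SEQ_LENGTH,
                        f"PM/MM sequence lengths differ in {ps.name!r} "
                        f"atom {pair.atom_index}", ps.name))
                else:
                    diffs = sum(a != b for a, b in
                                zip(pm.sequence, mm.sequence))
                    if diffs != 1:
                        out.append(Violation(
                            ViolationCode.SEQ_MISMATCH_COUNT,
                            f"PM/MM sequences differ at {diffs} offsets "
                            f"(expected 1) in {ps.name!r} atom "
                            f"{pair.atom_index}", ps.name))

    if spec.is_custom and not spec.parent_name:
        out.append(Violation(ViolationCode.MISSING_PARENT,
                             "custom spec lacks a parent name"))

    if not include_info:
        out = [v for v in out if not v.is_info]
    return out


# ---------------------------------------------------------------------------
# model equality


def _probe_key(p: Probe, with_seq: bool) -> tuple:
    base = (p.x, p.y, p.pbase, p.tbase, p.expos)
    return base + (p.sequence,) if with_seq else base


def _set_key(ps: ProbeSet, with_seq: bool) -> tuple:
    return (
        ps.name,
        ps.unit_type,
        ps.direction.value,
        tuple((pr.atom_index, pr.interrogation_position,
               _probe_key(pr.pm, with_seq), _probe_key(pr.mm, with_seq))
              for pr in ps.pairs),
    )


def model_key(spec: ArraySpec, include_sequences: bool = False) -> tuple:
    """Canonical tuple of everything that defines the spec's content.

    Provenance (dialect, version, custom/parent flags) and preserved unknown
    headers are deliberately excluded so that cross-dialect round trips
    compare equal.  Probe sequences are excluded by default because neither
    CDF dialect stores them; pass ``include_sequences=True`` to compare
    annotation state as well.
    """
    return (
        spec.chip_name,
        spec.rows,
        spec.cols,
        tuple(_set_key(ps, include_sequences) for ps in spec.probe_sets),
        tuple((qc.qc_type,
               tuple((c.x, c.y, c.probe_length, c.pm_flag, c.background_flag)
                     for c in qc.cells))
              for qc in spec.qc_blocks),
    )


def model_equal(a: ArraySpec, b: ArraySpec,
                include_sequences: bool = False) -> bool:
    """Content equality: names, dims, pair membership, coordinates, bases,
    atom order and QC blocks — ignoring provenance (and, by default,
    sequences, which CDF files cannot carry)."""
    return (model_key(a, include_sequences)
            == model_key(b, include_sequences))


def copy_spec(spec: ArraySpec) -> ArraySpec:
    """Deep, independent copy (editing the copy never touches the source)."""
    return ArraySpec(
        chip_name=spec.chip_name,
        rows=spec.rows,
        cols=spec.cols,
        probe_sets=[
            ProbeSet(
                name=ps.name,
                unit_number=ps.unit_number,
                unit_type=ps.unit_type,
                direction=ps.direction,
                pairs=[ProbePair(pr.atom_index, replace(pr.pm), replace(pr.mm),
                                 pr.interrogation_position)
                       for pr in ps.pairs],
            )
            for ps in spec.probe_sets
        ],
        qc_blocks=[QCUnit(qc.qc_type, [replace(c) for c in qc.cells])
                   for qc in spec.qc_blocks],
        source_dialect=spec.source_dialect,
        dialect_version=spec.dialect_version,
        is_custom=spec.is_custom,
        parent_name=spec.parent_name,
        extra_headers=dict(spec.extra_headers),
    )


def iter_pairs(spec: ArraySpec) -> Iterator[tuple[ProbeSet, ProbePair]]:
    for ps in spec.probe_sets:
        for pair in ps.pairs:
            yield ps, pair


def require_valid(spec: ArraySpec, context: str) -> None:
    """Raise ``ValueError`` listing violations; used by writer preconditions."""
    violations = validate_spec(spec)
    if violations:
        summary = "; ".join(v.message for v in violations[:5])
        more = f" (+{len(violations) - 5} more)" if len(violations) > 5 else ""
        raise ValueError(f"{context}: spec fails validation: {summary}{more}")
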