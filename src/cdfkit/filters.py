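"""Probe-pair filters, set algebra across specs, and diff/overlap reports.

Two filter families are implemented:

* **Motif filters** flag whole pairs whose PM or MM sequence contains a
  problematic subsequence.  The stock motifs are the G-run (four or more
  consecutive guanines, matched as any occurrence of ``GGGG``), whose probes
  show spuriously high, mutually correlated intensities, and the primer
  spacer ``CCTCC``, tied to T7-amplification bias during target prep.
* **Keep-list filters** remove every pair whose PM coordinate is absent
  from an externally supplied list of surviving probes (e.g. a BaFL-style
  deprecation output).

Filters operate on pairs, never single probes.  After pair removal, any
probe set left with fewer than ``min_pairs_remaining`` pairs (default 4) is
dropped entirely, and the report classifies every original set as removed,
modified or unmodified.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, NamedTuple, Sequence, Union

from cdfkit.model import (
    ArraySpec,
    ProbePair,
    ProbeSet,
    copy_spec,
    require_valid,
)

logger = logging.getLogger(__name__)

DEFAULT_MOTIFS = ("GGGG", "CCTCC")
DEFAULT_MIN_PAIRS = 4


class PairKey(NamedTuple):
    """Canonical identity of one probe pair: owning set + PM coordinate."""

    probe_set_name: str
    pm_x: int
    pm_y: int


@dataclass(frozen=True)
class MotifFilter:
    """Configuration for sequence-motif screening.

    ``search_in`` scopes the scan to the PM sequence, the MM sequence or
    both (the default: a motif in either partner condemns the pair).
    Motifs are matched as plain substrings on the stored sequence — no
    reverse-complement search.
    """

    motifs: tuple[str, ...] = DEFAULT_MOTIFS
    search_in: str = "both"          # pm | mm | both
    min_pairs_remaining: int = DEFAULT_MIN_PAIRS

    def __post_init__(self):
        if not self.motifs:
            raise ValueError("MotifFilter needs at least one motif")
        if self.search_in not in ("pm", "mm", "both"):
            raise ValueError(f"search_in must be pm|mm|both, got "
                             f"{self.search_in!r}")
        if self.min_pairs_remaining < 1:
            raise ValueError("min_pairs_remaining must be >= 1")


@dataclass
class FilterReport:
    """Classification of every examined probe set after a removal pass."""

    pairs_flagged: list[PairKey] = field(default_factory=list)
    removed_set_names: list[str] = field(default_factory=list)
    sets_modified: int = 0
    sets_unmodified: int = 0

    @property
    def sets_removed(self) -> int:
        return len(self.removed_set_names)

    @property
    def sets_examined(self) -> int:
        return self.sets_removed + self.sets_modified + self.sets_unmodified


@dataclass
class SpecDiff:
    """Default-vs-custom comparison: classification plus removal histogram."""

    removed_sets: list[str] = field(default_factory=list)
    modified_sets: list[str] = field(default_factory=list)
    unmodified_sets: list[str] = field(default_factory=list)
    added_sets: list[str] = field(default_factory=list)
    pairs_removed_histogram: dict[int, int] = field(default_factory=dict)
    pairs_removed_by_set: dict[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return len(self.removed_sets)

    @property
    def n_modified(self) -> int:
        return len(self.modified_sets)

    @property
    def n_unmodified(self) -> int:
        return len(self.unmodified_sets)


class OverlapCounts(NamedTuple):
    """Venn partition of two removal collections."""

    only_a: int
    only_b: int
    both: int

    @property
    def total(self) -> int:
        return self.only_a + self.only_b + self.both


def pair_key(set_name: str, pair: ProbePair) -> PairKey:
    return PairKey(set_name, pair.pm.x, pair.pm.y)


def spec_pair_keys(spec: ArraySpec) -> set[PairKey]:
    return {pair_key(ps.name, pr) for ps in spec.probe_sets
            for pr in ps.pairs}


def flag_motif_pairs(spec: ArraySpec,
                     filter: MotifFilter = MotifFilter()) -> list[PairKey]:
    """Flag every pair with a motif occurrence in the scoped sequence(s).

    All probes in scope must carry sequences (generate MM sequences first if
    the import provided only PM).  Whole pairs are flagged, never single
    probes.  Returned keys follow spec order.
    """
    flagged: list[PairKey] = []
    for ps in spec.probe_sets:
        for pair in ps.pairs:
            in_scope = []
            if filter.search_in in ("pm", "both"):
                in_scope.append(("PM", pair.pm))
            if filter.search_in in ("mm", "both"):
                in_scope.append(("MM", pair.mm))
            hit = False
            for label, probe in in_scope:
                if probe.sequence is None:
                    raise ValueError(
                        f"{label} probe at ({probe.x},{probe.y}) in "
                        f"{ps.name!r} has no sequence; import/generate "
                        "sequences before motif filtering")
                if any(m in probe.sequence for m in filter.motifs):
                    hit = True
            if hit:
                flagged.append(pair_key(ps.name, pair))
    return flagged


def pairs_from_keep_list(spec: ArraySpec,
                         kept_pm_coordinates: Iterable[tuple[int, int]],
                         ) -> list[PairKey]:
    """Invert a keep-list into the pairs to *remove*.

    A pair survives iff its PM coordinate appears in the keep-list; the
    returned keys are all the others.  Keep-list coordinates matching no PM
    probe are reported via logging and otherwise ignored.
    """
    kept = set(kept_pm_coordinates)
    pm_coords = {(pr.pm.x, pr.pm.y) for ps in spec.probe_sets
                 for pr in ps.pairs}
    unknown = kept - pm_coords
    if unknown:
        logger.warning("%d keep-list coordinate(s) match no PM probe "
                       "(e.g. %s)", len(unknown), sorted(unknown)[:3])
    return [pair_key(ps.name, pr) for ps in spec.probe_sets
            for pr in ps.pairs if (pr.pm.x, pr.pm.y) not in kept]


def read_keep_list(source: Union[str, Path, IO[str]],
                   ) -> list[tuple[int, int]]:
    """Read a BaFL-style keep-list: delimited lines of probe-set name,
    PM x, PM y (header auto-detected; comma or tab separated)."""
    if isinstance(source, (str, Path)):
        with open(source, newline="") as fh:
            return read_keep_list(fh)
    coords = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line:
            continue
        delim = "\t" if "\t" in line else ","
        fields = next(csv.reader([line], delimiter=delim))
        if len(fields) < 3:
            raise ValueError(f"keep-list line {lineno}: expected at least "
                             f"3 columns, got {len(fields)}")
        try:
            coords.append((int(fields[1]), int(fields[2])))
        except ValueError:
            if lineno == 1:
                continue  # header row
            raise ValueError(f"keep-list line {lineno}: non-integer "
                             f"coordinates in {fields!r}") from None
    return coords


def apply_removal(spec: ArraySpec, remove: Iterable[PairKey],
                  min_pairs_remaining: int = DEFAULT_MIN_PAIRS,
                  name: str | None = None) -> tuple[ArraySpec, FilterReport]:
    """Delete the given pairs; prune sets falling below the floor.

    Returns a new custom spec (the input is untouched) plus a report
    classifying every original set.  Every key must resolve to a pair of
    ``spec``.
    """
    require_valid(spec, "apply_removal")
    remove_set = set(remove)
    known = spec_pair_keys(spec)
    bad = remove_set - known
    if bad:
        raise KeyError(f"{len(bad)} removal key(s) resolve to no pair in "
                       f"{spec.chip_name!r} (e.g. {sorted(bad)[:3]})")

    report = FilterReport(pairs_flagged=sorted(remove_set))
    out_sets: list[ProbeSet] = []
    for ps in spec.probe_sets:
        keep = [pr for pr in ps.pairs
                if pair_key(ps.name, pr) not in remove_set]
        if len(keep) == len(ps.pairs):
            report.sets_unmodified += 1
            out_sets.append(_rebuild_set(ps, keep))
        elif len(keep) >= min_pairs_remaining:
            report.sets_modified += 1
            out_sets.append(_rebuild_set(ps, keep))
        else:
            report.removed_set_names.append(ps.name)

    custom = ArraySpec(
        chip_name=name or spec.chip_name,
        rows=spec.rows, cols=spec.cols,
        probe_sets=out_sets,
        qc_blocks=copy_spec(spec).qc_blocks,
        source_dialect=spec.source_dialect,
        dialect_version=spec.dialect_version,
        is_custom=True,
        parent_name=spec.parent_name or spec.chip_name)
    require_valid(custom, "apply_removal (result)")
    return custom, report


def _rebuild_set(ps: ProbeSet, pairs: Sequence[ProbePair]) -> ProbeSet:
    from dataclasses import replace as _replace
    return ProbeSet(
        name=ps.name,
        pairs=[ProbePair(pr.atom_index, _replace(pr.pm), _replace(pr.mm),
                         pr.interrogation_position) for pr in pairs],
        unit_number=ps.unit_number,
        unit_type=ps.unit_type,
        direction=ps.direction)


def set_algebra(a: ArraySpec, b: ArraySpec, op: str,
                min_pairs_remaining: int = DEFAULT_MIN_PAIRS,
                name: str | None = None) -> ArraySpec:
    """Merge two sibling specs by set-theoretic pair membership.

    Per probe-set name, pair membership (keyed by PM coordinate) becomes the
    ``intersect``, ``union`` or ``difference`` of the two inputs; sets left
    below ``min_pairs_remaining`` are dropped.  Both specs must share grid
    dimensions (i.e. derive from the same parent default).
    """
    if op not in ("intersect", "union", "difference"):
        raise ValueError(f"unknown set operation {op!r}")
    if (a.rows, a.cols) != (b.rows, b.cols):
        raise ValueError(
            f"grid mismatch: {a.chip_name!r} is {a.rows}x{a.cols} but "
            f"{b.chip_name!r} is {b.rows}x{b.cols}; the specs do not share "
            "a parent")
    require_valid(a, "set_algebra (a)")
    require_valid(b, "set_algebra (b)")

    b_keys = spec_pair_keys(b)
    b_sets = {ps.name: ps for ps in b.probe_sets}

    out_sets: list[ProbeSet] = []
    for ps in a.probe_sets:
        a_pairs = {pair_key(ps.name, pr): pr for pr in ps.pairs}
        if op == "intersect":
            chosen = [pr for k, pr in a_pairs.items() if k in b_keys]
        elif op == "difference":
            chosen = [pr for k, pr in a_pairs.items() if k not in b_keys]
        else:  # union: a's pairs, then b-only pairs of the same set
            chosen = list(a_pairs.values())
            if ps.name in b_sets:
                chosen += [pr for pr in b_sets[ps.name].pairs
                           if pair_key(ps.name, pr) not in a_pairs]
                chosen.sort(key=lambda pr: (pr.pm.y, pr.pm.x))
        if len(chosen) >= min_pairs_remaining:
            rebuilt = _rebuild_set(ps, chosen)
            for i, pr in enumerate(rebuilt.pairs):
                pr.atom_index = i
            out_sets.append(rebuilt)
    if op == "union":
        for ps in b.probe_sets:
            if all(ps.name != o.name for o in out_sets) and \
                    len(ps.pairs) >= min_pairs_remaining and \
                    ps.name not in {s.name for s in a.probe_sets}:
                out_sets.append(_rebuild_set(ps, ps.pairs))

    result = ArraySpec(
        chip_name=name or f"{a.chip_name}_{op}_{b.chip_name}",
        rows=a.rows, cols=a.cols,
        probe_sets=out_sets,
        qc_blocks=copy_spec(a).qc_blocks,
        source_dialect=a.source_dialect,
        dialect_version=a.dialect_version,
        is_custom=True,
        parent_name=a.parent_name or a.chip_name)
    require_valid(result, "set_algebra (result)")
    return result


def diff_specs(default_spec: ArraySpec, custom_spec: ArraySpec,
               standard_size: int | None = None) -> SpecDiff:
    """Classify every default probe set against a derived custom spec.

    A set is *removed* when absent from the custom spec, *modified* when
    present with fewer pairs, and *unmodified* when pair membership (by PM
    coordinate) is identical.  The histogram maps k (pairs removed) to the
    number of shared sets losing exactly k pairs.  ``standard_size``
    restricts the analysis to default sets with exactly that many pairs
    (16 covers the vast majority of sets on the supported arrays).  Custom
    sets with no default counterpart are reported as added.
    """
    custom_by_name = {ps.name: ps for ps in custom_spec.probe_sets}
    diff = SpecDiff()
    considered: set[str] = set()
    for ps in default_spec.probe_sets:
        if standard_size is not None and len(ps.pairs) != standard_size:
            continue
        considered.add(ps.name)
        custom = custom_by_name.get(ps.name)
        if custom is None:
            diff.removed_sets.append(ps.name)
            continue
        default_keys = {(pr.pm.x, pr.pm.y) for pr in ps.pairs}
        custom_keys = {(pr.pm.x, pr.pm.y) for pr in custom.pairs}
        k = len(default_keys - custom_keys)
        diff.pairs_removed_by_set[ps.name] = k
        diff.pairs_removed_histogram[k] = \
            diff.pairs_removed_histogram.get(k, 0) + 1
        if k == 0 and custom_keys == default_keys:
            diff.unmodified_sets.append(ps.name)
        else:
            diff.modified_sets.append(ps.name)
    diff.added_sets = [name for name in custom_by_name
                       if name not in {ps.name
                                       for ps in default_spec.probe_sets}]
    return diff


def removed_pair_keys(default_spec: ArraySpec,
                      custom_spec: ArraySpec) -> set[PairKey]:
    """Pairs of the default spec absent from the custom spec (including all
    pairs of wholly removed sets)."""
    return spec_pair_keys(default_spec) - spec_pair_keys(custom_spec)


def overlap_counts(removed_a: Iterable, removed_b: Iterable) -> OverlapCounts:
    """Three-way Venn partition of two removal collections.

    Works on any hashable keys: :class:`PairKey` objects for pair
    granularity, or probe-set names for set granularity.
    """
    sa, sb = set(removed_a), set(removed_b)
    return OverlapCounts(only_a=len(sa - sb), only_b=len(sb - sa),
                         both=len(sa & sb))


def affected_set_names(removed: Iterable[PairKey]) -> set[str]:
    """Probe sets touched by a removal collection (modified or removed)."""
    return {k.probe_set_name for k in removed}
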