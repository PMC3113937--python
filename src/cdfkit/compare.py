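"""Delta analysis: percent change of custom vs default expression values.

Summarization itself (MAS 5.0, dChip, RMA, ...) is external to this
package; the inputs here are two delimited expression tables — probe-set
rows by array columns — computed once with the default probe-set
definitions and once with a custom derivation.  For each probe set the
percent change is

    delta = 100 * (E_c - E_d) / E_d

with E_c the custom and E_d the default expression value.  Deltas are then
averaged per k, the number of probe pairs the custom spec removed from the
set, yielding the curve of mean percent change against pairs removed
(k = 0..12 by default: with 16-pair sets and a 4-pair floor at most 12
pairs can go).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Union

import pandas as pd


@dataclass
class DeltaCurve:
    """Mean percent change per number of pairs removed, with support."""

    mean_percent_change: dict[int, float] = field(default_factory=dict)
    support: dict[int, int] = field(default_factory=dict)  # observations per k

    def as_frame(self) -> pd.DataFrame:
        ks = sorted(self.mean_percent_change)
        return pd.DataFrame(
            {"pairs_removed": ks,
             "mean_percent_change": [self.mean_percent_change[k] for k in ks],
             "n_observations": [self.support[k] for k in ks]})

    def to_csv(self, dest: Union[str, Path, IO[str]]) -> None:
        self.as_frame().to_csv(dest, index=False)


def percent_change(e_custom: float, e_default: float) -> float:
    """100 * (E_c - E_d) / E_d.  The default value anchors the scale, so the
    function is not symmetric in its arguments."""
    if e_default <= 0:
        raise ValueError(f"default expression value must be positive, got "
                         f"{e_default}")
    return 100.0 * (e_custom - e_default) / e_default


def read_expression_table(source: Union[str, Path, IO[str]]) -> pd.DataFrame:
    """Read a delimited expression table: probe-set rows x array columns,
    first column the probe-set name, header row present."""
    df = pd.read_csv(source, index_col=0)
    if df.empty or df.shape[1] == 0:
        raise ValueError("expression table has no array columns")
    return df


def aggregate_delta(default_table: pd.DataFrame,
                    custom_table: pd.DataFrame,
                    pairs_removed: Mapping[str, int],
                    k_range: tuple[int, int] = (0, 12),
                    per_array_mean: bool = False) -> DeltaCurve:
    """Average percent change per k over all (array, probe set) observations.

    ``custom_table``'s probe sets must be a subset of ``default_table``'s
    and each must have an entry in ``pairs_removed``; sets whose k falls
    outside ``k_range`` are excluded.  By default all observations are
    pooled; with ``per_array_mean`` the curve averages the per-array means
    instead (identical when every array contributes the same sets).
    """
    missing_sets = custom_table.index.difference(default_table.index)
    if len(missing_sets):
        raise ValueError(
            f"{len(missing_sets)} probe set(s) in the custom table have no "
            f"default counterpart (e.g. {list(missing_sets[:3])})")
    missing_k = [s for s in custom_table.index if s not in pairs_removed]
    if missing_k:
        raise ValueError(
            f"{len(missing_k)} probe set(s) lack a pairs-removed entry "
            f"(e.g. {missing_k[:3]})")
    arrays = default_table.columns.intersection(custom_table.columns)
    if len(arrays) == 0:
        raise ValueError("the two tables share no array columns")

    lo, hi = k_range
    sets = [s for s in custom_table.index if lo <= pairs_removed[s] <= hi]
    d = default_table.loc[sets, arrays]
    c = custom_table.loc[sets, arrays]
    if (d <= 0).any().any():
        raise ValueError("default expression values must be positive")
    delta = 100.0 * (c - d) / d
    ks = pd.Series({s: pairs_removed[s] for s in sets})

    curve = DeltaCurve()
    for k, block in delta.groupby(ks):
        k = int(k)
        if per_array_mean:
            curve.mean_percent_change[k] = float(block.mean(axis=0).mean())
        else:
            curve.mean_percent_change[k] = float(block.values.mean())
        curve.support[k] = int(block.size)
    return curve
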