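"""Deterministic synthetic array specs, probe sequences and expression tables.

Everything in this package is testable without vendor downloads: the
generator builds a validated spec whose probes carry sequences, optionally
planting the G-run (``GGGG``) and primer-spacer (``CCTCC``) motifs into a
known subset of pairs.  Background sequences are rejection-sampled so that
*neither* motif occurs in either the PM or the derived MM sequence, making
the planted ground truth unambiguous: a pair is flagged by the motif filter
iff it was planted.

The expression-table generator is a stand-in for external summarization
(MAS 5.0 / dChip / RMA are deliberately not reimplemented): per (array,
probe set) it draws a positive baseline intensity and scales the custom
value by a configured function of k, the number of pairs removed from that
set, plus optional log-normal noise — giving the delta analysis a known
recovery target.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import pandas as pd

from cdfkit.model import (
    COMPLEMENT,
    ArraySpec,
    Direction,
    Probe,
    ProbePair,
    ProbeSet,
    require_valid,
)
from cdfkit.filters import PairKey, diff_specs
from cdfkit.sequences import mm_from_pm

PROBE_LEN = 25
_MOTIFS = ("GGGG", "CCTCC")


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    Defaults mirror the supported expression arrays: 16 pairs per set
    (the size of the vast majority of probe sets), 25-mer probes with the
    interrogation position at the central base, and the vendor layout of
    the MM feature directly below its PM.
    """

    n_sets: int = 10
    pairs_per_set: int = 16
    rows: int = 40
    cols: int = 40
    seed: int = 0
    frac_grun: float = 0.0
    frac_spacer: float = 0.0
    chip_name: str = "synthchip"

    def __post_init__(self):
        n_pairs = self.n_sets * self.pairs_per_set
        if not (0 <= self.frac_grun <= 1 and 0 <= self.frac_spacer <= 1):
            raise ValueError("motif fractions must lie in [0, 1]")
        if self.frac_grun + self.frac_spacer > 1:
            raise ValueError("motif fractions sum to more than 1")
        needed_rows = 2 * math.ceil(n_pairs / self.cols)
        if 2 * n_pairs > self.rows * self.cols or needed_rows > self.rows:
            raise ValueError(
                f"grid {self.rows}x{self.cols} cannot hold {n_pairs} pairs "
                f"({2 * n_pairs} probes) in the PM-over-MM layout")


@dataclass(frozen=True)
class GroundTruth:
    """Which pairs carry planted motifs."""

    grun: frozenset[PairKey]
    spacer: frozenset[PairKey]

    @property
    def flagged(self) -> frozenset[PairKey]:
        return self.grun | self.spacer


def _background_25mer(rng: random.Random) -> str:
    """A 25-mer free of both motifs in the PM *and* its MM counterpart."""
    while True:
        seq = "".join(rng.choice("ACGT") for _ in range(PROBE_LEN))
        mm = mm_from_pm(seq)
        if not any(m in s for m in _MOTIFS for s in (seq, mm)):
            return seq


def _plant(seq: str, motif: str, rng: random.Random) -> str:
    offset = rng.randrange(PROBE_LEN - len(motif) + 1)
    return seq[:offset] + motif + seq[offset + len(motif):]


def make_spec(config: SynthConfig) -> tuple[ArraySpec, GroundTruth]:
    """Build a validated, sequence-annotated spec plus planted ground truth.

    Output is a pure function of the config: the same config always yields
    a model-equal spec.  Pairs use the vendor layout (MM directly below its
    PM); coordinates never collide by construction.
    """
    rng = random.Random(config.seed)
    n_pairs = config.n_sets * config.pairs_per_set

    n_grun = round(config.frac_grun * n_pairs)
    n_spacer = round(config.frac_spacer * n_pairs)
    planted = rng.sample(range(n_pairs), n_grun + n_spacer)
    grun_idx = set(planted[:n_grun])
    spacer_idx = set(planted[n_grun:])

    probe_sets: list[ProbeSet] = []
    grun_keys: set[PairKey] = set()
    spacer_keys: set[PairKey] = set()
    pair_no = 0
    for s in range(config.n_sets):
        set_name = f"synset{s + 1:04d}_at"
        pairs = []
        for a in range(config.pairs_per_set):
            x = pair_no % config.cols
            y_pm = 2 * (pair_no // config.cols)
            pm_seq = _background_25mer(rng)
            if pair_no in grun_idx:
                pm_seq = _plant(pm_seq, "GGGG", rng)
                grun_keys.add(PairKey(set_name, x, y_pm))
            elif pair_no in spacer_idx:
                pm_seq = _plant(pm_seq, "CCTCC", rng)
                spacer_keys.add(PairKey(set_name, x, y_pm))
            mm_seq = mm_from_pm(pm_seq)
            central = pm_seq[PROBE_LEN // 2]
            tbase = COMPLEMENT[central]
            pm = Probe(x=x, y=y_pm, pbase=central, tbase=tbase, expos=a,
                       sequence=pm_seq)
            mm = Probe(x=x, y=y_pm + 1, pbase=COMPLEMENT[central],
                       tbase=tbase, expos=a, sequence=mm_seq)
            pairs.append(ProbePair(atom_index=a, pm=pm, mm=mm,
                                   interrogation_position=13))
            pair_no += 1
        probe_sets.append(ProbeSet(name=set_name, pairs=pairs,
                                   unit_number=s + 1,
                                   direction=Direction.ANTISENSE))

    spec = ArraySpec(chip_name=config.chip_name, rows=config.rows,
                     cols=config.cols, probe_sets=probe_sets)
    require_valid(spec, "make_spec")
    return spec, GroundTruth(grun=frozenset(grun_keys),
                             spacer=frozenset(spacer_keys))


def default_effect(k: int) -> float:
    """The stock planted effect: +10% expression per removed pair."""
    return 1.0 + 0.10 * k


def make_expression_table(
    spec_default: ArraySpec,
    spec_custom: ArraySpec,
    n_arrays: int,
    seed: int = 0,
    effect: Callable[[int], float] = default_effect,
    noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired default/custom expression tables with a planted k-effect.

    Rows are probe sets, columns are array labels.  The default value for
    each (set, array) is log-normal around a few hundred units (a typical
    summarized-intensity scale); the custom value is the default scaled by
    ``effect(k)`` — k being the number of pairs the custom spec removed
    from that set — times multiplicative log-normal noise of spread
    ``noise_sd`` (in log units; 0 gives exact recovery).
    """
    if n_arrays < 1:
        raise ValueError("n_arrays must be >= 1")
    rng = random.Random(seed)
    k_by_set = diff_specs(spec_default, spec_custom).pairs_removed_by_set

    arrays = [f"array{i + 1:02d}" for i in range(n_arrays)]
    custom_sets = [ps.name for ps in spec_custom.probe_sets]
    default_sets = [ps.name for ps in spec_default.probe_sets]

    default_rows = {}
    custom_rows = {name: [] for name in custom_sets}
    for name in default_sets:
        base = [math.exp(rng.gauss(5.5, 1.0)) for _ in arrays]
        default_rows[name] = base
        if name in custom_rows:
            mult = effect(k_by_set[name])
            custom_rows[name] = [
                v * mult * math.exp(rng.gauss(0.0, noise_sd)) if noise_sd
                else v * mult
                for v in base]

    default_df = pd.DataFrame.from_dict(default_rows, orient="index",
                                        columns=arrays)
    custom_df = pd.DataFrame.from_dict(custom_rows, orient="index",
                                       columns=arrays).loc[custom_sets]
    return default_df, custom_df


def write_fixture_dir(config: SynthConfig, outdir: str | Path,
                      n_arrays: int = 0) -> dict[str, Path]:
    """Emit a self-contained fixture directory: ASCII CDF, tab-delimited
    probe sequences, planted ground truth CSV and (optionally) paired
    expression tables.  Returns the paths written, keyed by role."""
    from cdfkit.io_ascii import write_cdf_ascii
    from cdfkit.sequences import export_sequences
    from cdfkit.filters import MotifFilter, apply_removal, flag_motif_pairs

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec, truth = make_spec(config)

    paths = {"cdf": outdir / f"{config.chip_name}.cdf",
             "sequences": outdir / f"{config.chip_name}_probes.tab",
             "truth": outdir / f"{config.chip_name}_planted.csv"}
    write_cdf_ascii(spec, paths["cdf"])
    export_sequences(spec, "delimited", paths["sequences"])
    with open(paths["truth"], "w") as fh:
        fh.write("motif,probe_set,pm_x,pm_y\n")
        for label, keys in (("grun", truth.grun), ("spacer", truth.spacer)):
            for key in sorted(keys):
                fh.write(f"{label},{key.probe_set_name},{key.pm_x},"
                         f"{key.pm_y}\n")

    if n_arrays:
        custom, _ = apply_removal(spec, flag_motif_pairs(spec, MotifFilter()))
        dflt, cust = make_expression_table(spec, custom, n_arrays,
                                           seed=config.seed)
        paths["expression_default"] = outdir / "expression_default.csv"
        paths["expression_custom"] = outdir / "expression_custom.csv"
        dflt.to_csv(paths["expression_default"], index_label="probe_set")
        cust.to_csv(paths["expression_custom"], index_label="probe_set")
    return paths
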