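"""Shared fixtures: tiny hand-built specs and seeded synthetic chips."""

import pytest

from cdfkit.model import ArraySpec, Direction, Probe, ProbePair, ProbeSet
from cdfkit.synthetic import SynthConfig, make_spec


def build_pair(atom, x, y, pbase="A", pos=13, expos=None, pm_seq=None,
               mm_seq=None):
    """PM at (x, y) with MM directly below, vendor-style."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    tbase = comp[pbase]
    pm = Probe(x=x, y=y, pbase=pbase, tbase=tbase,
               expos=atom if expos is None else expos, sequence=pm_seq)
    mm = Probe(x=x, y=y + 1, pbase=comp[pbase], tbase=tbase,
               expos=atom if expos is None else expos, sequence=mm_seq)
    return ProbePair(atom_index=atom, pm=pm, mm=mm,
                     interrogation_position=pos)


def build_spec(sets, rows=8, cols=8, name="handchip"):
    """sets: list of (name, n_pairs); pairs laid out left-to-right, two grid
    rows per probe-set row band."""
    probe_sets = []
    pair_no = 0
    for i, (set_name, n_pairs) in enumerate(sets):
        pairs = []
        for a in range(n_pairs):
            x = pair_no % cols
            y = 2 * (pair_no // cols)
            pairs.append(build_pair(a, x, y))
            pair_no += 1
        probe_sets.append(ProbeSet(name=set_name, pairs=pairs,
                                   unit_number=i + 1,
                                   direction=Direction.ANTISENSE))
    return ArraySpec(chip_name=name, rows=rows, cols=cols,
                     probe_sets=probe_sets)


@pytest.fixture
def two_set_spec():
    return build_spec([("alpha_at", 3), ("beta_at", 2)])


@pytest.fixture(scope="session")
def planted():
    """A 10-set chip with 25% G-run and 10% spacer pairs planted."""
    config = SynthConfig(n_sets=10, pairs_per_set=16, rows=40, cols=40,
                         seed=7, frac_grun=0.25, frac_spacer=0.10)
    return make_spec(config)


@pytest.fixture(scope="session")
def clean_chip():
    """A motif-free sequence-annotated chip."""
    spec, truth = make_spec(SynthConfig(n_sets=6, pairs_per_set=16,
                                        rows=40, cols=40, seed=11))
    assert not truth.flagged
    return spec
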