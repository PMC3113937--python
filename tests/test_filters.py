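"""Motif and keep-list filters, pruning, set algebra, diffs and overlaps."""

import io

import pytest

from cdfkit.filters import (
    MotifFilter,
    PairKey,
    apply_removal,
    diff_specs,
    flag_motif_pairs,
    overlap_counts,
    affected_set_names,
    pair_key,
    pairs_from_keep_list,
    read_keep_list,
    removed_pair_keys,
    set_algebra,
    spec_pair_keys,
)
from cdfkit.model import copy_spec, model_equal
from cdfkit.sequences import mm_from_pm
from conftest import build_spec

CLEAN = "ATATATATATATATATATATATATA"


def annotate(spec, sequences):
    """Assign PM sequences (list per spec order) and derive MMs."""
    i = 0
    for ps in spec.probe_sets:
        for pair in ps.pairs:
            pair.pm.sequence = sequences[i]
            pair.mm.sequence = mm_from_pm(sequences[i])
            i += 1


class TestMotifFlagging:
    def test_g_run_needs_four_gs(self):
        spec = build_spec([("a_at", 2)], rows=4, cols=4)
        annotate(spec, ["ATATGGGGATATATATATATATATA",
                        "ATATGGGATATATATATATATATAT"])
        flagged = flag_motif_pairs(spec, MotifFilter())
        assert flagged == [PairKey("a_at", 0, 0)]

    def test_search_scope_pm_vs_both(self):
        spec = build_spec([("a_at", 1)], rows=4, cols=4)
        pair = spec.probe_sets[0].pairs[0]
        pair.pm.sequence = CLEAN
        pair.mm.sequence = "ATATCCTCCATATATATATATATAT"
        assert flag_motif_pairs(spec, MotifFilter(search_in="both")) == \
            [PairKey("a_at", 0, 0)]
        assert flag_motif_pairs(spec, MotifFilter(search_in="pm")) == []

    def test_planted_spec_recovered_exactly(self, planted):
        spec, truth = planted
        flagged = set(flag_motif_pairs(spec, MotifFilter()))
        assert flagged == set(truth.flagged)
        # independent brute-force oracle: explicit window comparison
        brute = set()
        for ps in spec.probe_sets:
            for pair in ps.pairs:
                hit = False
                for seq in (pair.pm.sequence, pair.mm.sequence):
                    for motif in ("GGGG", "CCTCC"):
                        for off in range(len(seq) - len(motif) + 1):
                            if seq[off:off + len(motif)] == motif:
                                hit = True
                if hit:
                    brute.add(pair_key(ps.name, pair))
        assert brute == flagged

    def test_adding_a_motif_never_shrinks_the_flagged_set(self, planted):
        spec, _ = planted
        just_grun = set(flag_motif_pairs(spec, MotifFilter(("GGGG",))))
        both = set(flag_motif_pairs(spec, MotifFilter(("GGGG", "CCTCC"))))
        assert just_grun <= both

    def test_missing_sequence_is_an_error(self, two_set_spec):
        with pytest.raises(ValueError, match="no sequence"):
            flag_motif_pairs(two_set_spec, MotifFilter())


class TestKeepList:
    def test_full_keep_list_removes_nothing(self, two_set_spec):
        kept = [(pr.pm.x, pr.pm.y) for ps in two_set_spec.probe_sets
                for pr in ps.pairs]
        assert pairs_from_keep_list(two_set_spec, kept) == []

    def test_empty_keep_list_removes_everything(self, two_set_spec):
        removed = pairs_from_keep_list(two_set_spec, [])
        assert set(removed) == spec_pair_keys(two_set_spec)

    def test_partial_keep_matches_brute_force_complement(self):
        spec = build_spec([("a_at", 10)], rows=4, cols=16)
        all_pm = [(pr.pm.x, pr.pm.y) for pr in spec.probe_sets[0].pairs]
        kept = all_pm[:7]
        removed = pairs_from_keep_list(spec, kept)
        expected = {PairKey("a_at", x, y) for (x, y) in all_pm[7:]}
        assert set(removed) == expected and len(removed) == 3

    def test_keep_list_file_parsing(self):
        text = "probe_set,x,y\na_at,1,2\nb_at,3,4\n"
        assert read_keep_list(io.StringIO(text)) == [(1, 2), (3, 4)]
        tabbed = text.replace(",", "\t")
        assert read_keep_list(io.StringIO(tabbed)) == [(1, 2), (3, 4)]


class TestApplyRemoval:
    def _sixteen(self):
        return build_spec([("std_at", 16)], rows=4, cols=16)

    def test_twelve_removed_retains_four_modified(self):
        spec = self._sixteen()
        remove = [pair_key("std_at", p)
                  for p in spec.probe_sets[0].pairs[:12]]
        custom, report = apply_removal(spec, remove)
        assert len(custom.probe_sets[0].pairs) == 4
        assert report.sets_modified == 1 and report.sets_removed == 0

    def test_thirteen_removed_drops_the_set(self):
        spec = self._sixteen()
        remove = [pair_key("std_at", p)
                  for p in spec.probe_sets[0].pairs[:13]]
        custom, report = apply_removal(spec, remove)
        assert custom.probe_sets == []
        assert report.removed_set_names == ["std_at"]

    def test_empty_removal_is_identity(self, two_set_spec):
        custom, report = apply_removal(two_set_spec, [])
        assert model_equal(custom, two_set_spec)
        assert report.sets_unmodified == 2
        assert report.sets_examined == 2

    def test_input_never_mutated(self, two_set_spec):
        before = copy_spec(two_set_spec)
        apply_removal(two_set_spec,
                      [pair_key("alpha_at", two_set_spec.probe_sets[0].pairs[0])])
        assert model_equal(two_set_spec, before)

    def test_unresolvable_key_rejected(self, two_set_spec):
        with pytest.raises(KeyError):
            apply_removal(two_set_spec, [PairKey("ghost_at", 9, 9)])

    def test_pair_conservation_including_whole_set_losses(self, planted):
        spec, truth = planted
        custom, report = apply_removal(spec, truth.flagged, 9)
        assert report.removed_set_names  # the floor actually bites here
        lost_to_pruning = sum(
            len(spec.probe_set(name).pairs)
            - sum(1 for k in truth.flagged if k.probe_set_name == name)
            for name in report.removed_set_names)
        assert custom.n_pairs + len(truth.flagged) + lost_to_pruning \
            == spec.n_pairs


class TestSetAlgebra:
    def _siblings(self):
        """One 12-pair set; a keeps pairs 1..10, b keeps 3..12 (1-based)."""
        default = build_spec([("s_at", 12)], rows=4, cols=16)
        keys = [pair_key("s_at", p) for p in default.probe_sets[0].pairs]
        a, _ = apply_removal(default, keys[10:], name="a")
        b, _ = apply_removal(default, keys[:2], name="b")
        return default, a, b, keys

    def test_intersection_union_difference_cardinalities(self):
        _, a, b, _ = self._siblings()
        assert set_algebra(a, b, "intersect").n_pairs == 8
        assert set_algebra(a, b, "union").n_pairs == 12
        assert set_algebra(a, b, "difference", 1).n_pairs == 2

    def test_membership_matches_python_set_ops(self):
        _, a, b, keys = self._siblings()
        ka, kb = set(keys[:10]), set(keys[2:])
        assert spec_pair_keys(set_algebra(a, b, "intersect")) == ka & kb
        assert spec_pair_keys(set_algebra(a, b, "union")) == ka | kb
        assert spec_pair_keys(set_algebra(a, b, "difference", 1)) == ka - kb

    def test_small_overlap_pruned_by_floor(self):
        default = build_spec([("s_at", 12)], rows=4, cols=16)
        keys = [pair_key("s_at", p) for p in default.probe_sets[0].pairs]
        a, _ = apply_removal(default, keys[7:], name="a")   # keeps 0..6
        b, _ = apply_removal(default, keys[:4], name="b")   # keeps 4..11
        joint = set_algebra(a, b, "intersect", 4)  # overlap 4..6 = 3 pairs
        assert joint.probe_sets == []

    def test_grid_mismatch_rejected(self):
        a = build_spec([("s_at", 4)], rows=4, cols=8)
        b = build_spec([("s_at", 4)], rows=8, cols=8)
        with pytest.raises(ValueError, match="grid"):
            set_algebra(a, b, "intersect")

    def test_intersect_equals_sequential_removal_of_union(self, planted):
        """Building the joint spec by intersection must equal removing the
        union of both filters' pairs from the default."""
        spec, truth = planted
        a, _ = apply_removal(spec, truth.grun, name="a")
        b, _ = apply_removal(spec, truth.spacer, name="b")
        joint = set_algebra(a, b, "intersect", 4)
        seq, _ = apply_removal(spec, truth.grun | truth.spacer, 4)
        assert spec_pair_keys(joint) == spec_pair_keys(seq)
        assert joint.set_names() == seq.set_names()


class TestDiffSpecs:
    def test_toy_three_set_classification(self):
        default = build_spec([("A", 16), ("B", 16), ("C", 16)],
                             rows=8, cols=16)
        remove = [pair_key("B", p) for p in default.probe_set("B").pairs[:2]]
        remove += [pair_key("C", p) for p in default.probe_set("C").pairs]
        custom, _ = apply_removal(default, remove)
        diff = diff_specs(default, custom)
        assert diff.removed_sets == ["C"]
        assert diff.modified_sets == ["B"]
        assert diff.unmodified_sets == ["A"]
        assert diff.pairs_removed_histogram == {0: 1, 2: 1}

    def test_identity_diff(self, two_set_spec):
        diff = diff_specs(two_set_spec, copy_spec(two_set_spec))
        assert diff.n_removed == diff.n_modified == 0
        assert diff.n_unmodified == 2
        assert diff.pairs_removed_histogram == {0: 2}

    def test_classification_partitions_default_sets(self, planted):
        spec, truth = planted
        custom, _ = apply_removal(spec, truth.flagged, 8)
        diff = diff_specs(spec, custom)
        assert (diff.n_removed + diff.n_modified + diff.n_unmodified
                == len(spec.probe_sets))
        assert sum(diff.pairs_removed_histogram.values()) \
            == len(spec.probe_sets) - diff.n_removed

    def test_standard_size_restriction(self):
        default = build_spec([("A", 16), ("B", 8)], rows=8, cols=16)
        diff = diff_specs(default, copy_spec(default), standard_size=16)
        assert diff.n_unmodified == 1 and diff.n_removed == 0

    def test_added_sets_counted_not_fatal(self, two_set_spec):
        custom = copy_spec(two_set_spec)
        custom.probe_sets[1].name = "novel_at"
        diff = diff_specs(two_set_spec, custom)
        assert diff.removed_sets == ["beta_at"]
        assert diff.added_sets == ["novel_at"]


class TestOverlap:
    def test_finite_partition(self):
        a = {PairKey("s", i, 0) for i in range(1, 11)}
        b = {PairKey("s", i, 0) for i in range(8, 13)}
        venn = overlap_counts(a, b)
        assert (venn.only_a, venn.both, venn.only_b) == (7, 3, 2)
        assert venn.total == len(a | b)

    def test_identical_and_disjoint(self):
        a = {PairKey("s", i, 0) for i in range(5)}
        assert overlap_counts(a, a) == (0, 0, 5)
        b = {PairKey("t", i, 0) for i in range(3)}
        venn = overlap_counts(a, b)
        assert venn.both == 0 and venn.total == len(a) + len(b)

    def test_set_granularity_via_affected_names(self, planted):
        spec, truth = planted
        names_a = affected_set_names(truth.grun)
        names_b = affected_set_names(truth.spacer)
        venn = overlap_counts(names_a, names_b)
        assert venn.total == len(names_a | names_b)

    def test_removed_pair_keys_matches_diff(self, planted):
        spec, truth = planted
        custom, _ = apply_removal(spec, truth.flagged)
        removed = removed_pair_keys(spec, custom)
        assert removed == set(truth.flagged)  # no set fell below the floor
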