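"""Pedigree reading, ordering, classification and pruning."""

import numpy as np
import pytest

from ssram import (
    Pedigree,
    PedigreeError,
    a_inverse,
    classify_animals,
    prune_partition,
    prune_pedigree,
    read_pedigree,
)
from conftest import sim_dataset


class TestConstruction:
    def test_single_founder(self):
        ped = Pedigree.from_records([(1, 0, 0)])
        assert ped.n == 1 and ped.labels == (1,)

    def test_progeny_before_parent_is_reordered(self):
        ped = Pedigree.from_records([(3, 2, 1), (1, 0, 0), (2, 0, 0)])
        i3 = ped.code[3]
        assert i3 > ped.code[1] and i3 > ped.code[2]

    def test_cycle_is_a_hard_error_naming_the_cycle(self):
        with pytest.raises(PedigreeError, match="cycle"):
            Pedigree.from_records([(1, 2, 0), (2, 1, 0)])

    def test_unlisted_parent_rejected_unless_opted_in(self):
        with pytest.raises(PedigreeError, match="no animal record"):
            Pedigree.from_records([(2, 1, 0)])
        ped = Pedigree.from_records([(2, 1, 0)], add_missing_parents=True)
        assert set(ped.labels) == {1, 2}
        assert ped.parents_of(1) == (None, None)

    def test_na_tokens_mean_unknown_parent(self):
        ped = Pedigree.from_records([(1, "NA", ""), (2, "0", None)])
        assert ped.founders() == {1, 2}

    def test_duplicate_animals_rejected(self):
        with pytest.raises(PedigreeError, match="duplicate"):
            Pedigree.from_records([(1, 0, 0), (1, 0, 0)])

    def test_example_pedigree_shape(self, example):
        ped = example.ped
        assert ped.n == 12
        assert ped.founders() == {1, 2, 3}
        # non-founder animals with exactly one known parent: 4, 5, 6, 7, 8
        one_parent = {
            a for a in ped.labels
            if sum(p is not None for p in ped.parents_of(a)) == 1
        }
        assert one_parent == {4, 5, 6, 7, 8}


class TestReader:
    def test_reads_with_and_without_header_and_reordering_is_immaterial(self, tmp_path):
        rows = "4,2,1\n1,0,0\n2,0,0\n3,2,1\n"
        f1 = tmp_path / "noheader.csv"
        f1.write_text(rows)
        f2 = tmp_path / "header.csv"
        f2.write_text("animal,sire,dam\n" + rows)
        p1, p2 = read_pedigree(f1), read_pedigree(f2)
        assert p1.labels == p2.labels
        ainv1 = a_inverse(p1).to_dense()
        shuffled = tmp_path / "shuffled.csv"
        shuffled.write_text("3,2,1\n2,0,0\n4,2,1\n1,0,0\n")
        p3 = read_pedigree(shuffled)
        # label-keyed determinism: downstream matrices identical
        np.testing.assert_allclose(
            a_inverse(p3).reordered(p1.labels).to_dense(), ainv1, atol=1e-14
        )


class TestClassification:
    def test_example_sets_match_known_reduction_sets(self, example):
        s = classify_animals(
            example.ped, example.genotyped, set(example.records["animal"])
        )
        assert s.method1_p == frozenset({1, 2, 3, 4, 5, 6, 7, 10})
        assert s.method1_n == frozenset({8, 9, 11, 12})
        assert s.method2_p == frozenset({4, 5, 9, 10, 11, 12})
        assert s.method2_n == frozenset({1, 2, 3, 6, 7, 8})
        assert s.method3_q == frozenset({4, 5, 6, 7, 10})
        assert s.method3_r == frozenset({1, 2, 3})
        assert s.method3_n == frozenset({8, 9, 11, 12})

    def test_all_genotyped_degenerate(self, example):
        s = classify_animals(example.ped, example.ped.labels, {4})
        assert s.method1_p == frozenset(example.ped.labels)
        assert not s.method1_n and not s.method2_n

    @pytest.mark.parametrize("seed", range(6))
    def test_partition_invariants_on_random_pedigrees(self, seed):
        d = sim_dataset(seed, missing_sire_prob=0.2, missing_dam_prob=0.15)
        all_animals = frozenset(d.ped.labels)
        s = classify_animals(d.ped, d.genotyped, set(d.records["animal"]))
        # each method's sets partition the pedigree
        assert s.method1_p | s.method1_n == all_animals
        assert not s.method1_p & s.method1_n
        assert s.method2_p | s.method2_n == all_animals
        assert s.method3_q | s.method3_r | s.method3_n == all_animals
        assert not s.method3_q & s.method3_r
        assert s.method3_q | s.method3_r == s.method1_p
        assert not s.method3_r & (s.genotyped | s.phenotyped)
        # every known parent of a phenotyped absorbed nonparent is kept
        for a in s.method1_n & s.phenotyped:
            for par in d.ped.parents_of(a):
                assert par is None or par in s.method1_p
        for a in s.method3_n & s.phenotyped:
            for par in d.ped.parents_of(a):
                assert par is None or par in s.method3_q


class TestPruning:
    def test_example_animal_3_is_the_removal_candidate(self, example, expected):
        part = prune_partition(example.ped, example.genotyped)
        assert tuple(a for a, c in sorted(part.items()) if c == 0) == expected["prune_class0"]
        assert part[5] == part[10] == 2

    def test_all_genotyped_means_nothing_to_prune(self, example):
        part = prune_partition(example.ped, example.ped.labels)
        assert set(part.values()) == {2}

    def test_parent_of_genotyped_is_class_3(self):
        ped = Pedigree.from_records([("f", 0, 0), ("g", "f", 0)])
        part = prune_partition(ped, {"g"})
        assert part["f"] == 3

    def test_prune_removes_class0_and_blanks_their_references(self, example):
        part = prune_partition(example.ped, example.genotyped)
        pruned, removed = prune_pedigree(example.ped, part)
        assert removed == [3]
        assert pruned.n == 11
        assert pruned.parents_of(7) == (None, None)  # dam 3 removed

    def test_prune_refuses_without_genotyped_anchor(self, example):
        part = {a: 0 for a in example.ped.labels}
        with pytest.raises(PedigreeError, match="anchor"):
            prune_pedigree(example.ped, part)

    def test_empty_class0_leaves_pedigree_unchanged(self, example):
        part = {a: 2 for a in example.ped.labels}
        pruned, removed = prune_pedigree(example.ped, part)
        assert removed == [] and pruned is example.ped


class TestPropertyBased:
    """Structural invariants on arbitrary valid pedigrees."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    def _build(parent_picks):
        # animal i may pick parents only among animals 1..i-1 (or unknown)
        rows = []
        for i, (s_pick, d_pick) in enumerate(parent_picks, start=1):
            s = s_pick % i if s_pick is not None else 0
            d = d_pick % i if d_pick is not None else 0
            if s == d:
                d = 0
            rows.append((i, s, d))
        return Pedigree.from_records(rows)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(st.one_of(st.none(), st.integers(0, 50)),
                      st.one_of(st.none(), st.integers(0, 50))),
            min_size=1, max_size=25,
        ),
        st.data(),
    )
    def test_classification_partitions_any_pedigree(self, picks, data):
        ped = self._build(picks)
        labels = list(ped.labels)
        geno = set(data.draw(self.st.lists(self.st.sampled_from(labels),
                                           max_size=len(labels))))
        pheno = set(data.draw(self.st.lists(self.st.sampled_from(labels),
                                            max_size=len(labels))))
        s = classify_animals(ped, geno, pheno)
        allset = frozenset(labels)
        assert s.method1_p | s.method1_n == allset
        assert not s.method1_p & s.method1_n
        assert s.method2_p | s.method2_n == allset
        assert s.method3_q | s.method3_r == s.method1_p
        assert not s.method3_r & (s.genotyped | s.phenotyped)
        for a in s.method1_n & s.phenotyped:
            for par in ped.parents_of(a):
                assert par is None or par in s.method1_p
        for a in s.method3_n & s.phenotyped:
            for par in ped.parents_of(a):
                assert par is None or par in s.method3_q
        part = prune_partition(ped, geno)
        assert set(part) == set(labels)
        assert all(part[g] == 2 for g in geno)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(st.one_of(st.none(), st.integers(0, 50)),
                      st.one_of(st.none(), st.integers(0, 50))),
            min_size=1, max_size=20,
        )
    )
    def test_topological_order_and_a_inverse_oracle(self, picks):
        ped = self._build(picks)
        for lab in ped.labels:
            for par in ped.parents_of(lab):
                if par is not None:
                    assert ped.code[par] < ped.code[lab]
        from ssram import tabular_a
        prod = a_inverse(ped).to_dense() @ tabular_a(ped).to_dense()
        np.testing.assert_allclose(prod, np.eye(ped.n), atol=1e-9)
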