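"""Peptide-set algebra, annotation rollups and 16S taxon matching."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from epitopescan import (
    match_taxa,
    merge_samples,
    phylum_composition,
    source_summary,
    subtract_control,
    unique_per_sample,
)
from epitopescan.errors import ValidationError


def table(rows, columns=("sequence", "sample_id")):
    return pd.DataFrame(rows, columns=list(columns))


class TestUniquePerSample:
    def test_dedup_within_sample(self):
        res = unique_per_sample(table([("AAA", "s1"), ("AAA", "s1"), ("BBB", "s1")]))
        assert res["counts"] == {"s1": 2}

    def test_shared_sequences_counted_per_sample(self):
        res = unique_per_sample(
            table([("AAA", "s1"), ("BBB", "s1"), ("AAA", "s2"), ("BBB", "s2")])
        )
        assert res["counts"] == {"s1": 2, "s2": 2}
        assert res["sets"]["s1"] == res["sets"]["s2"]

    def test_empty_table_is_empty_result(self):
        res = unique_per_sample(pd.DataFrame(columns=["sequence", "sample_id"]))
        assert res["counts"] == {} and res["min"] is None


class TestSubtractControl:
    def test_disjoint_removes_nothing(self):
        filtered, removed = subtract_control({"A", "B"}, {"C"})
        assert filtered == {"A", "B"} and removed == 0

    def test_superset_control_empties_case(self):
        filtered, removed = subtract_control({"A", "B"}, {"A", "B", "C"})
        assert filtered == set() and removed == 2

    def test_removed_sequences_stay_removed_after_remerge(self):
        a, b = {"A", "B", "C"}, {"B", "D"}
        filtered, _ = subtract_control(a, b)
        remerged = merge_samples([filtered, b - a]).union
        assert "B" not in remerged


class TestMerge:
    def test_published_union_arithmetic(self):
        # 18 + 23 with 4 shared -> 37
        primary = {f"p{i}" for i in range(18)}
        recurrent = {f"p{i}" for i in range(4)} | {f"r{i}" for i in range(19)}
        res = merge_samples([primary, recurrent])
        assert res.union_size == 37
        assert len(res.pairwise_intersections[(0, 1)]) == 4

    def test_disjoint_and_identical(self):
        assert merge_samples([{"A"}, {"B"}]).union_size == 2
        assert merge_samples([{"A", "B"}, {"A", "B"}]).union == {"A", "B"}

    @given(
        sets=st.lists(
            st.sets(st.sampled_from([f"P{i}" for i in range(12)]), max_size=8),
            min_size=1,
            max_size=4,
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_inclusion_exclusion_and_idempotence(self, sets):
        res = merge_samples(sets)
        assert res.union == set().union(*sets)
        again = merge_samples([res.union])
        assert again.union == res.union  # idempotent
        for (i, j), inter in res.pairwise_intersections.items():
            assert len(sets[i] | sets[j]) == len(sets[i]) + len(sets[j]) - len(inter)


class TestSourceSummary:
    def test_hand_counts(self):
        df = table(
            [
                ("AAA", "s1", "P1", "Org1"),
                ("BBB", "s1", "P2", "Org1"),
                ("CCC", "s1", "P1", "Org1"),
            ],
            columns=("sequence", "sample_id", "source_protein", "organism"),
        )
        s = source_summary(df)
        assert (s.n_proteins, s.n_organisms) == (2, 1)

    def test_duplicated_rows_do_not_change_counts(self):
        df = table(
            [("AAA", "s1", "P1", "Org1")] * 3,
            columns=("sequence", "sample_id", "source_protein", "organism"),
        )
        s = source_summary(df)
        assert (s.n_proteins, s.n_organisms) == (1, 1)


class TestPhylumComposition:
    def test_single_phylum(self):
        df = table(
            [("AAA", "s", "Firmicutes"), ("BBB", "s", "Firmicutes")],
            columns=("sequence", "sample_id", "phylum"),
        )
        comp = phylum_composition(df)
        assert comp.loc[comp.phylum == "Firmicutes", "fraction"].item() == 1.0

    def test_sixty_forty_split(self):
        rows = [(f"P{i}", "s", "Proteobacteria") for i in range(6)]
        rows += [(f"F{i}", "s", "Firmicutes") for i in range(4)]
        comp = phylum_composition(table(rows, columns=("sequence", "sample_id", "phylum")))
        frac = dict(zip(comp.phylum, comp.fraction))
        assert frac["Proteobacteria"] == pytest.approx(0.6)
        assert frac["Firmicutes"] == pytest.approx(0.4)
        assert comp.fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_missing_lineage_goes_to_unassigned(self):
        df = table([("AAA", "s", None)], columns=("sequence", "sample_id", "phylum"))
        comp = phylum_composition(df)
        assert comp.phylum.tolist() == ["unassigned"]
        assert comp.fraction.item() == 1.0


class TestMatchTaxa:
    taxa = pd.DataFrame(
        [
            ("s1", "species", "Bacillus subtilis"),
            ("s1", "genus", "Bacillus"),
        ],
        columns=["sample_id", "rank", "name"],
    )

    def test_species_level_exact_match(self):
        matches, tally = match_taxa({"s1": ["Bacillus subtilis"]}, self.taxa, rank="species")
        assert matches["s1"].matched and tally == 1

    def test_genus_from_first_token(self):
        matches, tally = match_taxa({"s1": ["Bacillus anthracis"]}, self.taxa, rank="genus")
        assert matches["s1"].matched and tally == 1

    def test_case_insensitive(self):
        _, tally = match_taxa({"s1": ["bacillus SUBTILIS"]}, self.taxa, rank="species")
        assert tally == 1

    def test_no_match_and_unknown_rank(self):
        matches, tally = match_taxa({"s1": ["Escherichia coli"]}, self.taxa, rank="species")
        assert not matches["s1"].matched and tally == 0
        with pytest.raises(ValidationError):
            match_taxa({}, self.taxa, rank="family")

    def test_lineage_override_beats_token_parsing(self):
        lineage = {"Weird label 42": {"genus": "Bacillus"}}
        _, tally = match_taxa({"s1": ["Weird label 42"]}, self.taxa, rank="genus", lineage=lineage)
        assert tally == 1
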