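import numpy as np
import pandas as pd
import pytest

from itsdiv.errors import ParameterError, ValidationError
from itsdiv.partitions import (
    Partition,
    cluster_otus,
    collapse_haplotypes,
    country_haplotype_table,
)

from conftest import aln_from, two_haplotype_alignment


def make_samples(aln, countries, populations=None):
    populations = populations or ["P1"] * len(aln)
    return pd.DataFrame(
        {
            "population": populations,
            "country": countries,
            "substrate": ["leaves"] * len(aln),
            "date": [""] * len(aln),
        },
        index=pd.Index(aln.ids, name="isolate_id"),
    )


class TestPartitionInvariants:
    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValidationError):
            Partition("user", {"A": ("x", "y"), "B": ("y",)})

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            Partition("user", {"A": ()})


class TestClusterOtus:
    def test_identical_sequences_single_otu(self):
        aln = aln_from(["ACGT" * 10] * 5)
        part = cluster_otus(aln, 100.0)
        assert list(part.groups) == ["OTU-1"]
        assert len(part.groups["OTU-1"]) == 5

    def test_two_divergent_groups_split_at_99(self):
        # 10 / 460 columns differ -> similarity ~97.8 < 99
        aln = two_haplotype_alignment((3, 3), n_ts=5, n_tv=5, length=460)
        part = cluster_otus(aln, 99.0)
        assert len(part.groups) == 2

    def test_preset_recovers_truth_partition(self, table1):
        aln, _, truth, _ = table1
        part = cluster_otus(aln, 98.0)
        computed = {frozenset(m) for m in part.groups.values()}
        expected = {frozenset(m) for m in truth["partition"].groups.values()}
        assert computed == expected

    def test_labels_by_decreasing_size(self, table1):
        aln, _, _, _ = table1
        part = cluster_otus(aln, 98.0)
        sizes = [len(m) for m in part.groups.values()]
        assert sizes == sorted(sizes, reverse=True)
        assert list(part.groups)[0] == "OTU-1"

    def test_cluster_count_monotone_in_threshold(self, table1):
        aln, _, _, _ = table1
        counts = [len(cluster_otus(aln, t).groups)
                  for t in (100.0, 99.5, 99.0, 98.5, 98.0, 95.0, 90.0)]
        assert counts == sorted(counts, reverse=True)

    def test_single_linkage_chains_through_intermediate(self):
        # A-B similar, B-C similar, A-C not: single linkage joins all three
        a = "A" * 100
        b = "A" * 97 + "C" * 3
        c = "A" * 94 + "C" * 6
        aln = aln_from([a, b, c])
        single = cluster_otus(aln, 97.0, method="single")
        complete = cluster_otus(aln, 97.0, method="complete")
        assert len(single.groups) == 1
        assert len(complete.groups) == 2

    def test_threshold_validation(self):
        aln = aln_from(["ACGT", "ACGT"])
        with pytest.raises(ParameterError):
            cluster_otus(aln, 0.0)


class TestCollapseHaplotypes:
    def test_indel_only_variation_one_haplotype(self):
        aln = two_haplotype_alignment((4, 4), n_indel=1, length=40)
        part = collapse_haplotypes(aln)
        assert len(part.groups) == 1
        assert len(part.groups["H1"]) == 8

    def test_substitution_variants_split_with_frequencies(self):
        aln = two_haplotype_alignment((6, 2), n_ts=2, n_tv=5, n_indel=1, length=40)
        part = collapse_haplotypes(aln)
        assert [len(m) for m in part.groups.values()] == [6, 2]

    def test_single_sequence(self):
        part = collapse_haplotypes(aln_from(["ACGT"]))
        assert len(part.groups) == 1

    def test_idempotent_and_order_invariant(self):
        aln = two_haplotype_alignment((3, 2), n_tv=3, length=30)
        base = {frozenset(m) for m in collapse_haplotypes(aln).groups.values()}
        rev = aln.subset(aln.ids[::-1])
        again = {frozenset(m) for m in collapse_haplotypes(rev).groups.values()}
        assert base == again

    def test_refines_otu_partition(self, table1):
        aln, _, _, _ = table1
        otus = cluster_otus(aln, 98.0)
        haps = collapse_haplotypes(aln)
        otu_of = otus.labels
        for members in haps.groups.values():
            assert len({otu_of[m] for m in members}) == 1

    def test_equals_otus_at_100_on_gap_free_data(self):
        aln = two_haplotype_alignment((3, 3), n_ts=2, n_tv=2, length=60)
        otus = {frozenset(m) for m in cluster_otus(aln, 100.0).groups.values()}
        haps = {frozenset(m) for m in collapse_haplotypes(aln).groups.values()}
        assert otus == haps


class TestCountryHaplotypeTable:
    def test_three_of_four_share_a_haplotype(self):
        aln = two_haplotype_alignment((3, 1), n_tv=2, length=40)
        samples = make_samples(aln, ["Malaysia"] * 4)
        table, _ = country_haplotype_table(aln, samples, seed=0)
        m = table[table["country"] == "Malaysia"].sort_values("count", ascending=False)
        assert m["count"].tolist() == [3, 1]
        assert m["rel_freq"].tolist() == [0.75, 0.25]

    def test_small_countries_excluded(self):
        aln = two_haplotype_alignment((4, 3), n_tv=2, length=40)
        samples = make_samples(aln, ["Portugal"] * 4 + ["Spain"] * 3)
        table, _ = country_haplotype_table(aln, samples, seed=0)
        assert set(table["country"]) == {"Portugal"}

    def test_shared_haplotype_across_countries(self):
        aln = two_haplotype_alignment((5, 3), n_tv=2, length=40)
        countries = ["Portugal"] * 4 + ["Spain"] + ["Spain"] * 3
        samples = make_samples(aln, countries)
        table, _ = country_haplotype_table(aln, samples, seed=1)
        h1 = table[(table["haplotype"] == "H1") & (table["count"] > 0)]
        assert set(h1["country"]) == {"Portugal", "Spain"}

    def test_subsampling_is_seeded(self):
        aln = two_haplotype_alignment((6, 2), n_tv=2, length=40)
        samples = make_samples(aln, ["Portugal"] * 8)
        t1, _ = country_haplotype_table(aln, samples, seed=5)
        t2, _ = country_haplotype_table(aln, samples, seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_min_isolates_validation(self):
        aln = two_haplotype_alignment((2, 2), n_tv=2, length=40)
        samples = make_samples(aln, ["Portugal"] * 4)
        with pytest.raises(ParameterError):
            country_haplotype_table(aln, samples, min_isolates=1)
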