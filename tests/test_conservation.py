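"""Conserved-editing detection, recoding classification, and the control census."""

from collections import Counter

import pytest

from editrecode.alignment import align_genes
from editrecode.conservation import (
    PairClass,
    census_control_codons,
    classify_pair,
    classify_pairs,
    find_conserved_editing,
)
from editrecode.datamodel import EditingSite, Gene, SpeciesDataset


def _pair_datasets(cds_a, cds_b, sites_a, sites_b):
    """Two single-gene species with the given CDSs and edited positions."""
    ds_a = SpeciesDataset("A")
    ds_a.add_gene(Gene("g", "A", cds_a))
    ds_b = SpeciesDataset("B")
    ds_b.add_gene(Gene("g", "B", cds_b))
    for p in sites_a:
        ds_a.add_site(EditingSite("g", p))
    for p in sites_b:
        ds_b.add_site(EditingSite("g", p))
    aln = {"g": ("g", align_genes(ds_a.genes["g"], ds_b.genes["g"]))}
    return ds_a, ds_b, aln


class TestFindConservedEditing:
    def test_site_edited_in_both_species_pairs_up(self):
        # codon 1 is ACT in both; edited at its first position (cds_pos 3)
        ds_a, ds_b, aln = _pair_datasets(
            "TTGACTTAA", "TTGACTTAA", sites_a=[3], sites_b=[3])
        pairs, discards = find_conserved_editing(ds_a, ds_b, aln)
        assert len(pairs) == 1 and not discards
        p = pairs[0]
        assert (p.codon_a, p.codon_b, p.codon_pos) == ("ACT", "ACT", 0)

    def test_site_edited_only_in_a_is_tallied(self):
        ds_a, ds_b, aln = _pair_datasets(
            "TTGACTTAA", "TTGACTTAA", sites_a=[3], sites_b=[])
        pairs, discards = find_conserved_editing(ds_a, ds_b, aln)
        assert pairs == [] and discards["not_edited_in_b"] == 1

    def test_substitution_on_the_site_abolishes_pairing(self):
        # orthologous base is G in B: editing potential lost
        ds_a, ds_b, aln = _pair_datasets(
            "TTGACTTAA", "TTGGCTTAA", sites_a=[3], sites_b=[])
        pairs, discards = find_conserved_editing(ds_a, ds_b, aln)
        assert pairs == [] and discards["a_not_conserved"] == 1

    def test_unaligned_gene_is_tallied(self):
        ds_a, ds_b, _ = _pair_datasets("TTGACTTAA", "TTGACTTAA", [3], [3])
        pairs, discards = find_conserved_editing(ds_a, ds_b, {})
        assert pairs == [] and discards["gene_unaligned"] == 1


class TestClassifyPair:
    def _classify(self, cds_a, cds_b, pos):
        ds_a, ds_b, aln = _pair_datasets(cds_a, cds_b, [pos], [pos])
        (pair,), _ = find_conserved_editing(ds_a, ds_b, aln)
        return classify_pair(pair)

    def test_same_codon_same_recoding(self):
        assert self._classify("TTGACTTAA", "TTGACTTAA", 3) is PairClass.CONSERVED_RECODING

    def test_same_recoding_type_through_different_codons(self):
        # ACT (T>A) vs ACC (T>A): labels equal although codons differ
        assert self._classify("TTGACTTAA", "TTGACCTAA", 3) is PairClass.CONSERVED_RECODING

    def test_codon_change_next_to_site_gives_non_conserved_recoding(self):
        # ACT Thr>Ala in one species, ATT Ile>Val in the other
        assert (self._classify("TTGACTTAA", "TTGATTTAA", 3)
                is PairClass.NON_CONSERVED_RECODING)

    def test_synonymous_side_is_not_nonsynonymous_in_both(self):
        # CGA edited at third position is Arg>Arg
        assert (self._classify("TTGCGATAA", "TTGCGATAA", 5)
                is PairClass.NOT_NONSYNONYMOUS_IN_BOTH)

    def test_every_pair_gets_exactly_one_class(self, small_pair):
        from editrecode.analysis import PairwiseRecodingAnalysis

        ds_a, ds_b, _ = small_pair
        res = PairwiseRecodingAnalysis(ds_a, ds_b).fit()
        assert sum(res.class_counts.values()) == len(res.classified)
        assert set(res.class_counts) <= {c.value for c in PairClass}


class TestControlCensus:
    def test_identical_nonsyn_codons_count_in_total_only(self):
        ds_a, ds_b, aln = _pair_datasets("TTGACTTAA", "TTGACTTAA", [], [])
        c = census_control_codons(ds_a, ds_b, aln, edited_gene_ids={"g"})
        # codon ACT has one conserved unedited A, nonsynonymous if edited
        assert (c.n_total, c.n_diff_aa) == (1, 0)

    def test_different_amino_acids_count_in_both(self):
        ds_a, ds_b, aln = _pair_datasets("TTGACTTAA", "TTGATTTAA", [], [])
        c = census_control_codons(ds_a, ds_b, aln, edited_gene_ids={"g"})
        assert (c.n_total, c.n_diff_aa) == (1, 1)

    def test_synonymous_adenosines_count_in_neither(self):
        ds_a, ds_b, aln = _pair_datasets("TTGCGATAA", "TTGCGATAA", [], [])
        c = census_control_codons(ds_a, ds_b, aln, edited_gene_ids={"g"})
        assert (c.n_total, c.n_diff_aa) == (0, 0)

    def test_edited_adenosines_are_excluded(self):
        ds_a, ds_b, aln = _pair_datasets("TTGACTTAA", "TTGACTTAA", [3], [3])
        c = census_control_codons(ds_a, ds_b, aln, edited_gene_ids={"g"})
        assert c.n_total == 0

    def test_ratio_invariant_to_species_swap(self, small_pair):
        ds_a, ds_b, _ = small_pair
        fwd = {g: ("g", align_genes(ds_a.genes[g], ds_b.genes[g]))
               for g in sorted(ds_a.edited_gene_ids())}
        fwd = {g: (g, a[1]) for g, a in fwd.items()}
        rev = {g: (g, align_genes(ds_b.genes[g], ds_a.genes[g]))
               for g in sorted(ds_a.edited_gene_ids())}
        c1 = census_control_codons(ds_a, ds_b, fwd,
                                   edited_gene_ids=ds_a.edited_gene_ids())
        c2 = census_control_codons(ds_b, ds_a, rev,
                                   edited_gene_ids=ds_a.edited_gene_ids())
        assert c1.n_total == c2.n_total and c1.n_diff_aa == c2.n_diff_aa

    def test_per_codon_mode_counts_codons_once(self):
        # AAT: two adenosines, both nonsynonymous if edited (N>D, N>S)
        ds_a, ds_b, aln = _pair_datasets("TTGAATTAA", "TTGAATTAA", [], [])
        per_site = census_control_codons(ds_a, ds_b, aln, edited_gene_ids={"g"})
        per_codon = census_control_codons(ds_a, ds_b, aln, edited_gene_ids={"g"},
                                          per_codon=True)
        assert per_site.n_total == 2 and per_codon.n_total == 1


def test_noiseless_pair_classification_recovers_truth(noiseless_pair):
    """With zero divergence noise, class counts equal the planted truth."""
    from editrecode.analysis import PairwiseRecodingAnalysis

    ds_a, ds_b, truth = noiseless_pair
    res = PairwiseRecodingAnalysis(ds_a, ds_b).fit()
    planted = truth.category_counts()
    assert res.class_counts.get("conserved_recoding", 0) == planted["conserved_recoding"]
    assert (res.class_counts.get("non_conserved_recoding", 0)
            == planted["non_conserved_recoding"])
    assert res.discards["not_edited_in_b"] == planted["species_specific"]
    assert res.discards["a_not_conserved"] == planted["A_lost"]
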