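"""SNP consequence annotation vs an exhaustive oracle, and codon censuses."""

import itertools

import pytest
from Bio.Data import CodonTable

from editrecode.alignment import align_genes
from editrecode.conservation import classify_pairs, find_conserved_editing
from editrecode.datamodel import EditingSite, Gene, Snp, SpeciesDataset
from editrecode.snp_codon import (
    annotate_snp,
    census_control_codons_with_ns_snp,
    census_recoding_codons_with_ns_snp,
)

_FWD = dict(CodonTable.unambiguous_dna_by_id[1].forward_table)
for _s in CodonTable.unambiguous_dna_by_id[1].stop_codons:
    _FWD[_s] = "*"


def _oracle_class(codon, pos, alt):
    post = codon[:pos] + alt + codon[pos + 1 :]
    pre_aa, post_aa = _FWD[codon], _FWD[post]
    if pre_aa == "*" and post_aa == "*":
        return "stop_retained"
    if pre_aa == "*":
        return "stop_loss"
    if post_aa == "*":
        return "stop_gain"
    return "synonymous" if pre_aa == post_aa else "nonsynonymous"


def test_annotate_snp_matches_exhaustive_oracle():
    """All 576 (codon, position, alternate) combinations classify exactly as
    the standard genetic code dictates."""
    combos = [
        (c, p, a)
        for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
        for p in range(3)
        for a in "ACGT"
        if a != c[p]
    ]
    assert len(combos) == 576
    checked = 0
    for codon, pos, alt in combos:
        # embed the codon in a valid CDS: ATG <codon> TAA, skipping cases
        # where the embedded codon is itself a stop (tested via terminal flag)
        if _FWD[codon] == "*":
            continue
        gene = Gene("g", "sp", "ATG" + codon + "TAA")
        snp = Snp("g", 3 + pos, codon[pos], alt)
        ann = annotate_snp(snp, gene)
        assert ann.consequence.value == _oracle_class(codon, pos, alt)
        assert ann.pre_codon == codon
        assert ann.post_codon == codon[:pos] + alt + codon[pos + 1 :]
        assert not ann.in_terminal_stop
        checked += 1
    assert checked == 549  # 576 minus the 27 stop-codon embeddings


@pytest.mark.parametrize(
    "codon,pos,alt,expected",
    [
        ("AGT", 1, "C", "nonsynonymous"),  # AGT Ser -> ACT Thr
        ("AAA", 2, "G", "synonymous"),     # AAA Lys -> AAG Lys
        ("CGA", 0, "T", "stop_gain"),      # CGA Arg -> TGA stop
    ],
)
def test_known_snp_examples(codon, pos, alt, expected):
    gene = Gene("g", "sp", "ATG" + codon + "TAA")
    ann = annotate_snp(Snp("g", 3 + pos, codon[pos], alt), gene)
    assert ann.consequence.value == expected


def test_terminal_stop_snp_is_flagged():
    gene = Gene("g", "sp", "ATGAAATAA")
    ann = annotate_snp(Snp("g", 8, "A", "G"), gene)
    assert ann.in_terminal_stop


def _scenario(snp_list):
    """One gene, one conserved-recoding site at cds_pos 3 (codon ACT)."""
    ds_a = SpeciesDataset("A")
    ds_a.add_gene(Gene("g", "A", "TTGACTAAATAA"))
    ds_b = SpeciesDataset("B")
    ds_b.add_gene(Gene("g", "B", "TTGACTAAATAA"))
    ds_a.add_site(EditingSite("g", 3))
    ds_b.add_site(EditingSite("g", 3))
    for snp in snp_list:
        ds_a.add_snp(snp)
    aln = {"g": ("g", align_genes(ds_a.genes["g"], ds_b.genes["g"]))}
    pairs, _ = find_conserved_editing(ds_a, ds_b, aln)
    classified, _ = classify_pairs(pairs)
    return ds_a, ds_b, aln, classified


class TestRecodingCodonCensus:
    def test_nonsyn_snp_at_other_codon_position_counts_once(self):
        # two qualifying SNPs in the same codon still count the codon once
        snps = [Snp("g", 4, "C", "T"), Snp("g", 4, "C", "G")]  # ACT->ATT, ACT->AGT
        _, _, _, classified = _scenario(snps)
        ds_a = _scenario(snps)[0]
        c = census_recoding_codons_with_ns_snp(classified, ds_a)
        assert (c.k, c.n) == (1, 1)

    def test_snp_on_the_edited_adenosine_does_not_count(self):
        ds_a, _, _, classified = _scenario([Snp("g", 3, "A", "G")])
        c = census_recoding_codons_with_ns_snp(classified, ds_a)
        assert (c.k, c.n) == (0, 1)
        c_incl = census_recoding_codons_with_ns_snp(
            classified, ds_a, include_edited_position=True)
        assert (c_incl.k, c_incl.n) == (1, 1)

    def test_no_snps_gives_zero_k(self):
        ds_a, _, _, classified = _scenario([])
        c = census_recoding_codons_with_ns_snp(classified, ds_a)
        assert (c.k, c.n) == (0, 1)

    def test_counting_is_idempotent_under_duplicate_rows(self):
        snp = Snp("g", 4, "C", "T")
        ds_a, _, _, classified = _scenario([snp, snp, snp])
        c = census_recoding_codons_with_ns_snp(classified, ds_a)
        assert (c.k, c.n) == (1, 1)

    def test_census_invariant_to_snp_order(self):
        s1, s2 = Snp("g", 4, "C", "T"), Snp("g", 7, "A", "C")
        a = _scenario([s1, s2])
        b = _scenario([s2, s1])
        ca = census_recoding_codons_with_ns_snp(a[3], a[0])
        cb = census_recoding_codons_with_ns_snp(b[3], b[0])
        assert (ca.k, ca.n) == (cb.k, cb.n)


class TestControlSnpCensus:
    def test_counts_conserved_unedited_nonsyn_codons_with_ns_snp(self):
        # codon AAA (cds 6..8) is unedited, A->G nonsynonymous, conserved;
        # it has no non-A position so can never carry a qualifying SNP.
        ds_a, ds_b, aln, _ = _scenario([])
        c = census_control_codons_with_ns_snp(ds_a, ds_b, aln,
                                              edited_gene_ids={"g"})
        assert (c.k, c.n) == (0, 1)

    def test_ns_snp_at_non_a_position_of_control_codon_counts(self):
        ds_a = SpeciesDataset("A")
        ds_a.add_gene(Gene("g", "A", "TTGACTTAA"))
        ds_b = SpeciesDataset("B")
        ds_b.add_gene(Gene("g", "B", "TTGACTTAA"))
        ds_a.add_snp(Snp("g", 4, "C", "T"))  # ACT->ATT Thr>Ile, nonsyn
        aln = {"g": ("g", align_genes(ds_a.genes["g"], ds_b.genes["g"]))}
        c = census_control_codons_with_ns_snp(ds_a, ds_b, aln,
                                              edited_gene_ids={"g"})
        assert (c.k, c.n) == (1, 1)

    def test_synonymous_snps_never_count(self):
        ds_a = SpeciesDataset("A")
        ds_a.add_gene(Gene("g", "A", "TTGACTTAA"))
        ds_b = SpeciesDataset("B")
        ds_b.add_gene(Gene("g", "B", "TTGACTTAA"))
        ds_a.add_snp(Snp("g", 5, "T", "C"))  # ACT->ACC Thr, synonymous
        aln = {"g": ("g", align_genes(ds_a.genes["g"], ds_b.genes["g"]))}
        c = census_control_codons_with_ns_snp(ds_a, ds_b, aln,
                                              edited_gene_ids={"g"})
        assert (c.k, c.n) == (0, 1)

    def test_codon_conservation_mode_is_stricter_than_aa_mode(self):
        ds_a = SpeciesDataset("A")
        ds_a.add_gene(Gene("g", "A", "TTGACTTAA"))
        ds_b = SpeciesDataset("B")
        ds_b.add_gene(Gene("g", "B", "TTGACCTAA"))  # ACC: same Thr, other codon
        aln = {"g": ("g", align_genes(ds_a.genes["g"], ds_b.genes["g"]))}
        aa_mode = census_control_codons_with_ns_snp(
            ds_a, ds_b, aln, edited_gene_ids={"g"}, conserved="aa")
        codon_mode = census_control_codons_with_ns_snp(
            ds_a, ds_b, aln, edited_gene_ids={"g"}, conserved="codon")
        assert aa_mode.n == 1 and codon_mode.n == 0
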