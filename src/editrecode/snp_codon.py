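"""SNP consequence annotation and codon-level co-occurrence with recoding.

A population SNP at one of the two non-adenosine positions of a codon that
hosts a conserved recoding site is exactly the kind of mutation that, once
fixed, converts conserved recoding into conserved editing with
non-conserved recoding. This module annotates SNP consequences under the
standard code and counts, per codon, how often such nonsynonymous SNPs
co-occur with (i) conserved recoding sites and (ii) the unedited-adenosine
control universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from .consequence import ConsequenceClass, classify_change
from .conservation import AlignmentMap, PairClass, SitePair
from .datamodel import Gene, Snp, SpeciesDataset
from .genetics import CODON_TO_AA, NUCLEOTIDES


@dataclass(frozen=True)
class SnpConsequence:
    snp: Snp
    codon_index: int
    codon_pos: int
    pre_codon: str
    post_codon: str
    consequence: ConsequenceClass
    in_terminal_stop: bool


def _build_snp_table() -> dict[tuple[str, int, str], tuple[str, ConsequenceClass]]:
    table = {}
    for b1 in NUCLEOTIDES:
        for b2 in NUCLEOTIDES:
            for b3 in NUCLEOTIDES:
                codon = b1 + b2 + b3
                for pos in range(3):
                    for alt in NUCLEOTIDES:
                        if alt == codon[pos]:
                            continue
                        post = codon[:pos] + alt + codon[pos + 1 :]
                        table[(codon, pos, alt)] = (
                            post,
                            classify_change(CODON_TO_AA[codon], CODON_TO_AA[post]),
                        )
    return table


#: all 576 (codon, position, alternate) combinations, precomputed
_SNP = _build_snp_table()


def annotate_snp(snp: Snp, gene: Gene) -> SnpConsequence:
    """Codon-table consequence of a single-nucleotide change.

    SNPs inside the terminal stop codon are flagged so tallies of
    synonymous/nonsynonymous changes can exclude them.
    """
    base = gene.cds[snp.cds_pos]
    if base != snp.ref_base:
        raise ValueError(
            f"SNP REF {snp.ref_base} mismatches CDS base {base} at "
            f"{snp.gene_id}:{snp.cds_pos}"
        )
    codon = gene.codon(snp.codon_index)
    post, cls = _SNP[(codon, snp.codon_pos, snp.alt_base)]
    return SnpConsequence(
        snp=snp, codon_index=snp.codon_index, codon_pos=snp.codon_pos,
        pre_codon=codon, post_codon=post, consequence=cls,
        in_terminal_stop=snp.cds_pos >= gene.coding_length,
    )


@dataclass(frozen=True)
class SnpCodonCensus:
    """k qualifying codons carrying >=1 nonsynonymous SNP, out of n."""

    k: int
    n: int

    def __post_init__(self) -> None:
        assert 0 <= self.k <= self.n


def _ns_snp_positions(
    dataset: SpeciesDataset, include_terminal_stop: bool = False
) -> dict[tuple[str, int], set[int]]:
    """(gene_id, codon_index) -> codon positions carrying a nonsynonymous SNP.

    Duplicate SNP rows and multiple alternates collapse into one position
    set, so downstream counting is idempotent.
    """
    out: dict[tuple[str, int], set[int]] = {}
    for snp in dataset.snps:
        gene = dataset.genes[snp.gene_id]
        ann = annotate_snp(snp, gene)
        if ann.in_terminal_stop and not include_terminal_stop:
            continue
        if ann.consequence is ConsequenceClass.NONSYNONYMOUS:
            out.setdefault((snp.gene_id, snp.codon_index), set()).add(snp.codon_pos)
    return out


def census_recoding_codons_with_ns_snp(
    classified_pairs: Iterable[tuple[SitePair, PairClass]],
    dataset_a: SpeciesDataset,
    include_edited_position: bool = False,
) -> SnpCodonCensus:
    """Among conserved-recoding sites, count codons with a nonsynonymous SNP
    at a non-edited position of the same codon.

    Only SNPs at the two codon positions other than the edited adenosine
    qualify by default; ``include_edited_position`` adds SNPs on the edited
    A itself (the editing-abolishing class), reported via the same counter
    for sensitivity analysis.
    """
    ns = _ns_snp_positions(dataset_a)
    n = k = 0
    for pair, cls in classified_pairs:
        if cls is not PairClass.CONSERVED_RECODING:
            continue
        n += 1
        positions = ns.get((pair.gene_id_a, pair.site_a.codon_index), set())
        if include_edited_position:
            qualifying = positions
        else:
            qualifying = positions - {pair.site_a.codon_pos}
        if qualifying:
            k += 1
    return SnpCodonCensus(k=k, n=n)


def census_control_codons_with_ns_snp(
    dataset_a: SpeciesDataset,
    dataset_b: SpeciesDataset,
    alignments: AlignmentMap,
    edited_gene_ids: Optional[set[str]] = None,
    require_both: bool = True,
    conserved: str = "aa",
) -> SnpCodonCensus:
    """Control universe for the SNP co-occurrence test.

    ``n`` counts codons (in edited genes) that (1) contain an adenosine
    unedited in both species, (2) would be nonsynonymous if A→G occurred,
    and (3) are conserved between the species — identical encoded amino
    acid by default (``conserved='aa'``) or identical codon
    (``conserved='codon'``). ``k`` counts those with >=1 nonsynonymous SNP
    at a codon position other than the qualifying adenosines.
    """
    if conserved not in {"aa", "codon"}:
        raise ValueError("conserved must be 'aa' or 'codon'")
    if edited_gene_ids is None:
        edited_gene_ids = dataset_a.edited_gene_ids()
    ns = _ns_snp_positions(dataset_a)
    edited_b_all: dict[str, set[int]] = {}
    for s in dataset_b.sites:
        edited_b_all.setdefault(s.gene_id, set()).add(s.cds_pos)
    from .consequence import annotate_a_to_g

    n = k = 0
    for gene_id in sorted(edited_gene_ids):
        entry = alignments.get(gene_id)
        if entry is None:
            continue
        gene_id_b, aln = entry
        ed_a = dataset_a.edited_positions(gene_id)
        ed_b = edited_b_all.get(gene_id_b, set())
        for ia, ib, codon_a, codon_b in aln.codon_pairs():
            if conserved == "aa":
                if CODON_TO_AA[codon_a] != CODON_TO_AA[codon_b]:
                    continue
            elif codon_a != codon_b:
                continue
            hits = []
            for off in range(3):
                if codon_a[off] != "A" or codon_b[off] != "A":
                    continue
                if 3 * ia + off in ed_a or 3 * ib + off in ed_b:
                    continue
                if annotate_a_to_g(codon_a, off)[0] is not ConsequenceClass.NONSYNONYMOUS:
                    continue
                if require_both and (
                    annotate_a_to_g(codon_b, off)[0] is not ConsequenceClass.NONSYNONYMOUS
                ):
                    continue
                hits.append(off)
            if not hits:
                continue
            n += 1
            positions = ns.get((gene_id, ia), set())
            if positions - set(hits):
                k += 1
    return SnpCodonCensus(k=k, n=n)


def write_snp_match_tsv(
    classified_pairs: Iterable[tuple[SitePair, PairClass]],
    dataset_a: SpeciesDataset,
    path: str | Path,
) -> None:
    """Per-site report of nonsynonymous SNPs sharing a conserved-recoding codon."""
    ns: dict[tuple[str, int], list[SnpConsequence]] = {}
    for snp in dataset_a.snps:
        ann = annotate_snp(snp, dataset_a.genes[snp.gene_id])
        if ann.consequence is ConsequenceClass.NONSYNONYMOUS and not ann.in_terminal_stop:
            ns.setdefault((snp.gene_id, snp.codon_index), []).append(ann)
    lines = [
        "#gene\tsite_pos_1based\tcodon\tsnp_pos_1based\tref\talt\t"
        "snp_pre_codon\tsnp_post_codon\tsnp_class"
    ]
    for pair, cls in classified_pairs:
        if cls is not PairClass.CONSERVED_RECODING:
            continue
        for ann in ns.get((pair.gene_id_a, pair.site_a.codon_index), []):
            if ann.codon_pos == pair.site_a.codon_pos:
                continue
            lines.append(
                f"{pair.gene_id_a}\t{pair.site_a.cds_pos + 1}\t{pair.codon_a}\t"
                f"{ann.snp.cds_pos + 1}\t{ann.snp.ref_base}\t{ann.snp.alt_base}\t"
                f"{ann.pre_codon}\t{ann.post_codon}\t{ann.consequence.value}"
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
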