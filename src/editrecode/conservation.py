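"""Cross-species conserved-editing detection and control-codon censuses.

A site edited in two species at the same orthologous adenosine is
"conserved editing". When both edits are nonsynonymous, the recoding may
nevertheless differ between species if a substitution elsewhere in the
codon changed the encoded amino acid (e.g. AGT Ser>Gly in one species vs
ACT Thr>Ala in the other): "conserved editing with non-conserved
recoding". This module finds conserved site pairs, classifies them, and
builds the genome-wide unedited-adenosine control census that supplies the
null expectation for how often aligned codons around a conserved adenosine
encode different amino acids.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

from .alignment import CodonAlignment
from .consequence import ConsequenceClass, RecodingEvent, annotate_a_to_g
from .datamodel import EditingSite, SpeciesDataset


class PairClass(enum.Enum):
    CONSERVED_RECODING = "conserved_recoding"
    NON_CONSERVED_RECODING = "non_conserved_recoding"
    NOT_NONSYNONYMOUS_IN_BOTH = "not_nonsynonymous_in_both"
    NOT_CONSERVED_EDITING = "not_conserved_editing"


@dataclass(frozen=True)
class SitePair:
    """An orthologous adenosine edited in both species."""

    gene_id_a: str
    gene_id_b: str
    site_a: EditingSite
    pos_b: int
    codon_a: str
    codon_b: str
    codon_pos: int
    event_a: RecodingEvent
    event_b: RecodingEvent


@dataclass(frozen=True)
class ControlCodonCensus:
    """Unedited-adenosine control counts.

    ``n_total``: conserved (aligned, gap-free) adenosines unedited in both
    species whose A→G change is nonsynonymous; ``n_diff_aa``: the subset in
    codon pairs encoding different amino acids.
    """

    n_total: int
    n_diff_aa: int

    def __post_init__(self) -> None:
        assert 0 <= self.n_diff_aa <= self.n_total


# Alignments are supplied as gene_id_a -> (gene_id_b, CodonAlignment)
AlignmentMap = Mapping[str, tuple[str, CodonAlignment]]


def find_conserved_editing(
    dataset_a: SpeciesDataset,
    dataset_b: SpeciesDataset,
    alignments: AlignmentMap,
) -> tuple[list[SitePair], Counter]:
    """Pair species-A editing sites with orthologous edited adenosines in B.

    A pair is emitted iff the lifted position exists (codon gap-free), both
    species carry 'A' there, and both species list it as edited. Discarded
    sites are tallied by reason, never raised.
    """
    pairs: list[SitePair] = []
    discards: Counter[str] = Counter()
    edited_b: dict[str, set[int]] = {}
    for s in dataset_b.sites:
        edited_b.setdefault(s.gene_id, set()).add(s.cds_pos)

    for site in sorted(dataset_a.sites, key=lambda s: (s.gene_id, s.cds_pos)):
        entry = alignments.get(site.gene_id)
        if entry is None:
            discards["gene_unaligned"] += 1
            continue
        gene_id_b, aln = entry
        gene_a = dataset_a.genes[site.gene_id]
        if site.cds_pos >= gene_a.coding_length:
            discards["terminal_stop"] += 1
            continue
        pos_b = aln.map_cds_position(site.cds_pos)
        if pos_b is None:
            discards["codon_gapped"] += 1
            continue
        base_b = aln.cds_b[pos_b]
        if base_b != "A":
            # DNA substitution on the editing site itself abolished the
            # editing potential in the other lineage
            discards["a_not_conserved"] += 1
            continue
        if pos_b not in edited_b.get(gene_id_b, set()):
            discards["not_edited_in_b"] += 1
            continue
        codon_a = aln.cds_a[3 * site.codon_index : 3 * site.codon_index + 3]
        ib = pos_b // 3
        codon_b = aln.cds_b[3 * ib : 3 * ib + 3]
        _, ev_a = annotate_a_to_g(codon_a, site.codon_pos)
        _, ev_b = annotate_a_to_g(codon_b, pos_b % 3)
        pairs.append(
            SitePair(
                gene_id_a=site.gene_id, gene_id_b=gene_id_b, site_a=site,
                pos_b=pos_b, codon_a=codon_a, codon_b=codon_b,
                codon_pos=site.codon_pos, event_a=ev_a, event_b=ev_b,
            )
        )
    return pairs, discards


def classify_pair(pair: SitePair) -> PairClass:
    """Recoding-conservation class of a conserved-editing site pair."""
    cls_a = annotate_a_to_g(pair.codon_a, pair.codon_pos)[0]
    cls_b = annotate_a_to_g(pair.codon_b, pair.codon_pos)[0]
    if (cls_a is not ConsequenceClass.NONSYNONYMOUS
            or cls_b is not ConsequenceClass.NONSYNONYMOUS):
        return PairClass.NOT_NONSYNONYMOUS_IN_BOTH
    label_a = f"{pair.event_a.pre_aa}>{pair.event_a.post_aa}"
    label_b = f"{pair.event_b.pre_aa}>{pair.event_b.post_aa}"
    if label_a == label_b:
        return PairClass.CONSERVED_RECODING
    return PairClass.NON_CONSERVED_RECODING


def classify_pairs(pairs: Iterable[SitePair]) -> tuple[list[tuple[SitePair, PairClass]], Counter]:
    classified = [(p, classify_pair(p)) for p in pairs]
    counts = Counter(c.value for _, c in classified)
    return classified, counts


def census_control_codons(
    dataset_a: SpeciesDataset,
    dataset_b: SpeciesDataset,
    alignments: AlignmentMap,
    edited_gene_ids: Optional[set[str]] = None,
    require_both: bool = True,
    per_codon: bool = False,
) -> ControlCodonCensus:
    """Count conserved, unedited, nonsynonymous-if-edited adenosines.

    Restricted to ``edited_gene_ids`` (default: species-A edited genes that
    have an alignment) to control for the higher conservation of edited
    genes. ``require_both`` demands the A→G change be nonsynonymous in both
    species (the symmetric reading); switch off for reference-species-only.
    ``per_codon`` counts each qualifying codon once instead of each
    qualifying adenosine.
    """
    if edited_gene_ids is None:
        edited_gene_ids = dataset_a.edited_gene_ids()
    edited_a = {g: dataset_a.edited_positions(g) for g in edited_gene_ids}
    edited_b_all: dict[str, set[int]] = {}
    for s in dataset_b.sites:
        edited_b_all.setdefault(s.gene_id, set()).add(s.cds_pos)

    n_total = n_diff = 0
    for gene_id in sorted(edited_gene_ids):
        entry = alignments.get(gene_id)
        if entry is None:
            continue
        gene_id_b, aln = entry
        ed_a = edited_a.get(gene_id, set())
        ed_b = edited_b_all.get(gene_id_b, set())
        for ia, ib, codon_a, codon_b in aln.codon_pairs():
            hits = []
            for off in range(3):
                if codon_a[off] != "A" or codon_b[off] != "A":
                    continue
                pos_a, pos_b = 3 * ia + off, 3 * ib + off
                if pos_a in ed_a or pos_b in ed_b:
                    continue
                cls_a = annotate_a_to_g(codon_a, off)[0]
                if cls_a is not ConsequenceClass.NONSYNONYMOUS:
                    continue
                if require_both:
                    cls_b = annotate_a_to_g(codon_b, off)[0]
                    if cls_b is not ConsequenceClass.NONSYNONYMOUS:
                        continue
                hits.append(off)
            if not hits:
                continue
            from .genetics import CODON_TO_AA

            diff = CODON_TO_AA[codon_a] != CODON_TO_AA[codon_b]
            if per_codon:
                n_total += 1
                n_diff += int(diff)
            else:
                n_total += len(hits)
                n_diff += len(hits) * int(diff)
    return ControlCodonCensus(n_total=n_total, n_diff_aa=n_diff)


def write_pair_report_tsv(
    classified: Iterable[tuple[SitePair, PairClass]], path: str | Path
) -> None:
    lines = [
        "#gene_a\tgene_b\tpos_a_1based\tpos_b_1based\tcodon_a\tcodon_b\t"
        "codon_pos\trecoding_a\trecoding_b\tclass"
    ]
    for p, c in classified:
        ra = f"{p.event_a.pre_aa}>{p.event_a.post_aa}"
        rb = f"{p.event_b.pre_aa}>{p.event_b.post_aa}"
        lines.append(
            f"{p.gene_id_a}\t{p.gene_id_b}\t{p.site_a.cds_pos + 1}\t{p.pos_b + 1}\t"
            f"{p.codon_a}\t{p.codon_b}\t{p.codon_pos}\t{ra}\t{rb}\t{c.value}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
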