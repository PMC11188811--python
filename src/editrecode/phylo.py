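"""Clade-wide screen for conserved editing with non-conserved recoding.

Nonsynonymous editing sites conserved across a set of reference editomes
are projected, through reference→target codon alignments, onto every
target species of a clade. Because editing loss is rare, a target whose
orthologous codon retains the adenosine can be presumed edited; if that
codon encodes a different amino acid than the reference, the site is a
candidate for conserved editing with non-conserved recoding in that
species. Candidates are hypotheses — transcriptome confirmation of editing
in the target is outside this package's scope, and the status field keeps
that explicit.

Only tree topology is consumed (branch lengths are ignored); the tree
orders the per-species summary.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import dendropy
import pandas as pd

from .consequence import ConsequenceClass, annotate_a_to_g
from .conservation import AlignmentMap
from .datamodel import EditingSite, SpeciesDataset
from .genetics import CODON_TO_AA

logger = logging.getLogger(__name__)


class ScreenStatus(enum.Enum):
    CANDIDATE = "candidate"
    CONSERVED_RECODING = "conserved_recoding"
    A_LOST = "A_lost"
    UNALIGNABLE = "unalignable"


@dataclass(frozen=True)
class CandidateSite:
    """One (reference site, target species) screening outcome."""

    gene_id: str
    site: EditingSite
    ref_codon: str
    ref_type: str
    target_species: str
    status: ScreenStatus
    target_gene_id: Optional[str] = None
    target_pos: Optional[int] = None
    target_codon: Optional[str] = None
    hypothetical_type: Optional[str] = None


def build_reference_sites(
    primary: SpeciesDataset,
    other_refs: Sequence[SpeciesDataset],
    alignments_to_refs: Sequence[AlignmentMap],
) -> list[EditingSite]:
    """Sites of the primary editome that are nonsynonymous and conserved-
    edited (with a nonsynonymous consequence) in every other reference
    editome at the orthologous position."""
    if len(other_refs) != len(alignments_to_refs):
        raise ValueError("need one alignment map per non-primary reference")
    edited_refs = []
    for ref in other_refs:
        idx: dict[str, set[int]] = {}
        for s in ref.sites:
            idx.setdefault(s.gene_id, set()).add(s.cds_pos)
        edited_refs.append(idx)

    out: list[EditingSite] = []
    for site in sorted(primary.sites, key=lambda s: (s.gene_id, s.cds_pos)):
        gene = primary.genes[site.gene_id]
        if site.cds_pos >= gene.coding_length:
            continue
        codon = gene.codon(site.codon_index)
        if annotate_a_to_g(codon, site.codon_pos)[0] is not ConsequenceClass.NONSYNONYMOUS:
            continue
        ok = True
        for ref, idx, amap in zip(other_refs, edited_refs, alignments_to_refs):
            entry = amap.get(site.gene_id)
            if entry is None:
                ok = False
                break
            gene_id_r, aln = entry
            pos_r = aln.map_cds_position(site.cds_pos)
            if pos_r is None or aln.cds_b[pos_r] != "A":
                ok = False
                break
            if pos_r not in idx.get(gene_id_r, set()):
                ok = False
                break
            codon_r = aln.cds_b[3 * (pos_r // 3) : 3 * (pos_r // 3) + 3]
            if annotate_a_to_g(codon_r, pos_r % 3)[0] is not ConsequenceClass.NONSYNONYMOUS:
                ok = False
                break
        if ok:
            out.append(site)
    return out


def screen_target(
    ref_sites: Sequence[EditingSite],
    ref_dataset: SpeciesDataset,
    target_dataset: SpeciesDataset,
    alignments: AlignmentMap,
) -> list[CandidateSite]:
    """Classify every reference site against one target species.

    candidate: adenosine retained but the codon encodes a different amino
    acid (non-conserved recoding if the presumed editing exists);
    conserved_recoding: adenosine retained, same amino acid; A_lost: the
    orthologous base is no longer 'A'; unalignable: no ortholog or the
    codon falls in an alignment gap.
    """
    out: list[CandidateSite] = []
    for site in ref_sites:
        gene = ref_dataset.genes[site.gene_id]
        ref_codon = gene.codon(site.codon_index)
        _, ref_ev = annotate_a_to_g(ref_codon, site.codon_pos)
        ref_type = f"{ref_ev.pre_aa}>{ref_ev.post_aa}"
        common = dict(
            gene_id=site.gene_id, site=site, ref_codon=ref_codon,
            ref_type=ref_type, target_species=target_dataset.species_id,
        )
        entry = alignments.get(site.gene_id)
        if entry is None:
            out.append(CandidateSite(status=ScreenStatus.UNALIGNABLE, **common))
            continue
        gene_id_t, aln = entry
        pos_t = aln.map_cds_position(site.cds_pos)
        if pos_t is None:
            out.append(CandidateSite(status=ScreenStatus.UNALIGNABLE,
                                     target_gene_id=gene_id_t, **common))
            continue
        it = pos_t // 3
        codon_t = aln.cds_b[3 * it : 3 * it + 3]
        if aln.cds_b[pos_t] != "A":
            out.append(CandidateSite(
                status=ScreenStatus.A_LOST, target_gene_id=gene_id_t,
                target_pos=pos_t, target_codon=codon_t, **common))
            continue
        post = codon_t[: pos_t % 3] + "G" + codon_t[pos_t % 3 + 1 :]
        hyp = f"{CODON_TO_AA[codon_t]}>{CODON_TO_AA[post]}"
        if CODON_TO_AA[codon_t] != CODON_TO_AA[ref_codon]:
            status = ScreenStatus.CANDIDATE
        else:
            status = ScreenStatus.CONSERVED_RECODING
        out.append(CandidateSite(
            status=status, target_gene_id=gene_id_t, target_pos=pos_t,
            target_codon=codon_t, hypothetical_type=hyp, **common))
    return out


def read_tree_topology(source: str | Path) -> dendropy.Tree:
    """Read a newick tree, topology only (branch lengths are discarded)."""
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    tree = dendropy.Tree.get(data=text, schema="newick")
    for edge in tree.preorder_edge_iter():
        edge.length = None
    return tree


def tree_leaf_order(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def summarize_screen(
    candidates_by_species: Mapping[str, Sequence[CandidateSite]],
    tree: Optional[dendropy.Tree] = None,
) -> pd.DataFrame:
    """Per-species status tallies, one row per species in tree leaf order.

    Species absent from the tree are appended (with a warning) after the
    ordered ones; per-row counts always sum to that species' screened-site
    count.
    """
    order = []
    if tree is not None:
        leaves = tree_leaf_order(tree)
        order = [sp for sp in leaves if sp in candidates_by_species]
        missing = sorted(set(candidates_by_species) - set(leaves))
        if missing:
            logger.warning("species not in tree, appended unordered: %s", missing)
        order += missing
    else:
        order = sorted(candidates_by_species)
    rows = []
    for sp in order:
        counts = Counter(c.status for c in candidates_by_species[sp])
        rows.append({
            "species": sp,
            **{s.value: counts.get(s, 0) for s in ScreenStatus},
            "total": sum(counts.values()),
        })
    return pd.DataFrame(rows)


def write_candidates_tsv(
    candidates_by_species: Mapping[str, Sequence[CandidateSite]], path: str | Path
) -> None:
    lines = [
        "#species\tgene\tref_pos_1based\tref_codon\tref_recoding\t"
        "target_codon\thypothetical_recoding\tstatus"
    ]
    for sp in sorted(candidates_by_species):
        for c in candidates_by_species[sp]:
            lines.append(
                f"{sp}\t{c.gene_id}\t{c.site.cds_pos + 1}\t{c.ref_codon}\t"
                f"{c.ref_type}\t{c.target_codon or '.'}\t"
                f"{c.hypothetical_type or '.'}\t{c.status.value}"
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
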