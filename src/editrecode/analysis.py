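"""High-level analysis objects: build from datasets, ``fit()``, inspect Results.

`PairwiseRecodingAnalysis` runs the full two-species pipeline — ortholog
pairing, protein-guided codon alignment, conserved-editing detection,
recoding classification, unedited-adenosine control census, Fisher
enrichment, and (when SNPs are attached) the SNP co-occurrence test.
`CladeRecodingScreen` runs the multi-species candidate screen. Both follow
the estimator convention of returning a Results object whose ``summary()``
prints the headline numbers.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import conservation, phylo, snp_codon
from .alignment import align_genes, make_aligner, pick_ortholog
from .conservation import AlignmentMap, PairClass, SitePair
from .datamodel import SpeciesDataset
from .enrichment import EnrichmentResult, enrichment_report

logger = logging.getLogger(__name__)


def _build_alignment_map(
    dataset_a: SpeciesDataset,
    dataset_b: SpeciesDataset,
    gene_ids: Sequence[str],
    aligner,
    ortholog: str = "auto",
) -> tuple[AlignmentMap, Counter]:
    """Align each species-A gene to its species-B ortholog.

    ``ortholog='by_id'`` pairs genes sharing an id (curated ortholog tables
    and the simulator provide matched ids); ``'best_hit'`` picks the
    best-global-score candidate among all species-B proteins; ``'auto'``
    uses shared ids when most ids overlap, else best hit.
    """
    discards: Counter[str] = Counter()
    mode = ortholog
    if mode == "auto":
        ids_a = set(gene_ids)
        overlap = len(ids_a & set(dataset_b.genes)) / max(1, len(ids_a))
        mode = "by_id" if overlap >= 0.5 else "best_hit"
        logger.info("ortholog mode resolved to %r (id overlap %.0f%%)",
                    mode, 100 * overlap)
    candidates = {gid: g.protein for gid, g in dataset_b.genes.items()}
    alignments: dict[str, tuple[str, object]] = {}
    for gene_id in sorted(gene_ids):
        gene_a = dataset_a.genes[gene_id]
        if mode == "by_id":
            if gene_id not in dataset_b.genes:
                discards["no_ortholog"] += 1
                continue
            target_id = gene_id
        else:
            target_id, _ = pick_ortholog(gene_a.protein, candidates, aligner=aligner)
        alignments[gene_id] = (
            target_id,
            align_genes(gene_a, dataset_b.genes[target_id], aligner=aligner),
        )
    return alignments, discards


@dataclass
class PairwiseRecodingResults:
    """Fitted results of a two-species recoding-conservation analysis."""

    species_a: str
    species_b: str
    classified: list[tuple[SitePair, PairClass]]
    class_counts: Counter
    discards: Counter
    control_census: conservation.ControlCodonCensus
    enrichment: EnrichmentResult
    snp_observed: Optional[snp_codon.SnpCodonCensus] = None
    snp_control: Optional[snp_codon.SnpCodonCensus] = None
    snp_enrichment: Optional[EnrichmentResult] = None
    alignments: AlignmentMap = field(default_factory=dict)

    @property
    def n_nonsynonymous_both(self) -> int:
        return (self.class_counts.get(PairClass.CONSERVED_RECODING.value, 0)
                + self.class_counts.get(PairClass.NON_CONSERVED_RECODING.value, 0))

    def summary(self) -> str:
        lines = [
            f"Pairwise recoding-conservation analysis: "
            f"{self.species_a} vs {self.species_b}",
            f"  conserved-editing site pairs: {len(self.classified)}",
        ]
        for cls in PairClass:
            if cls is PairClass.NOT_CONSERVED_EDITING:
                continue
            lines.append(f"    {cls.value}: {self.class_counts.get(cls.value, 0)}")
        lines.append(
            "  sites discarded: "
            + (", ".join(f"{k}={v}" for k, v in sorted(self.discards.items()))
               or "none")
        )
        lines.append(
            f"  control census: {self.control_census.n_diff_aa} different-AA "
            f"of {self.control_census.n_total} conserved unedited adenosines"
        )
        lines.append("  " + self.enrichment.summary())
        if self.snp_enrichment is not None:
            lines.append("  " + self.snp_enrichment.summary())
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "species_a": self.species_a,
            "species_b": self.species_b,
            "n_pairs": len(self.classified),
            "class_counts": dict(self.class_counts),
            "discards": dict(self.discards),
            "control_census": {
                "n_total": self.control_census.n_total,
                "n_diff_aa": self.control_census.n_diff_aa,
            },
            "enrichment": self.enrichment.to_dict(),
        }
        if self.snp_enrichment is not None:
            out["snp"] = {
                "observed": {"k": self.snp_observed.k, "n": self.snp_observed.n},
                "control": {"k": self.snp_control.k, "n": self.snp_control.n},
                "enrichment": self.snp_enrichment.to_dict(),
            }
        return out

    def pairs_frame(self) -> pd.DataFrame:
        rows = []
        for p, c in self.classified:
            rows.append({
                "gene_a": p.gene_id_a, "gene_b": p.gene_id_b,
                "pos_a": p.site_a.cds_pos, "pos_b": p.pos_b,
                "codon_a": p.codon_a, "codon_b": p.codon_b,
                "codon_pos": p.codon_pos,
                "recoding_a": f"{p.event_a.pre_aa}>{p.event_a.post_aa}",
                "recoding_b": f"{p.event_b.pre_aa}>{p.event_b.post_aa}",
                "class": c.value,
            })
        return pd.DataFrame(rows, columns=[
            "gene_a", "gene_b", "pos_a", "pos_b", "codon_a", "codon_b",
            "codon_pos", "recoding_a", "recoding_b", "class"])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        conservation.write_pair_report_tsv(self.classified, outdir / "site_pairs.tsv")
        (outdir / "summary.json").write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )


class PairwiseRecodingAnalysis:
    """Two-species conserved-editing / non-conserved-recoding analysis.

    Parameters
    ----------
    dataset_a, dataset_b:
        The reference and comparison species; editing sites must be
        attached to both, SNPs (optional) to ``dataset_a``.
    ortholog:
        'by_id', 'best_hit', or 'auto' (see ``_build_alignment_map``).
    require_both:
        Control adenosines must be nonsynonymous-if-edited in both species
        (symmetric definition) rather than in the reference only.
    control_per_codon:
        Count control codons once per codon instead of once per adenosine.
    snp_conserved:
        Conservation criterion for the SNP control universe: identical
        encoded amino acid ('aa') or identical codon ('codon').
    """

    def __init__(
        self,
        dataset_a: SpeciesDataset,
        dataset_b: SpeciesDataset,
        *,
        matrix: str = "BLOSUM62",
        gap_open: float = 10.0,
        gap_extend: float = 1.0,
        ortholog: str = "auto",
        require_both: bool = True,
        control_per_codon: bool = False,
        snp_conserved: str = "aa",
    ) -> None:
        self.dataset_a = dataset_a
        self.dataset_b = dataset_b
        self.aligner = make_aligner(matrix, gap_open, gap_extend)
        self.ortholog = ortholog
        self.require_both = require_both
        self.control_per_codon = control_per_codon
        self.snp_conserved = snp_conserved

    def fit(self) -> PairwiseRecodingResults:
        edited_genes = sorted(
            g for g in self.dataset_a.edited_gene_ids() if g in self.dataset_a.genes
        )
        alignments, align_discards = _build_alignment_map(
            self.dataset_a, self.dataset_b, edited_genes, self.aligner,
            ortholog=self.ortholog,
        )
        pairs, discards = conservation.find_conserved_editing(
            self.dataset_a, self.dataset_b, alignments
        )
        discards.update(align_discards)
        classified, class_counts = conservation.classify_pairs(pairs)
        census = conservation.census_control_codons(
            self.dataset_a, self.dataset_b, alignments,
            edited_gene_ids=set(edited_genes),
            require_both=self.require_both,
            per_codon=self.control_per_codon,
        )
        n_ns_both = (class_counts.get(PairClass.CONSERVED_RECODING.value, 0)
                     + class_counts.get(PairClass.NON_CONSERVED_RECODING.value, 0))
        enr = enrichment_report(
            class_counts.get(PairClass.NON_CONSERVED_RECODING.value, 0),
            n_ns_both,
            census.n_diff_aa,
            census.n_total,
            label=f"non-conserved recoding {self.dataset_a.species_id} vs "
                  f"{self.dataset_b.species_id}",
        ) if n_ns_both and census.n_total else enrichment_report(
            0, max(n_ns_both, 1), census.n_diff_aa, max(census.n_total, 1),
            label="non-conserved recoding (degenerate inputs)",
        )
        result = PairwiseRecodingResults(
            species_a=self.dataset_a.species_id,
            species_b=self.dataset_b.species_id,
            classified=classified,
            class_counts=class_counts,
            discards=discards,
            control_census=census,
            enrichment=enr,
            alignments=alignments,
        )
        if self.dataset_a.snps:
            obs = snp_codon.census_recoding_codons_with_ns_snp(
                classified, self.dataset_a
            )
            ctrl = snp_codon.census_control_codons_with_ns_snp(
                self.dataset_a, self.dataset_b, alignments,
                edited_gene_ids=set(edited_genes),
                require_both=self.require_both,
                conserved=self.snp_conserved,
            )
            result.snp_observed = obs
            result.snp_control = ctrl
            result.snp_enrichment = enrichment_report(
                obs.k, max(obs.n, 1), ctrl.k, max(ctrl.n, 1),
                label=f"nonsynonymous SNPs in conserved-recoding codons "
                      f"({self.dataset_a.species_id})",
            )
        return result


@dataclass
class CladeScreenResults:
    """Fitted results of the clade-wide candidate screen."""

    primary_species: str
    ref_sites: list
    per_species: dict[str, list[phylo.CandidateSite]]
    summary_table: pd.DataFrame

    def summary(self) -> str:
        lines = [
            f"Clade screen anchored on {self.primary_species}: "
            f"{len(self.ref_sites)} reference-conserved nonsynonymous sites",
            self.summary_table.to_string(index=False),
        ]
        return "\n".join(lines)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        phylo.write_candidates_tsv(self.per_species, outdir / "candidates.tsv")
        self.summary_table.to_csv(outdir / "screen_summary.tsv", sep="\t",
                                  index=False)


class CladeRecodingScreen:
    """Screen a clade for conserved editing with non-conserved recoding.

    ``ref_datasets`` (primary first) define the reference-conserved
    nonsynonymous site set; each target species is screened through a
    primary→target codon alignment. The tree orders the summary and is
    consumed as topology only.
    """

    def __init__(
        self,
        ref_datasets: Sequence[SpeciesDataset],
        target_datasets: Sequence[SpeciesDataset],
        tree: Optional[str] = None,
        *,
        matrix: str = "BLOSUM62",
        gap_open: float = 10.0,
        gap_extend: float = 1.0,
        ortholog: str = "auto",
    ) -> None:
        if not ref_datasets:
            raise ValueError("need at least one reference dataset")
        self.primary = ref_datasets[0]
        self.other_refs = list(ref_datasets[1:])
        self.targets = list(target_datasets)
        self.tree = phylo.read_tree_topology(tree) if tree else None
        self.aligner = make_aligner(matrix, gap_open, gap_extend)
        self.ortholog = ortholog

    def fit(self) -> CladeScreenResults:
        edited = sorted(
            g for g in self.primary.edited_gene_ids() if g in self.primary.genes
        )
        ref_maps = []
        for ref in self.other_refs:
            amap, _ = _build_alignment_map(self.primary, ref, edited,
                                           self.aligner, ortholog=self.ortholog)
            ref_maps.append(amap)
        ref_sites = phylo.build_reference_sites(self.primary, self.other_refs,
                                                ref_maps)
        ref_genes = sorted({s.gene_id for s in ref_sites})
        per_species: dict[str, list[phylo.CandidateSite]] = {}
        for target in self.targets:
            amap, _ = _build_alignment_map(self.primary, target, ref_genes,
                                           self.aligner, ortholog=self.ortholog)
            per_species[target.species_id] = phylo.screen_target(
                ref_sites, self.primary, target, amap
            )
        table = phylo.summarize_screen(per_species, tree=self.tree)
        return CladeScreenResults(
            primary_species=self.primary.species_id,
            ref_sites=ref_sites,
            per_species=per_species,
            summary_table=table,
        )
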