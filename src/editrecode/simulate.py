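"""Synthetic multi-species editome generator with exact truth tables.

The generator emulates the data regime the comparative analysis consumes:
orthologous CDS sets diverged by a per-site substitution process with
transition bias, editing sites planted in four conservation categories
(conserved recoding, conserved editing with non-conserved recoding,
species-specific, and adenosine-lost), and population SNPs whose
nonsynonymous co-occurrence with conserved-recoding codons carries a
tunable enrichment factor. Planted codons are protected from background
substitution, so the truth table is exact by construction and every
pipeline stage can be tested by parameter recovery.

The substitution model is a per-site Bernoulli draw with a
transition:transversion weighting, not a continuous-time Markov chain: the
analysis consumes substitution *patterns*, not branch lengths, and the
simple model keeps the truth table exact. Substitutions that would create
a stop codon are resampled among the remaining alternates. No indel
process is simulated (edited Drosophila genes are strongly
length-conserved), so alignments of simulated pairs are ungapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .consequence import ConsequenceClass, classify_change
from .datamodel import DataError, EditingSite, Gene, Snp, SpeciesDataset
from .genetics import CODON_TO_AA, NUCLEOTIDES, SENSE_CODONS, TRANSITION

# ---------------------------------------------------------------------------
# static codon resources
# ---------------------------------------------------------------------------


def _is_nonsyn_a2g(codon: str, pos: int) -> bool:
    if codon[pos] != "A":
        return False
    post = codon[:pos] + "G" + codon[pos + 1 :]
    return (
        classify_change(CODON_TO_AA[codon], CODON_TO_AA[post])
        is ConsequenceClass.NONSYNONYMOUS
    )


#: (codon, pos) slots where editing the A is a nonsynonymous recoding
RECODING_SLOTS: list[tuple[str, int]] = sorted(
    (c, p)
    for c in SENSE_CODONS
    for p in range(3)
    if _is_nonsyn_a2g(c, p)
)


def _non_conserved_partners() -> dict[tuple[str, int], list[str]]:
    """For each recoding slot, sense codons reachable by one substitution at a
    non-A position that keep the edited A, stay a nonsynonymous recoding slot,
    and change the encoded amino acid (the AGT->ACT scenario)."""
    out: dict[tuple[str, int], list[str]] = {}
    for codon, pos in RECODING_SLOTS:
        partners = []
        for other in range(3):
            if other == pos:
                continue
            for alt in NUCLEOTIDES:
                if alt == codon[other]:
                    continue
                c2 = codon[:other] + alt + codon[other + 1 :]
                if c2 in CODON_TO_AA and CODON_TO_AA[c2] != "*":
                    if CODON_TO_AA[c2] != CODON_TO_AA[codon] and _is_nonsyn_a2g(c2, pos):
                        partners.append(c2)
        if partners:
            out[(codon, pos)] = sorted(partners)
    return out


NON_CONSERVED_PARTNERS = _non_conserved_partners()
NCR_SLOTS = sorted(NON_CONSERVED_PARTNERS)


def _syn_alts() -> dict[tuple[str, int], list[str]]:
    out: dict[tuple[str, int], list[str]] = {}
    for c in SENSE_CODONS:
        for p in range(3):
            alts = []
            for alt in NUCLEOTIDES:
                if alt == c[p]:
                    continue
                c2 = c[:p] + alt + c[p + 1 :]
                if CODON_TO_AA[c2] == CODON_TO_AA[c]:
                    alts.append(alt)
            if alts:
                out[(c, p)] = alts
    return out


SYN_ALTS = _syn_alts()


def _nonsyn_non_a_choices() -> dict[str, list[tuple[int, str]]]:
    """Per codon, the (position, alt) choices at non-adenosine positions whose
    substitution is nonsynonymous and stop-free."""
    out: dict[str, list[tuple[int, str]]] = {}
    for c in SENSE_CODONS:
        choices = []
        for p in range(3):
            if c[p] == "A":
                continue
            for alt in NUCLEOTIDES:
                if alt == c[p]:
                    continue
                c2 = c[:p] + alt + c[p + 1 :]
                if (
                    CODON_TO_AA[c2] != "*"
                    and CODON_TO_AA[c2] != CODON_TO_AA[c]
                ):
                    choices.append((p, alt))
        if choices:
            out[c] = choices
    return out


NONSYN_NON_A_CHOICES = _nonsyn_non_a_choices()


# ---------------------------------------------------------------------------
# parameters and truth
# ---------------------------------------------------------------------------


@dataclass
class SimParams:
    """Study conditions for a simulated species pair.

    Defaults scale the sibling-species comparison down to a desk-size
    genome while keeping the headline site counts: 480 conserved-recoding
    and 4 non-conserved-recoding sites among the planted editome, a 2%
    per-lineage substitution rate (sibling-species CDS divergence), and
    DGRP-like SNP densities (~0.025 nonsynonymous SNPs per codon, ~0.016
    synonymous SNPs per site with a synonymous alternate).
    """

    n_genes: int = 60
    mean_codons: int = 300
    min_codons: int = 50
    substitution_rate: float = 0.02
    ts_tv: float = 2.0
    n_conserved_recoding: int = 480
    n_non_conserved_recoding: int = 4
    n_species_specific: int = 150
    n_a_lost: int = 30
    snp_nonsyn_codon_prob: float = 0.025
    snp_syn_site_prob: float = 0.016
    snp_enrichment_factor: float = 1.0
    seed: int = 0
    species_a: str = "speciesA"
    species_b: str = "speciesB"

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "snp_nonsyn_codon_prob", "snp_syn_site_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.snp_enrichment_factor < 0:
            raise ValueError("snp_enrichment_factor must be >= 0")

    @property
    def n_planted(self) -> int:
        return (self.n_conserved_recoding + self.n_non_conserved_recoding
                + self.n_species_specific + self.n_a_lost)


@dataclass
class TruthTable:
    """Planted ground truth: one row per site; one row per placed SNP."""

    sites: pd.DataFrame
    snps: pd.DataFrame

    def category_counts(self) -> dict[str, int]:
        return self.sites["category"].value_counts().to_dict()


# ---------------------------------------------------------------------------
# internal machinery
# ---------------------------------------------------------------------------


def _choose_weighted_alt(rng: np.random.Generator, base: str, ts_tv: float,
                         forbidden: set[str]) -> Optional[str]:
    alts = [b for b in NUCLEOTIDES if b != base and b not in forbidden]
    if not alts:
        return None
    weights = np.array([ts_tv if TRANSITION[base] == a else 1.0 for a in alts])
    return alts[rng.choice(len(alts), p=weights / weights.sum())]


def _mutate_lineage(
    codons: list[str],
    protected: set[int],
    rate: float,
    ts_tv: float,
    rng: np.random.Generator,
) -> list[str]:
    """One lineage's background substitutions; stop-creating changes are
    resampled among remaining alternates. Start and stop codons are fixed."""
    if rate == 0:
        return list(codons)
    out = list(codons)
    n_cod = len(codons)
    hits = np.nonzero(rng.random(3 * n_cod) < rate)[0]
    for pos in hits:
        ci, off = pos // 3, pos % 3
        if ci == 0 or ci == n_cod - 1 or ci in protected:
            continue
        codon = out[ci]
        base = codon[off]
        forbidden: set[str] = set()
        while True:
            alt = _choose_weighted_alt(rng, base, ts_tv, forbidden)
            if alt is None:
                break
            cand = codon[:off] + alt + codon[off + 1 :]
            if CODON_TO_AA[cand] != "*":
                out[ci] = cand
                break
            forbidden.add(alt)
    return out


def _ancestral_genes(params: SimParams, rng: np.random.Generator) -> list[list[str]]:
    genes = []
    for _ in range(params.n_genes):
        n_cod = max(params.min_codons, int(rng.poisson(params.mean_codons)))
        body = rng.choice(len(SENSE_CODONS), size=n_cod - 1)
        genes.append(["ATG"] + [SENSE_CODONS[i] for i in body] + ["TAA"])
    return genes


# ---------------------------------------------------------------------------
# pairwise simulation
# ---------------------------------------------------------------------------


def simulate_pair(params: SimParams) -> tuple[SpeciesDataset, SpeciesDataset, TruthTable]:
    """Simulate a diverged species pair with planted editing sites and SNPs.

    Deterministic under ``params.seed``: identical parameters give
    byte-identical datasets. Raises :class:`DataError` before emission if
    the planted site counts do not fit the gene content.
    """
    ss = np.random.SeedSequence(params.seed)
    rng_genes, rng_plant, rng_mut_a, rng_mut_b, rng_snp, rng_level = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    ancestral = _ancestral_genes(params, rng_genes)
    gene_ids = [f"g{idx:04d}" for idx in range(params.n_genes)]

    # candidate planting slots: coding codons excluding start and stop
    slots = [
        (gi, ci)
        for gi, codons in enumerate(ancestral)
        for ci in range(1, len(codons) - 1)
    ]
    if params.n_planted > len(slots):
        raise DataError(
            f"cannot plant {params.n_planted} sites into {len(slots)} codons"
        )
    chosen = rng_plant.choice(len(slots), size=params.n_planted, replace=False)
    categories = (
        ["conserved_recoding"] * params.n_conserved_recoding
        + ["non_conserved_recoding"] * params.n_non_conserved_recoding
        + ["species_specific"] * params.n_species_specific
        + ["A_lost"] * params.n_a_lost
    )

    protected: dict[int, set[int]] = {gi: set() for gi in range(params.n_genes)}
    codons_a = [list(c) for c in ancestral]
    codons_b = [list(c) for c in ancestral]
    truth_rows = []
    for slot_idx, category in zip(chosen, categories):
        gi, ci = slots[slot_idx]
        protected[gi].add(ci)
        if category == "non_conserved_recoding":
            codon, pos = NCR_SLOTS[rng_plant.integers(len(NCR_SLOTS))]
            partners = NON_CONSERVED_PARTNERS[(codon, pos)]
            partner = partners[rng_plant.integers(len(partners))]
            if rng_plant.random() < 0.5:
                ca, cb = codon, partner
            else:
                ca, cb = partner, codon
        else:
            codon, pos = RECODING_SLOTS[rng_plant.integers(len(RECODING_SLOTS))]
            ca = cb = codon
            if category == "A_lost":
                for repl in (TRANSITION["A"], "C", "T"):
                    cand = codon[:pos] + repl + codon[pos + 1 :]
                    if CODON_TO_AA[cand] != "*":
                        cb = cand
                        break
        codons_a[gi][ci] = ca
        codons_b[gi][ci] = cb
        truth_rows.append({
            "gene_id": gene_ids[gi],
            "cds_pos": 3 * ci + pos,
            "codon_pos": pos,
            "category": category,
            "codon_a": ca,
            "codon_b": cb,
        })

    # background divergence (planted codons are protected)
    for gi in range(params.n_genes):
        codons_a[gi] = _mutate_lineage(codons_a[gi], protected[gi],
                                       params.substitution_rate, params.ts_tv,
                                       rng_mut_a)
        codons_b[gi] = _mutate_lineage(codons_b[gi], protected[gi],
                                       params.substitution_rate, params.ts_tv,
                                       rng_mut_b)

    ds_a = SpeciesDataset(species_id=params.species_a)
    ds_b = SpeciesDataset(species_id=params.species_b)
    for gi, gid in enumerate(gene_ids):
        ds_a.add_gene(Gene(gid, params.species_a, "".join(codons_a[gi])))
        ds_b.add_gene(Gene(gid, params.species_b, "".join(codons_b[gi])))

    # editing-site lists
    truth_rows.sort(key=lambda r: (r["gene_id"], r["cds_pos"]))
    for row in truth_rows:
        level = round(float(rng_level.uniform(0.01, 1.0)), 3)
        ds_a.add_site(EditingSite(row["gene_id"], row["cds_pos"], level=level))
        if row["category"] in {"conserved_recoding", "non_conserved_recoding"}:
            level_b = round(float(rng_level.uniform(0.01, 1.0)), 3)
            ds_b.add_site(EditingSite(row["gene_id"], row["cds_pos"], level=level_b))

    # SNPs in species A
    recoding_codons = {
        (r["gene_id"], r["cds_pos"] // 3)
        for r in truth_rows
        if r["category"] == "conserved_recoding"
    }
    snp_rows = []
    for gi, gid in enumerate(gene_ids):
        codons = codons_a[gi]
        for ci in range(1, len(codons) - 1):
            codon = codons[ci]
            in_recoding = (gid, ci) in recoding_codons
            p_ns = params.snp_nonsyn_codon_prob * (
                params.snp_enrichment_factor if in_recoding else 1.0
            )
            if rng_snp.random() < min(1.0, p_ns):
                choices = NONSYN_NON_A_CHOICES.get(codon)
                if choices:
                    p, alt = choices[rng_snp.integers(len(choices))]
                    snp_rows.append({
                        "gene_id": gid, "cds_pos": 3 * ci + p,
                        "ref": codon[p], "alt": alt, "channel": "nonsyn",
                        "in_recoding_codon": in_recoding,
                    })
            for off in range(3):
                key = (codon, off)
                if key in SYN_ALTS and rng_snp.random() < params.snp_syn_site_prob:
                    alts = SYN_ALTS[key]
                    alt = alts[rng_snp.integers(len(alts))]
                    snp_rows.append({
                        "gene_id": gid, "cds_pos": 3 * ci + off,
                        "ref": codon[off], "alt": alt, "channel": "syn",
                        "in_recoding_codon": in_recoding,
                    })
    for row in snp_rows:
        ds_a.add_snp(Snp(row["gene_id"], row["cds_pos"], row["ref"], row["alt"]))

    truth = TruthTable(
        sites=pd.DataFrame(truth_rows,
                           columns=["gene_id", "cds_pos", "codon_pos", "category",
                                    "codon_a", "codon_b"]),
        snps=pd.DataFrame(snp_rows,
                          columns=["gene_id", "cds_pos", "ref", "alt", "channel",
                                   "in_recoding_codon"]),
    )
    return ds_a, ds_b, truth


# ---------------------------------------------------------------------------
# clade simulation
# ---------------------------------------------------------------------------


@dataclass
class CladeSimParams:
    """Study conditions for a clade-wide screen simulation.

    The reference triple mimics the three-editome construction of the
    conserved nonsynonymous reference set; target species receive planted
    same-codon amino-acid-changing substitutions that retain the edited A
    (candidates) or lose it (A_lost), per ``candidate_plan`` /
    ``a_lost_plan`` mappings from species id to site count.
    """

    n_genes: int = 25
    mean_codons: int = 300
    min_codons: int = 50
    substitution_rate: float = 0.01
    ts_tv: float = 2.0
    n_ref_sites: int = 30
    ref_species: tuple[str, ...] = ("dmel", "dsim", "dpse")
    candidate_plan: Mapping[str, int] = field(default_factory=dict)
    a_lost_plan: Mapping[str, int] = field(default_factory=dict)
    seed: int = 0


def default_clade_topology(n_targets: int = 18,
                           ref: Sequence[str] = ("dmel", "dsim", "dpse")) -> str:
    """A ladder topology placing ``n_targets`` species between the first two
    reference species and the third, newick text."""
    targets = [f"t{i:02d}" for i in range(1, n_targets + 1)]
    inner = ref[2]
    for t in reversed(targets):
        inner = f"({t},{inner})"
    return f"(({ref[0]},{ref[1]}),{inner});"


def simulate_clade(
    params: CladeSimParams, topology: Optional[str] = None
) -> tuple[dict[str, SpeciesDataset], str, pd.DataFrame]:
    """Simulate a clade with reference-conserved recoding sites and planted
    candidate/A-lost events in designated target species.

    Returns (datasets by species, newick topology, truth table with one row
    per (site, target species) giving the planted screen status).
    """
    import dendropy

    n_targets_planned = len(set(params.candidate_plan) | set(params.a_lost_plan))
    if topology is None:
        topology = default_clade_topology(max(18, n_targets_planned),
                                          ref=params.ref_species)
    tree = dendropy.Tree.get(data=topology, schema="newick")
    species = [l.taxon.label for l in tree.leaf_node_iter()]
    for sp in params.ref_species:
        if sp not in species:
            raise DataError(f"reference species {sp!r} missing from topology")
    for sp in list(params.candidate_plan) + list(params.a_lost_plan):
        if sp not in species:
            raise DataError(f"planned species {sp!r} missing from topology")
        if sp in params.ref_species:
            raise DataError(f"cannot plant divergence in reference species {sp!r}")

    ss = np.random.SeedSequence(params.seed)
    rng_genes, rng_plant, rng_branch_root, rng_level = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    base = SimParams(n_genes=params.n_genes, mean_codons=params.mean_codons,
                     min_codons=params.min_codons)
    ancestral = _ancestral_genes(base, rng_genes)
    gene_ids = [f"g{idx:04d}" for idx in range(params.n_genes)]

    slots = [
        (gi, ci)
        for gi, codons in enumerate(ancestral)
        for ci in range(1, len(codons) - 1)
    ]
    total_planted = params.n_ref_sites
    if total_planted > len(slots):
        raise DataError("cannot plant reference sites into the gene content")
    chosen = rng_plant.choice(len(slots), size=total_planted, replace=False)
    planted = []  # (gi, ci, pos, codon)
    protected: dict[int, set[int]] = {gi: set() for gi in range(params.n_genes)}
    for slot_idx in chosen:
        gi, ci = slots[slot_idx]
        codon, pos = NCR_SLOTS[rng_plant.integers(len(NCR_SLOTS))]
        ancestral[gi][ci] = codon
        protected[gi].add(ci)
        planted.append((gi, ci, pos, codon))
    planted.sort()

    # propagate sequences down the tree, one substream per branch
    node_seqs: dict[int, list[list[str]]] = {id(tree.seed_node): ancestral}
    branch_rngs = iter(np.random.default_rng(s)
                       for s in np.random.SeedSequence(
                           rng_branch_root.integers(2**31)).spawn(200))
    leaf_seqs: dict[str, list[list[str]]] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            seqs = node_seqs[id(node)]
        else:
            parent = node_seqs[id(node.parent_node)]
            rng = next(branch_rngs)
            seqs = [
                _mutate_lineage(parent[gi], protected[gi],
                                params.substitution_rate, params.ts_tv, rng)
                for gi in range(params.n_genes)
            ]
            node_seqs[id(node)] = seqs
        if node.is_leaf():
            leaf_seqs[node.taxon.label] = [list(g) for g in seqs]

    # plant target-species divergence at reference sites
    assignable = list(range(len(planted)))
    truth_rows = []
    plans = [(sp, k, "candidate") for sp, k in sorted(params.candidate_plan.items())]
    plans += [(sp, k, "A_lost") for sp, k in sorted(params.a_lost_plan.items())]
    planted_status: dict[tuple[str, int], str] = {}
    for sp, k, kind in plans:
        if k > len(assignable):
            raise DataError("more planted divergences than reference sites")
        take = [assignable.pop(int(i))
                for i in sorted(rng_plant.choice(len(assignable), size=k,
                                                 replace=False), reverse=True)]
        for site_idx in sorted(take):
            gi, ci, pos, codon = planted[site_idx]
            if kind == "candidate":
                partners = NON_CONSERVED_PARTNERS[(codon, pos)]
                leaf_seqs[sp][gi][ci] = partners[rng_plant.integers(len(partners))]
            else:
                for repl in (TRANSITION["A"], "C", "T"):
                    cand = codon[:pos] + repl + codon[pos + 1 :]
                    if CODON_TO_AA[cand] != "*":
                        leaf_seqs[sp][gi][ci] = cand
                        break
            planted_status[(sp, site_idx)] = kind

    for site_idx, (gi, ci, pos, codon) in enumerate(planted):
        for sp in species:
            if sp in params.ref_species:
                continue
            status = planted_status.get((sp, site_idx), "conserved_recoding")
            truth_rows.append({
                "gene_id": gene_ids[gi], "cds_pos": 3 * ci + pos,
                "species": sp, "status": status,
            })

    datasets: dict[str, SpeciesDataset] = {}
    for sp in species:
        ds = SpeciesDataset(species_id=sp)
        for gi, gid in enumerate(gene_ids):
            ds.add_gene(Gene(gid, sp, "".join(leaf_seqs[sp][gi])))
        datasets[sp] = ds
    for sp in params.ref_species:
        for gi, ci, pos, codon in planted:
            level = round(float(rng_level.uniform(0.01, 1.0)), 3)
            datasets[sp].add_site(
                EditingSite(gene_ids[gi], 3 * ci + pos, level=level)
            )

    truth = pd.DataFrame(truth_rows,
                         columns=["gene_id", "cds_pos", "species", "status"])
    return datasets, topology, truth
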