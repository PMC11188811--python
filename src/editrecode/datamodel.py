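"""Core domain types: genes, editing sites, SNPs, and per-species datasets.

Conventions
-----------
* All in-memory coordinates are 0-based offsets into the sense-strand CDS;
  file formats use 1-based positions (VCF/TSV convention).
* A CDS is stored in sense orientation. Strand handling (extract A on '+',
  T on '-') happens once at ingestion; every downstream operation is
  strand-free.
* A terminal stop codon is allowed and retained on the CDS, but the derived
  protein excludes it and analyses flag positions inside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .genetics import NUCLEOTIDES, translate_cds


class DataError(Exception):
    """Structural problem with input data (hard error, exit code 2 in the CLI)."""


class CdsValidationError(DataError):
    """A CDS record failed validation (record-level; usually logged and skipped)."""


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene's CDS in sense-strand orientation.

    ``protein`` is the standard-table translation of the coding part,
    excluding the terminal stop codon if present.
    """

    gene_id: str
    species_id: str
    cds: str
    genome_strand: str = "+"

    def __post_init__(self) -> None:
        if set(self.cds) - set(NUCLEOTIDES):
            bad = sorted(set(self.cds) - set(NUCLEOTIDES))
            raise CdsValidationError(f"{self.gene_id}: non-ACGT characters {bad}")
        if not self.cds or len(self.cds) % 3:
            raise CdsValidationError(
                f"{self.gene_id}: CDS length {len(self.cds)} not divisible by 3"
            )
        aa = translate_cds(self.cds)
        internal = aa[:-1] if aa.endswith("*") else aa
        if "*" in internal:
            raise CdsValidationError(f"{self.gene_id}: internal stop codon")

    @property
    def protein(self) -> str:
        aa = translate_cds(self.cds)
        return aa[:-1] if aa.endswith("*") else aa

    @property
    def has_terminal_stop(self) -> bool:
        return translate_cds(self.cds).endswith("*")

    @property
    def coding_length(self) -> int:
        """Length of the CDS excluding the terminal stop codon."""
        return 3 * len(self.protein)

    def codon(self, codon_index: int) -> str:
        return self.cds[3 * codon_index : 3 * codon_index + 3]


@dataclass(frozen=True)
class EditingSite:
    """A genomically encoded adenosine subject to A-to-I editing.

    ``cds_pos`` is 0-based; the referenced base must be 'A' (checked when
    the site is attached to a dataset).
    """

    gene_id: str
    cds_pos: int
    level: Optional[float] = None

    @property
    def codon_index(self) -> int:
        return self.cds_pos // 3

    @property
    def codon_pos(self) -> int:
        return self.cds_pos % 3

    def __post_init__(self) -> None:
        if self.cds_pos < 0:
            raise DataError(f"negative CDS position for site in {self.gene_id}")
        if self.level is not None and not (0.0 <= self.level <= 1.0):
            raise DataError(f"editing level {self.level} outside [0, 1]")


@dataclass(frozen=True)
class Snp:
    """A biallelic single-nucleotide polymorphism in CDS coordinates."""

    gene_id: str
    cds_pos: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        for b in (self.ref_base, self.alt_base):
            if b not in NUCLEOTIDES:
                raise DataError(f"SNP base {b!r} not in ACGT")
        if self.ref_base == self.alt_base:
            raise DataError("SNP ref and alt bases are identical")

    @property
    def codon_index(self) -> int:
        return self.cds_pos // 3

    @property
    def codon_pos(self) -> int:
        return self.cds_pos % 3


@dataclass
class SpeciesDataset:
    """All per-species inputs: genes, editing sites, and (optionally) SNPs."""

    species_id: str
    genes: dict[str, Gene] = field(default_factory=dict)
    sites: list[EditingSite] = field(default_factory=list)
    snps: list[Snp] = field(default_factory=list)

    def add_gene(self, gene: Gene) -> None:
        if gene.gene_id in self.genes:
            raise DataError(f"duplicate gene id {gene.gene_id!r}")
        self.genes[gene.gene_id] = gene

    def add_site(self, site: EditingSite) -> None:
        gene = self.genes.get(site.gene_id)
        if gene is None:
            raise DataError(f"site references unknown gene {site.gene_id!r}")
        if site.cds_pos >= len(gene.cds):
            raise DataError(
                f"site position {site.cds_pos} beyond CDS of {site.gene_id}"
            )
        if gene.cds[site.cds_pos] != "A":
            raise DataError(
                f"site at {site.gene_id}:{site.cds_pos} is on "
                f"{gene.cds[site.cds_pos]!r}, not 'A'"
            )
        self.sites.append(site)

    def add_snp(self, snp: Snp) -> None:
        gene = self.genes.get(snp.gene_id)
        if gene is None:
            raise DataError(f"SNP references unknown gene {snp.gene_id!r}")
        if snp.cds_pos >= len(gene.cds):
            raise DataError(f"SNP position {snp.cds_pos} beyond CDS of {snp.gene_id}")
        if gene.cds[snp.cds_pos] != snp.ref_base:
            raise DataError(
                f"SNP REF {snp.ref_base} mismatches CDS base "
                f"{gene.cds[snp.cds_pos]} at {snp.gene_id}:{snp.cds_pos}"
            )
        self.snps.append(snp)

    # -- lookup helpers -------------------------------------------------

    def edited_positions(self, gene_id: str) -> set[int]:
        return {s.cds_pos for s in self.sites if s.gene_id == gene_id}

    def sites_by_gene(self) -> dict[str, list[EditingSite]]:
        out: dict[str, list[EditingSite]] = {}
        for s in self.sites:
            out.setdefault(s.gene_id, []).append(s)
        return out

    def snps_by_gene(self) -> dict[str, list[Snp]]:
        out: dict[str, list[Snp]] = {}
        for s in self.snps:
            out.setdefault(s.gene_id, []).append(s)
        return out

    def edited_gene_ids(self) -> set[str]:
        """Genes carrying at least one editing site."""
        return {s.gene_id for s in self.sites}

    def validate(self) -> None:
        """Re-assert the dataset-wide invariants (every site sits on 'A', etc.)."""
        for s in self.sites:
            gene = self.genes[s.gene_id]
            assert gene.cds[s.cds_pos] == "A"
        for v in self.snps:
            gene = self.genes[v.gene_id]
            assert gene.cds[v.cds_pos] == v.ref_base


def dataset_from_genes(species_id: str, genes: Iterable[Gene]) -> SpeciesDataset:
    ds = SpeciesDataset(species_id=species_id)
    for g in genes:
        ds.add_gene(g)
    return ds
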