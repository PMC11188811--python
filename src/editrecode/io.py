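"""Readers and writers for the formats the pipeline touches.

FASTA (CDS and protein) goes through Biopython's SeqIO. Editing-site lists
are TSV with 1-based positions. SNPs come as a minimal VCF v4 subset in
which CHROM holds the gene id and POS is the 1-based position on the CDS
(the upstream convention for CDS-space SNP tables), or as an equivalent
TSV; both share one parser because the VCF subset is column-oriented.

Record-level problems (bad CDS, site not on an adenosine, REF mismatch) are
logged and counted, never fatal; structural problems (duplicate ids,
malformed rows) raise :class:`~editrecode.datamodel.DataError`.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .datamodel import (
    CdsValidationError,
    DataError,
    EditingSite,
    Gene,
    Snp,
    SpeciesDataset,
)
from .genetics import revcomp

logger = logging.getLogger(__name__)


def read_strand_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping gene id -> strand ('+' or '-')."""
    table: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2 or parts[1] not in {"+", "-"}:
            raise DataError(f"{path}:{lineno}: malformed strand-table row {line!r}")
        table[parts[0]] = parts[1]
    return table


def read_cds_fasta(
    path: str | Path,
    species_id: str,
    strand_table: Optional[dict[str, str]] = None,
) -> SpeciesDataset:
    """Read CDS FASTA into a :class:`SpeciesDataset`, normalizing to sense strand.

    Records whose gene is annotated on the '-' genome strand are
    reverse-complemented on ingestion so that edited adenosines are 'A'
    everywhere downstream. Records failing CDS validation are logged,
    counted in ``dataset.rejections`` and skipped.
    """
    ds = SpeciesDataset(species_id=species_id)
    rejections: Counter[str] = Counter()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        strand = (strand_table or {}).get(rec.id, "+")
        if strand == "-":
            seq = revcomp(seq)
        try:
            gene = Gene(gene_id=rec.id, species_id=species_id, cds=seq,
                        genome_strand=strand)
        except CdsValidationError as exc:
            logger.warning("rejected CDS record: %s", exc)
            rejections["invalid_cds"] += 1
            continue
        ds.add_gene(gene)  # duplicate ids raise DataError (hard)
    ds.rejections = rejections  # type: ignore[attr-defined]
    return ds


def read_sites_tsv(path: str | Path, dataset: SpeciesDataset) -> Counter:
    """Attach editing sites from a TSV (gene_id, position 1-based[, level]).

    Returns the counter of rejected rows by reason. Malformed rows are hard
    errors naming the line.
    """
    rejections: Counter[str] = Counter()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise DataError(f"{path}:{lineno}: expected >=2 columns, got {line!r}")
        gene_id = parts[0]
        try:
            pos1 = int(parts[1])
            level = float(parts[2]) if len(parts) > 2 and parts[2] != "" else None
        except ValueError as exc:
            raise DataError(f"{path}:{lineno}: malformed row: {exc}") from exc
        if gene_id not in dataset.genes:
            logger.warning("%s:%d: unknown gene %r, site skipped", path, lineno, gene_id)
            rejections["unknown_gene"] += 1
            continue
        site = EditingSite(gene_id=gene_id, cds_pos=pos1 - 1, level=level)
        try:
            dataset.add_site(site)
        except DataError as exc:
            logger.warning("%s:%d: %s", path, lineno, exc)
            rejections["not_adenosine"] += 1
    return rejections


def read_snps(path: str | Path, dataset: SpeciesDataset) -> Counter:
    """Attach SNPs from a minimal VCF (CHROM=gene id, POS 1-based on CDS) or TSV.

    Multi-allelic ALT fields are split into one biallelic record per
    alternate. Rows whose REF mismatches the CDS are logged and skipped.
    """
    rejections: Counter[str] = Counter()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) >= 5 and not parts[2].isdigit():
            # VCF layout: CHROM POS ID REF ALT ...
            gene_id, pos_s, _id, ref, alt = parts[:5]
        elif len(parts) >= 4:
            # TSV layout: gene_id pos ref alt
            gene_id, pos_s, ref, alt = parts[:4]
        else:
            raise DataError(f"{path}:{lineno}: unrecognized SNP row {line!r}")
        try:
            pos1 = int(pos_s)
        except ValueError as exc:
            raise DataError(f"{path}:{lineno}: malformed position: {exc}") from exc
        if gene_id not in dataset.genes:
            logger.warning("%s:%d: unknown gene %r, SNP skipped", path, lineno, gene_id)
            rejections["unknown_gene"] += 1
            continue
        for alt_base in alt.split(","):
            try:
                snp = Snp(gene_id=gene_id, cds_pos=pos1 - 1,
                          ref_base=ref.upper(), alt_base=alt_base.upper())
                dataset.add_snp(snp)
            except DataError as exc:
                logger.warning("%s:%d: %s", path, lineno, exc)
                rejections["ref_mismatch"] += 1
    return rejections


# ---------------------------------------------------------------------------
# writers (all tab-separated UTF-8 with a commented header line)
# ---------------------------------------------------------------------------


def write_cds_fasta(dataset: SpeciesDataset, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(g.cds), id=g.gene_id, description="")
        for g in sorted(dataset.genes.values(), key=lambda g: g.gene_id)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_sites_tsv(dataset: SpeciesDataset, path: str | Path) -> None:
    lines = ["#gene_id\tposition_1based\tlevel"]
    for s in sorted(dataset.sites, key=lambda s: (s.gene_id, s.cds_pos)):
        level = "" if s.level is None else f"{s.level:g}"
        lines.append(f"{s.gene_id}\t{s.cds_pos + 1}\t{level}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_snps_vcf(dataset: SpeciesDataset, path: str | Path) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=editrecode (CHROM = gene id, POS = 1-based CDS position)",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for v in sorted(dataset.snps, key=lambda v: (v.gene_id, v.cds_pos, v.alt_base)):
        lines.append(
            f"{v.gene_id}\t{v.cds_pos + 1}\t.\t{v.ref_base}\t{v.alt_base}\t.\t.\t."
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_dataset(dataset: SpeciesDataset, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA + sites TSV (+ VCF if SNPs present) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sp = dataset.species_id
    paths = {
        "cds": outdir / f"{sp}.cds.fasta",
        "sites": outdir / f"{sp}.sites.tsv",
    }
    write_cds_fasta(dataset, paths["cds"])
    write_sites_tsv(dataset, paths["sites"])
    if dataset.snps:
        paths["snps"] = outdir / f"{sp}.snps.vcf"
        write_snps_vcf(dataset, paths["snps"])
    return paths


def read_dataset(
    species_id: str,
    cds_path: str | Path,
    sites_path: Optional[str | Path] = None,
    snps_path: Optional[str | Path] = None,
    strand_table_path: Optional[str | Path] = None,
) -> SpeciesDataset:
    """Convenience loader used by the CLI: FASTA [+ sites TSV] [+ SNP VCF/TSV]."""
    strands = read_strand_table(strand_table_path) if strand_table_path else None
    ds = read_cds_fasta(cds_path, species_id, strand_table=strands)
    if sites_path:
        read_sites_tsv(sites_path, ds)
    if snps_path:
        read_snps(snps_path, ds)
    return ds
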