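"""Protein-guided ortholog pairing, codon alignment, and CDS liftover.

Orthologous CDS pairs are compared through a global protein alignment
(Needleman–Wunsch with affine gaps, BLOSUM62 by default) that is then
back-translated onto the CDSs: each aligned amino-acid column becomes a
codon column, so a protein gap expands to a codon gap of width 3 and the
within-codon offset of any CDS position is preserved across species. That
codon alignment is the liftover used to ask "what sits at the orthologous
position in the other species?".

Highly conserved coding genes — the regime this pipeline targets — make
the ortholog search and alignment robust to scoring details; parameters
are nevertheless exposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .datamodel import Gene
from .genetics import AMINO_ACIDS

logger = logging.getLogger(__name__)

_ALLOWED = AMINO_ACIDS | {"X"}


def make_aligner(
    matrix: str = "BLOSUM62", gap_open: float = 10.0, gap_extend: float = 1.0
) -> Align.PairwiseAligner:
    """Global affine-gap aligner: a gap of length L costs open + extend*(L-1)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


@dataclass(frozen=True)
class ProteinAlignment:
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        assert len(self.aligned_a) == len(self.aligned_b)


def global_protein_align(
    seq_a: str,
    seq_b: str,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> ProteinAlignment:
    """Optimal global alignment of two protein sequences.

    The traceback among co-optimal alignments is the first of Biopython's
    deterministic enumeration, so results are reproducible run to run.
    """
    for name, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not seq:
            raise ValueError(f"{name} is empty")
        bad = set(seq) - _ALLOWED
        if bad:
            raise ValueError(f"{name} contains non-amino-acid characters {sorted(bad)}")
    if aligner is None:
        aligner = make_aligner()
    aln = next(iter(aligner.align(seq_a, seq_b)))
    return ProteinAlignment(aligned_a=str(aln[0]), aligned_b=str(aln[1]),
                            score=float(aln.score))


def pick_ortholog(
    query_protein: str,
    candidates: Mapping[str, str],
    aligner: Optional[Align.PairwiseAligner] = None,
) -> tuple[str, float]:
    """Best-scoring candidate under global alignment; ties break to the
    lexicographically smaller id (and are logged)."""
    if not candidates:
        raise ValueError("empty candidate set")
    if aligner is None:
        aligner = make_aligner()
    scores = {
        cid: aligner.score(query_protein, cseq) for cid, cseq in candidates.items()
    }
    best = max(scores.values())
    winners = sorted(cid for cid, s in scores.items() if s == best)
    if len(winners) > 1:
        logger.warning(
            "ortholog tie at score %.1f among %s; taking %r",
            best, winners, winners[0],
        )
    return winners[0], best


@dataclass
class CodonAlignment:
    """Codon-level view of a protein alignment over two CDSs.

    ``columns[k] = (ia, ib)`` gives the codon index of each species at
    aligned column k, or ``None`` where that species has a gap. Positions
    in a terminal stop codon are outside the alignment and never map.
    """

    cds_a: str
    cds_b: str
    columns: list[tuple[Optional[int], Optional[int]]]

    def __post_init__(self) -> None:
        self._a_to_col = {ia: k for k, (ia, _) in enumerate(self.columns) if ia is not None}
        self._b_to_col = {ib: k for k, (_, ib) in enumerate(self.columns) if ib is not None}

    def map_cds_position(self, pos_in_a: int) -> Optional[int]:
        """Lift a CDS position of species A to species B (None if unmapped)."""
        if not (0 <= pos_in_a < len(self.cds_a)):
            raise ValueError(f"position {pos_in_a} outside CDS (len {len(self.cds_a)})")
        col = self._a_to_col.get(pos_in_a // 3)
        if col is None:
            return None
        ib = self.columns[col][1]
        if ib is None:
            return None
        return 3 * ib + pos_in_a % 3

    def map_b_to_a(self, pos_in_b: int) -> Optional[int]:
        if not (0 <= pos_in_b < len(self.cds_b)):
            raise ValueError(f"position {pos_in_b} outside CDS (len {len(self.cds_b)})")
        col = self._b_to_col.get(pos_in_b // 3)
        if col is None:
            return None
        ia = self.columns[col][0]
        if ia is None:
            return None
        return 3 * ia + pos_in_b % 3

    def codon_pairs(self):
        """Yield (codon_index_a, codon_index_b, codon_a, codon_b) for every
        gap-free column."""
        for ia, ib in self.columns:
            if ia is None or ib is None:
                continue
            yield ia, ib, self.cds_a[3 * ia : 3 * ia + 3], self.cds_b[3 * ib : 3 * ib + 3]

    def aligned_codon_rows(self) -> tuple[str, str]:
        """Gapped codon-level strings (gap codon = '---'), for FASTA export."""
        row_a, row_b = [], []
        for ia, ib in self.columns:
            row_a.append("---" if ia is None else self.cds_a[3 * ia : 3 * ia + 3])
            row_b.append("---" if ib is None else self.cds_b[3 * ib : 3 * ib + 3])
        return "".join(row_a), "".join(row_b)


def backtranslate(
    protein_alignment: ProteinAlignment, cds_a: str, cds_b: str
) -> CodonAlignment:
    """Expand a protein alignment to a codon alignment of the two CDSs.

    The CDSs may carry a terminal stop codon; it is outside the aligned
    region. Raises ``ValueError`` naming the first discordant residue if a
    protein row is not the translation of its CDS.
    """
    from .genetics import translate_cds

    for label, row, cds in (("a", protein_alignment.aligned_a, cds_a),
                            ("b", protein_alignment.aligned_b, cds_b)):
        degapped = row.replace("-", "")
        aa = translate_cds(cds)
        prot = aa[:-1] if aa.endswith("*") else aa
        if degapped != prot:
            for i, (x, y) in enumerate(zip(degapped, prot)):
                if x != y:
                    raise ValueError(
                        f"protein row {label} mismatches CDS translation at "
                        f"residue {i}: {x!r} != {y!r}"
                    )
            raise ValueError(
                f"protein row {label} length {len(degapped)} mismatches "
                f"translation length {len(prot)}"
            )

    columns: list[tuple[Optional[int], Optional[int]]] = []
    ia = ib = 0
    for ca, cb in zip(protein_alignment.aligned_a, protein_alignment.aligned_b):
        col_a = col_b = None
        if ca != "-":
            col_a, ia = ia, ia + 1
        if cb != "-":
            col_b, ib = ib, ib + 1
        columns.append((col_a, col_b))
    return CodonAlignment(cds_a=cds_a, cds_b=cds_b, columns=columns)


def align_genes(
    gene_a: Gene, gene_b: Gene, aligner: Optional[Align.PairwiseAligner] = None
) -> CodonAlignment:
    """Protein-align two genes and back-translate to a codon alignment."""
    pa = global_protein_align(gene_a.protein, gene_b.protein, aligner=aligner)
    return backtranslate(pa, gene_a.cds, gene_b.cds)


def write_alignment_fasta(
    codon_alignment: CodonAlignment,
    id_a: str,
    id_b: str,
    path,
    view: str = "codon",
) -> None:
    """Write the aligned pair as FASTA, codon view ('---' gaps) or protein view."""
    if view == "codon":
        row_a, row_b = codon_alignment.aligned_codon_rows()
    else:
        from .genetics import CODON_TO_AA

        def protein_row(row: str) -> str:
            return "".join(
                "-" if row[i : i + 3] == "---" else CODON_TO_AA[row[i : i + 3]]
                for i in range(0, len(row), 3)
            )

        ra, rb = codon_alignment.aligned_codon_rows()
        row_a, row_b = protein_row(ra), protein_row(rb)
    text = f">{id_a}\n{row_a}\n>{id_b}\n{row_b}\n"
    from pathlib import Path

    Path(path).write_text(text, encoding="utf-8")
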