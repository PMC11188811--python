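"""Genetic-code helpers shared across the package.

All coding-sequence analysis uses the standard nuclear genetic code
(NCBI table 1); stops are represented by ``'*'``.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable
from Bio.Seq import Seq

NUCLEOTIDES = "ACGT"
_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, with '*' for the three stop codons
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(_STANDARD.stop_codons)
SENSE_CODONS = tuple(sorted(c for c in CODON_TO_AA if c not in STOP_CODONS))

#: the 20 amino acids plus the ambiguity code accepted by the aligner
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: purine/pyrimidine partners for transition-biased mutation models
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return str(Seq(seq).reverse_complement())


@lru_cache(maxsize=None)
def translate_cds(cds: str) -> str:
    """Translate a CDS (length divisible by 3) codon by codon; stops become '*'."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return "".join(CODON_TO_AA[cds[i : i + 3]] for i in range(0, len(cds), 3))


def codon_of(cds: str, cds_pos: int) -> str:
    """The codon containing 0-based position ``cds_pos``."""
    start = 3 * (cds_pos // 3)
    return cds[start : start + 3]
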