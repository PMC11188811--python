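"""Consequence annotation of A→G substitution at every adenosine of a CDS.

A-to-I editing presents an inosine that the ribosome reads as guanosine, so
the consequence of editing an adenosine is exactly the consequence of an
A→G substitution in its codon. This module classifies that change under
the standard nuclear code and defines the "recoding type" comparison key —
the ordered amino-acid pair ``"X>Y"`` — that downstream conservation
analysis uses to decide whether two species' edits recode the same way.

Stop-affecting changes are classified separately (``stop_gain``,
``stop_loss``, ``stop_retained``) and contaminate neither the synonymous
nor the nonsynonymous tally.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from .datamodel import Gene
from .genetics import CODON_TO_AA, NUCLEOTIDES


class ConsequenceClass(enum.Enum):
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    STOP_RETAINED = "stop_retained"


@dataclass(frozen=True)
class RecodingEvent:
    """The codon change induced by A→G at one codon position."""

    pre_codon: str
    post_codon: str
    pre_aa: str
    post_aa: str
    codon_pos: int


def classify_change(pre_aa: str, post_aa: str) -> ConsequenceClass:
    """Classify a single-codon amino-acid change; stops are '*'."""
    if pre_aa == "*" and post_aa == "*":
        return ConsequenceClass.STOP_RETAINED
    if pre_aa == "*":
        return ConsequenceClass.STOP_LOSS
    if post_aa == "*":
        return ConsequenceClass.STOP_GAIN
    if pre_aa == post_aa:
        return ConsequenceClass.SYNONYMOUS
    return ConsequenceClass.NONSYNONYMOUS


def _build_a2g_table() -> dict[tuple[str, int], tuple[ConsequenceClass, RecodingEvent]]:
    table = {}
    for b1 in NUCLEOTIDES:
        for b2 in NUCLEOTIDES:
            for b3 in NUCLEOTIDES:
                codon = b1 + b2 + b3
                for pos in range(3):
                    if codon[pos] != "A":
                        continue
                    post = codon[:pos] + "G" + codon[pos + 1 :]
                    ev = RecodingEvent(codon, post, CODON_TO_AA[codon],
                                       CODON_TO_AA[post], pos)
                    table[(codon, pos)] = (classify_change(ev.pre_aa, ev.post_aa), ev)
    return table


#: all 48 (codon, adenosine-position) combinations, precomputed
_A2G = _build_a2g_table()


def annotate_a_to_g(codon: str, codon_pos: int) -> tuple[ConsequenceClass, RecodingEvent]:
    """Consequence of editing the adenosine at ``codon_pos`` of ``codon``.

    Raises ``ValueError`` if the position does not hold an 'A' (a caller bug,
    since editing sites are adenosines by definition).
    """
    key = (codon, codon_pos)
    if key not in _A2G:
        if len(codon) != 3 or set(codon) - set(NUCLEOTIDES):
            raise ValueError(f"not a DNA codon: {codon!r}")
        raise ValueError(f"codon {codon} has no 'A' at position {codon_pos}")
    return _A2G[key]


def recoding_type(event: RecodingEvent) -> str:
    """Canonical ``"X>Y"`` label of a nonsynonymous recoding event.

    Two events are "the same recoding type" iff their labels are equal,
    regardless of the underlying codons.
    """
    if classify_change(event.pre_aa, event.post_aa) is not ConsequenceClass.NONSYNONYMOUS:
        raise ValueError(
            f"recoding type is defined only for nonsynonymous events "
            f"({event.pre_codon}>{event.post_codon} is not)"
        )
    return f"{event.pre_aa}>{event.post_aa}"


@dataclass(frozen=True)
class AdenosineAnnotation:
    """One adenosine of a CDS with its A→G consequence."""

    cds_pos: int
    codon_index: int
    codon_pos: int
    consequence: ConsequenceClass
    event: RecodingEvent
    in_terminal_stop: bool


def enumerate_adenosine_sites(gene: Gene) -> list[AdenosineAnnotation]:
    """Annotate every 'A' of the CDS, in positional order.

    Adenosines in the terminal stop codon are annotated but flagged so
    set-builders can exclude them.
    """
    out: list[AdenosineAnnotation] = []
    coding_len = gene.coding_length
    for pos, base in enumerate(gene.cds):
        if base != "A":
            continue
        codon_index, codon_pos = pos // 3, pos % 3
        codon = gene.codon(codon_index)
        cls, ev = annotate_a_to_g(codon, codon_pos)
        out.append(
            AdenosineAnnotation(pos, codon_index, codon_pos, cls, ev,
                                in_terminal_stop=pos >= coding_len)
        )
    return out


def iter_dataset_adenosines(dataset) -> Iterator[tuple[str, AdenosineAnnotation]]:
    for gene_id in sorted(dataset.genes):
        for ann in enumerate_adenosine_sites(dataset.genes[gene_id]):
            yield gene_id, ann


def write_adenosine_annotation_tsv(dataset, path: str | Path) -> int:
    """Per-gene annotation TSV; returns the number of rows written."""
    lines = ["#gene_id\tpos_1based\tcodon\tcodon_pos\tclass\trecoding_type"]
    n = 0
    for gene_id, ann in iter_dataset_adenosines(dataset):
        rtype = (
            f"{ann.event.pre_aa}>{ann.event.post_aa}"
            if ann.consequence is ConsequenceClass.NONSYNONYMOUS
            else ""
        )
        lines.append(
            f"{gene_id}\t{ann.cds_pos + 1}\t{ann.event.pre_codon}\t"
            f"{ann.codon_pos}\t{ann.consequence.value}\t{rtype}"
        )
        n += 1
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    return n
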