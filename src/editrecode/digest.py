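"""In-silico tryptic digest and MS detectability of recoded residues.

Trypsin cleaves after lysine (K) or arginine (R), so a residue of interest
sits in a fixed "tryptic interval" between consecutive K/R positions. MS
pipelines typically identify peptides of 6–30 amino acids; a recoded
residue inside a longer (or shorter) interval escapes detection however
deeply the sample is measured. This module produces the zero-missed
fragments (which tile the protein exactly), optional missed-cleavage
concatenations, and a per-site detectability verdict under a length
window.

By default cleavage is unconditional after K/R; ``strict_trypsin=True``
adds the classical "not before proline" exception.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .genetics import AMINO_ACIDS

_ALLOWED = AMINO_ACIDS | {"X"}


@dataclass(frozen=True)
class Peptide:
    """A digest fragment, as half-open 0-based protein coordinates."""

    sequence: str
    start: int
    end: int
    missed: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


def _cut_points(protein: str, strict_trypsin: bool) -> list[int]:
    cuts = [0]
    for i, aa in enumerate(protein[:-1]):
        if aa in "KR" and not (strict_trypsin and protein[i + 1] == "P"):
            cuts.append(i + 1)
    cuts.append(len(protein))
    return cuts


def cleave(
    protein: str, missed_cleavages: int = 0, strict_trypsin: bool = False
) -> list[Peptide]:
    """All digest fragments with up to ``missed_cleavages`` internal K/R.

    Zero-missed fragments tile the protein exactly; with m missed
    cleavages every concatenation of <= m+1 adjacent fragments is also
    emitted. Fragments are ordered by start position, then span.
    """
    if not protein:
        raise ValueError("empty protein")
    bad = set(protein) - _ALLOWED
    if bad:
        raise ValueError(f"non-amino-acid characters {sorted(bad)}")
    cuts = _cut_points(protein, strict_trypsin)
    out: list[Peptide] = []
    for i in range(len(cuts) - 1):
        for m in range(missed_cleavages + 1):
            j = i + 1 + m
            if j >= len(cuts):
                break
            start, end = cuts[i], cuts[j]
            out.append(Peptide(protein[start:end], start, end, missed=m))
    out.sort(key=lambda p: (p.start, p.end))
    return out


@dataclass(frozen=True)
class DetectabilityReport:
    """Whether the fragment(s) containing a residue fit the MS length window."""

    site_aa_pos: int
    peptide: Peptide
    detectable: bool
    min_len: int
    max_len: int
    missed_cleavages: int


def site_detectability(
    protein: str,
    site_aa_pos: int,
    min_len: int = 6,
    max_len: int = 30,
    missed_cleavages: int = 0,
    strict_trypsin: bool = False,
) -> DetectabilityReport:
    """Can the residue at ``site_aa_pos`` appear in an identifiable peptide?

    The reported peptide is the zero-missed tryptic interval containing the
    site; with missed cleavages allowed, the site is detectable if ANY
    emitted fragment containing it fits [min_len, max_len].
    """
    if not (0 <= site_aa_pos < len(protein)):
        raise ValueError(f"site position {site_aa_pos} outside protein")
    fragments = cleave(protein, missed_cleavages=missed_cleavages,
                       strict_trypsin=strict_trypsin)
    containing = [p for p in fragments if p.start <= site_aa_pos < p.end]
    zero_missed = next(p for p in containing if p.missed == 0)
    detectable = any(min_len <= p.length <= max_len for p in containing)
    return DetectabilityReport(
        site_aa_pos=site_aa_pos, peptide=zero_missed, detectable=detectable,
        min_len=min_len, max_len=max_len, missed_cleavages=missed_cleavages,
    )


def write_detectability_tsv(
    reports: Sequence[tuple[str, DetectabilityReport]], path: str | Path
) -> None:
    lines = [
        "#protein_id\tsite_aa_pos_1based\tfragment_start_1based\tfragment_end\t"
        "fragment_length\tdetectable\tmin_len\tmax_len\tmissed_cleavages"
    ]
    for pid, r in reports:
        lines.append(
            f"{pid}\t{r.site_aa_pos + 1}\t{r.peptide.start + 1}\t{r.peptide.end}\t"
            f"{r.peptide.length}\t{str(r.detectable).lower()}\t{r.min_len}\t"
            f"{r.max_len}\t{r.missed_cleavages}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
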