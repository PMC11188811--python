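# editrecode

Comparative analysis of A-to-I RNA editing **recoding conservation** across
species.

## The problem

Adenosine-to-inosine (A-to-I) RNA editing in coding sequence is read as an
A→G change by the ribosome, so an edited adenosine can "recode" the
protein. An orthologous adenosine edited in two species is *conserved
editing* — but if a DNA substitution elsewhere in the codon fixed in one
lineage, the same edit recodes **different** amino acids in the two
species (e.g. AGT Ser>Gly in one, ACT Thr>Ala in the other): *conserved
editing with non-conserved recoding*. Whether such sites are suppressed or
favoured by selection is a question about the function of recoding itself.

`editrecode` provides the full pipeline to ask that question from CDS
FASTA files, editing-site lists, and population SNP tables:

* per-adenosine A→G consequence annotation under the standard genetic code;
* protein-guided ortholog pairing, codon alignment (Needleman–Wunsch with
  affine gaps, BLOSUM62), and cross-species CDS-position liftover;
* conserved-editing detection and recoding-type classification;
* observed-vs-expected enrichment against a genome-wide unedited-adenosine
  control, tested with a one-sided Fisher exact test computed in log space;
* codon-level co-occurrence of nonsynonymous SNPs with conserved recoding
  sites (the intra-species view of the same selection question);
* a clade-wide phylogenetic screen for candidate species in which a
  reference-conserved recoding site sits in a diverged codon;
* in-silico tryptic digest (cleavage after K/R) with a peptide-length
  window explaining when recoded peptides escape MS detection;
* a synthetic editome-evolution generator with exact truth tables, so
  every stage is testable with no downloads.

## The statistic at the core

For editing sites nonsynonymous in both species, let k of n conserved
site pairs show different recoding types. For the control, census the
aligned, unedited adenosines in edited genes whose A→G change would be
nonsynonymous: of N such adenosines, K sit in codon pairs encoding
different amino acids. The comparison is the 2×2 table

|            | different AA / type | same |
|------------|--------------------:|-----:|
| edited     | k                   | n−k  |
| unedited   | K                   | N−K  |

with observed fraction k/n, expected fraction K/N, the sample odds ratio,
and the one-sided (enrichment) Fisher exact p — the hypergeometric upper
tail Pr[X ≥ k], accumulated in log space so that million-scale control
denominators remain exact. The SNP analysis uses the same machinery with
"carries a nonsynonymous SNP at a non-edited codon position" as the
special outcome.

## Worked example

```python
from editrecode import PairwiseRecodingAnalysis, SimParams, simulate_pair

params = SimParams(seed=42, snp_enrichment_factor=5.0)
ds_a, ds_b, truth = simulate_pair(params)
result = PairwiseRecodingAnalysis(ds_a, ds_b).fit()
print(result.summary())
```

prints

```
Pairwise recoding-conservation analysis: speciesA vs speciesB
  conserved-editing site pairs: 484
    conserved_recoding: 480
    non_conserved_recoding: 4
    not_nonsynonymous_in_both: 0
  sites discarded: a_not_conserved=30, not_edited_in_b=150
  control census: 451 different-AA of 8669 conserved unedited adenosines
  non-conserved recoding speciesA vs speciesB: observed 4/484 = 0.826%, expected 451/8669 = 5.20%, OR = 0.152, one-sided Fisher p = 1
  nonsynonymous SNPs in conserved-recoding codons (speciesA): observed 52/480 = 10.8%, expected 177/6940 = 2.55%, OR = 4.64, one-sided Fisher p = 3.29e-16
```

Reading the output: the simulator planted 484 conserved nonsynonymous
editing sites of which 4 recode differently, and the pipeline recovered
exactly those counts (0.826% observed). The control fraction (5.20%)
reflects the simulator's neutral divergence, which is far higher than the
selective constraint real edited genes experience — the generator models
patterns, not dN/dS. The five-fold planted SNP enrichment in
conserved-recoding codons is detected (OR 4.64, p ≈ 3e-16).

The same analyses are available from the shell:

```bash
editrecode simulate --mode pair --seed 42 --out run/
editrecode pairwise --cds-a run/speciesA.cds.fasta --sites-a run/speciesA.sites.tsv \
    --cds-b run/speciesB.cds.fasta --sites-b run/speciesB.sites.tsv --out run/pairwise/
editrecode snp-enrich ... ; editrecode phylo-screen ... ; editrecode digest ...
```

Each run directory contains per-site TSVs, a `summary.json`, and a
`manifest.json` with input checksums, parameters, and discard tallies;
reruns are byte-identical.

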