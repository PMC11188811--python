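# Methods

## Model and definitions

A CDS is analysed in sense-strand space; strand handling (an edited site
is an A on the '+' genome strand, a T on '−') is applied once at FASTA
ingestion by reverse-complementing '−'-strand records, so every
downstream operation is strand-free. Internal coordinates are 0-based;
all file formats use 1-based positions (VCF/TSV convention).

A-to-I editing is modelled as an A→G substitution in the codon, because
inosine pairs as guanosine during translation. The consequence of editing
an adenosine is classified under the standard nuclear genetic code into
`synonymous`, `nonsynonymous`, or one of three stop-affecting classes
(`stop_gain`, `stop_loss`, `stop_retained`). Stop-affecting changes are
excluded from both the synonymous and the nonsynonymous tallies — their
handling in published genome-wide counts is rarely stated, so keeping them
separate lets either convention be reproduced. Adenosines in a terminal
stop codon are annotated but flagged, and all set-builders exclude them.

The *recoding type* of a nonsynonymous event is the ordered amino-acid
pair `"X>Y"`; two events are the same recoding type iff their labels are
equal, regardless of the underlying codons. A pair of orthologous edited
adenosines is classified as:

* `conserved_recoding` — nonsynonymous in both species, equal labels;
* `non_conserved_recoding` — nonsynonymous in both, different labels
  (the focal category: a substitution elsewhere in the codon changed the
  pre-edit amino acid);
* `not_nonsynonymous_in_both` — otherwise.

## Ortholog pairing, codon alignment and liftover

Proteins are aligned with global Needleman–Wunsch using affine gaps
(Biopython's `PairwiseAligner`; BLOSUM62, gap open 10, extend 1, all
configurable: a gap of length L costs open + extend·(L−1)). Among
co-optimal alignments the first of Biopython's deterministic enumeration
is taken, so runs are reproducible; optimal scores are verified against a
brute-force enumeration oracle in the test suite. Ortholog choice
(`pick_ortholog`) takes the candidate with the maximal global score, ties
broken to the lexicographically smaller id and logged — edited coding
genes in the flies this pipeline targets are strongly conserved, which
makes both the ortholog search and the alignment insensitive to scoring
details.

The protein alignment is back-translated onto the CDSs: each amino-acid
column becomes a codon column and each protein gap a width-3 codon gap, so
lifting a CDS position across species preserves its within-codon offset.
Codon columns with a gap in either species are excluded from all
"conserved" sets; sites falling in them are discarded with a reason code
that appears in every report. The high-level analyses pair genes by
shared id when the two datasets' id sets overlap (curated ortholog tables
and the simulator provide matched ids) and fall back to
best-global-score search otherwise.

## Control census and enrichment testing

The null for "how often do aligned codons around a conserved adenosine
encode different amino acids?" is the census of adenosines that are
(i) aligned gap-free at the same codon position in both species,
(ii) unedited in both, and (iii) nonsynonymous-if-edited. The
nonsynonymous requirement is applied in **both** species by default,
matching the symmetric definition used for the observed pairs; a
reference-species-only switch exists. The census is restricted to edited
genes to control for their higher conservation. Counting is per adenosine
on both the observed and the control side (a codon with two qualifying
adenosines contributes two entries); a per-codon mode exists for
sensitivity analysis.

Enrichment is tested with the one-sided Fisher exact test, alternative
"greater" (every comparison in this pipeline asks about
overrepresentation; two-sided is available behind a flag). The p-value is
the hypergeometric upper tail Pr[X ≥ k], computed as a log-sum-exp over
log-pmf terms (log-gamma based), which survives control denominators of
~1.3 million where naive factorials overflow. Degenerate margins return
p = 1 with a warning. Percentages in reports are printed with three
significant digits. Small-table p-values are validated against exact
rational enumeration to 1e-10 relative; at million-scale denominators the
implementation and an independent log-space survival-function route agree
to ~1e-9 relative, which is far below any decision threshold.

## SNP co-occurrence

SNP consequences are classified from the precomputed table of all 576
(codon, position, alternate) combinations. The observed census counts
conserved-recoding sites whose codon carries ≥1 nonsynonymous SNP at a
codon position *other than* the edited adenosine (several qualifying SNPs
still count the codon once; duplicate rows are idempotent). An option
includes SNPs on the edited A itself — the editing-abolishing class —
reported separately. The control universe counts codons in edited genes
that contain a qualifying unedited adenosine and are conserved between the
species; "conserved" defaults to identical encoded amino acid, with an
identical-codon mode available, since either reading is defensible. SNP
lists are used as supplied; an optional minor-allele filter defaults off.

## Phylogenetic candidate screen

Reference sites are the nonsynonymous editing sites of the primary
editome that are edited, adenosine-bearing, and nonsynonymous at the
orthologous position in every other reference editome. Each such site is
projected through a primary→target codon alignment onto every target
species of the clade and classified as `candidate` (adenosine retained,
different encoded amino acid — non-conserved recoding if the presumed
editing exists), `conserved_recoding`, `A_lost`, or `unalignable`.
Because editing-loss events are rare, retention of the adenosine is
treated as grounds to presume editing, but candidates are reported as
hypotheses — transcriptome confirmation is out of scope, and the status
field keeps that explicit. Trees are consumed as topology only (branch
lengths are ignored); the per-species summary follows tree leaf order,
with species missing from the tree appended after a warning.

## Tryptic digest detectability

Cleavage is unconditional after K or R by default; the classical
"no cleavage before proline" exception is available behind
`strict_trypsin` but off by default, because the published interval
arithmetic this module reproduces uses the unconditional rule.
Zero-missed fragments tile the protein exactly; with m missed cleavages
all concatenations of ≤ m+1 adjacent fragments are emitted. A residue is
detectable if any fragment containing it has length within
[min_len, max_len], default [6, 30] — the range MS pipelines typically
identify. Mass computation, charge states and FDR are deliberately
absent; the module answers only the length-window feasibility question.

## Synthetic data generator

`simulate_pair` emulates the data regime of a sibling-species comparison:

* **Genome**: 60 genes of ~300 codons (Poisson lengths, minimum 50),
  uniform sense-codon usage, ATG start, TAA stop. This scales the real
  edited-gene universe down by roughly two orders of magnitude so the
  whole pipeline runs in seconds; counts, not fractions of the control
  census, are what the recovery tests compare.
* **Planted editing sites**: 480 conserved-recoding and 4
  non-conserved-recoding sites (the headline counts of the close-pair
  comparison), 150 species-specific and 30 adenosine-lost sites
  (roughly the scaled proportions of a ~2000-site editome of which half
  is conserved). Non-conserved sites receive a single non-A same-codon
  substitution in one random lineage that changes the amino acid while
  preserving the edited adenosine; adenosine-lost sites have the A
  replaced (transition preferred) in the second species.
* **Divergence**: per-site Bernoulli substitutions at rate 0.02 per
  lineage (sibling-species CDS divergence), transition:transversion
  weight 2. Stop-creating changes are resampled among remaining
  alternates so realized rates stay near nominal. No indel process is
  simulated — edited fly genes are strongly length-conserved — so
  alignments of simulated pairs are ungapped; gaps are exercised by
  hand-built alignments in the tests instead. Planted codons are
  protected from background substitution, which keeps the truth table
  exact at any noise level.
* **SNPs** (species A): each codon carries a nonsynonymous SNP at a
  non-adenosine position with probability 0.025 — multiplied by
  `snp_enrichment_factor` in codons hosting a planted conserved-recoding
  site — matching the density of a global fly population panel
  (~177k nonsynonymous SNPs over ~7M codons); synonymous SNPs are added
  per site at 0.016. Placement is restricted to positions with a
  nonsynonymous, stop-free alternate, so at factor 1 the observed and
  control per-codon hit probabilities are identical by construction and
  the estimated odds ratio is centred on 1 (verified across 50 seeds).
* **Determinism**: one root seed drives a hierarchy of numpy
  `SeedSequence` substreams (genes, planting, per-lineage mutation, SNPs,
  editing levels), so identical parameters give byte-identical outputs.

`simulate_clade` plants reference-conserved recoding sites in the common
ancestor, propagates sequences down the supplied topology (one
substream per branch, planted codons protected), and applies
amino-acid-changing adenosine-preserving substitutions (candidates) or
adenosine-removing substitutions (A-lost) in designated target species.
The default topology is a ladder of 18 targets between the first two and
the third reference species.

What passing the recovery tests shows — and does not show: the generator
produces the *configurations* the classifier must recognize, with exact
truth; it does not model codon-usage bias, dN/dS heterogeneity, indels,
editing-level variation with condition, or linkage between SNPs. Results
on real editomes additionally depend on ortholog-call quality and on the
completeness of the input site lists, which the pipeline takes as given.

## Numerical and degenerate-input choices

* Empty site lists or SNP-free inputs produce zero-count reports with
  p = 1, never errors; structural file problems (duplicate ids, malformed
  rows) are hard errors, record-level problems are logged, counted and
  skipped.
* Odds ratios use the plain sample estimator, reported as infinity when
  the control arm has zero special outcomes.
* Ortholog ties and species missing from the summary tree are resolved
  deterministically (lexicographic id; appended after ordered rows) and
  logged.
* CLI reruns on identical inputs are byte-identical; manifests record
  input SHA-256 checksums, parameters, and discard tallies.

## Known limitations

Site detection from raw reads, isoform selection (the longest-CDS choice
is assumed done upstream), multiple-sequence alignment (the clade screen
composes pairwise liftovers through the reference species),
ancestral-state reconstruction of editing gain/loss, population-genetic
statistics beyond counting, and MS spectral search are all out of scope.
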