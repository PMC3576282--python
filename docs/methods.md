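# Methods

## The synonymous-codon universe

All statistics are computed over the 59 codons of the standard nuclear
genetic code (NCBI table 1) that carry synonymous information: the three
stop codons and the single-codon amino acids Met (ATG) and Trp (TGG) are
excluded, leaving 18 amino acids each encoded by 2–6 codons. Six-codon
families (Leu, Ser, Arg) are treated as single groups, not split into
2-fold/4-fold sub-boxes: the unit of normalization is the amino acid.
`sc_set` is lexicographically ordered and every output vector uses a fixed
ordering (codons lexicographic; dinucleotide cells with A,C,G,T ordering;
third-position classes reported as NNA, NNT, NNC, NNG), so all TSV outputs
are bit-stable.

## Gene models

Gene structures are read from GFF3 CDS features grouped by the Parent chain
(CDS → mRNA → gene), with fallbacks to `gene_id`/`locus_tag` attributes; a
dialect knob can force a different grouping key. Coordinates stay 1-based
inclusive (the GFF3 convention) up to the single point of sequence slicing.
Where a gene has several transcripts, the **primary transcript** is the one
with the longest total CDS, ties broken by lexicographic transcript id —
a deterministic rule that needs no annotation-specific "canonical" tags.

The GFF3 phase column is read but never trusted: reading frame is
recomputed from segment lengths, because annotation phase errors are common
and the analysis depends on frame only through the assembled CDS.
Transcripts spanning several contigs or mixing strands cannot form a linear
CDS and are dropped (counted). Assembled CDS are validated — start ATG,
terminal TAA/TGA/TAG, no internal stop, length divisible by 3, length ≥ 6 —
and failures are *rejected with a coded reason* rather than repaired; no
silent coordinate surgery (e.g. extending a stop-less CDS by 3 bases) is
attempted. Codons containing non-ACGT bases are dropped individually; a
gene is rejected only when more than 10% (configurable) of its codons are
ambiguous, which preserves sample size without letting low-quality models
through.

## Split-codon exon attribution

A codon interrupted by an intron after its first nucleotide (phase-1
boundary) is attributed to the intron's 3′-adjacent exon; one interrupted
after its second nucleotide (phase-2) to the 5′-adjacent exon. Both rules,
plus the trivial unsplit case, reduce to *the exon containing the codon's
middle nucleotide*, which is how the implementation computes ownership in
one vectorized pass; the test suite checks this equivalence against a
literal nucleotide-walk implementation of the two rules on random gene
models.

Neighbour contexts (`next_first`, `prev_last`) are computed on the spliced
CDS, across intron junctions, because every statistic here is defined on
coding sequence. The terminal stop codon is outside the 59-codon set but
its first nucleotide is still a valid `next_first` for the penultimate
codon (and symmetrically the start codon's last base feeds `prev_last`):
nothing in the junction-pair definition excludes it, and keeping it
maximizes usable contexts.

## Statistics

Within a stratum (intron-number bin 0–9, exon-position cell for 2–10-exon
genes, or a whole genome):

* per-codon frequency = codon count / its amino-acid group total, undefined
  (NaN, never 0) when the group is unobserved;
* NNX frequency = count of codons with third nucleotide X / total count
  over the 59-codon set (the four values sum to 1);
* AT:GC ratio per amino acid = (A+T)-ending / (C+G)-ending counts, with
  zero denominators propagating as missing and excluded (and counted) in
  the 18-amino-acid mean;
* the four 16-cell context tables. The within-codon tables (second–third,
  first–second) divide by the stratum codon total. For the junction tables
  the natural denominator is ambiguous between "all 59-codon occurrences"
  and "occurrences possessing the relevant neighbour"; the default is the
  latter, so each 16-vector sums to 1 and is comparable across strata of
  different sizes, with `denominator="total"` restoring the former.

Counts are **pooled across genes** within a stratum before frequencies are
computed (the frequency definitions divide by stratum-level totals); a
per-gene-mean mode (`mean_profiles`) is provided for sensitivity analysis,
weighting genes equally instead of by codon count.

Trends against intron number use Spearman rank correlation by default —
only the direction of the relationship is of interest and the functional
form is unknown — with Pearson switchable. Statistics constant across bins,
or defined in fewer than 3 bins, are reported with NaN ρ rather than a
meaningless 0.

One structural caveat: the genetic code's box structure is not A↔T
symmetric (2-fold boxes pair T with C, and A with G), so genome-level
NNA = NNT is *not* expected even under fully symmetric mutation pressure;
the symmetry of `third_class_frequency` is therefore tested on counts
restricted to codons whose third-position mirror is a synonym.

## Shape classification

Exon-position profiles are labelled **cap** (∩) when the mean over
interstitial exons exceeds the mean of the first and last exon by more than
a tolerance, **cup** (∪) in the opposite case, **flat** within the
tolerance, and **mixed** when undefined (fewer than 3 exons, or missing
values). The tolerance is relative — by default 2% of the terminal mean —
so the label is invariant to positive rescaling of the statistic. Strict
invariance to adding a constant holds only at tolerance 0 (the band tracks
the terminal mean's magnitude); this is a deliberate trade-off, since the
statistics being classified are ratios and frequencies with a natural zero.

First-exon conservation is quantified as the coefficient of variation of a
statistic's value at each position class (first, interstitial, last) across
exon-total groups 2–10.

## Multivariate comparison

Per-genome feature matrices concatenate per-stratum statistics with
deterministic column ordering; strata empty in some genomes are imputed by
the column mean (count logged). Clustering is agglomerative with Euclidean
distance and complete linkage by default (both switchable) — the historical
"joining tree" style of analysis is an agglomerative similarity clustering,
not a phylogeny — with rows sorted by label first so the tree is invariant
to input order; trees are exported as Newick. PCA standardizes columns
(features mix frequencies and ratios of different scales), drops
zero-variance columns (counted), extracts two components, and applies a
varimax rotation to their loadings, since only the first two components are
plotted. Varimax is orthogonal, so the rotated loading pair stays
orthonormal and the total variance of the two components is conserved; a
fixed sign convention (largest-magnitude loading positive per component)
makes scores deterministic.

## The synthetic genome generator

The generator is the package's ground-truth instrument. It emulates the
three compositional structures the analysis is designed to detect, each
planted explicitly:

1. **Intron-number trend** — third-position class probabilities
   (pA, pT, pC, pG) are a linear function of intron count: default base
   (0.20, 0.20, 0.30, 0.30) with 0.02 per intron moving from C and G to A
   and T, i.e. genes run from mildly GC3-rich at 0 introns to strongly
   AT3-rich at 9 — the land-plant-like regime. Codons are drawn by class
   (renormalized over the classes each amino acid possesses) and uniformly
   within the (amino acid, class) cell.
2. **Exon-position effect** — `cap` (or `cup`) shifts half the effect size
   (default 0.10) from each of C,G to each of A,T (or back) for codons
   owned by interstitial exons only, planting arched profiles.
3. **Junction CpG depletion** — after drawing the codon stream, each
   junction where a C-ending codon precedes a G-initial codon keeps its C
   with probability κ and is otherwise synonymously converted to the
   T-ending codon of the same codon box (the deamination analogue; every
   C-ending codon in the standard code has a same-box T synonym, while the
   downstream G sits at a first position and cannot be changed
   synonymously). κ is derived analytically from the requested depletion
   factor d — κ = d(1−p_G)/(1−d·p_G), where p_G is the probability a codon
   starts with G, fixed by amino-acid composition (only Ala, Asp, Glu, Gly,
   Val have G-initial codons) — so that the post-process junction (C,G)
   cell equals d times the product of the junction marginals. At d < 1 the
   conversions also shift third-position composition from C to T, exactly
   as deamination does in real genomes; `expected_third_class_freq`
   accounts for this analytically and is the reference value the recovery
   tests compare against.

Amino acids are i.i.d. uniform over the 18 by default: identity matters to
no statistic except grouping, and uniform usage maximizes per-group counts
at small n. Exon boundaries are cut at arbitrary nucleotide offsets
(minimum-length guarantee plus a multinomial split of the remainder), so
split-codon phases 0/1/2 all occur. Introns are neutral GT…AG filler
(geometric length, minimum 20 nt) — a test scrambles all non-CDS bases and
asserts the codon records are unchanged. Half the genes are placed on the
minus strand; gene size defaults to ~30 codons per exon (Poisson, minimum
5). Everything is driven by one `numpy` Generator seed, and identical seeds
give byte-identical FASTA/GFF3/TSV.

What the generator does **not** emulate: codon autocorrelation, realistic
splice-site motifs or intron length distributions, amino-acid composition
bias, isochore structure, annotation errors (beyond what the validators
reject), or within-codon CpG depletion. Passing recovery tests therefore
demonstrates the estimators' correctness and power under clean conditions,
not robustness to the full messiness of real annotation.

## Problem sizes and numerical choices

The recovery analyses use 200 genes per intron bin (trend), 500 genes per
exon-total group 3–10 (shapes), ~50,000 codons (CpG factor), and 4 genomes
of 40 genes (multivariate) — sizes at which the planted effects sit many
standard errors above the decision thresholds while the full suite runs in
well under a minute. Frequency normalizations are asserted to 1e-12;
statistic-vs-oracle comparisons to 1e-12; varimax variance conservation to
1e-10. Undefined values propagate as NaN throughout and are never silently
zero-filled except by the documented column-mean imputation in the profile
matrix.

## Known limitations

* "Exon" here always means *coding segment*: UTR-only exons are invisible
  to a CDS-based analysis, so exon indices refer to coding exons.
* The per-gene-mean pooling mode is provided but the pooled mode is the
  default and the one exercised by the recovery suite.
* Rejected gene models are counted, not repaired; genomes with pervasive
  stop-exclusive CDS annotation will show high `no_stop` tallies and should
  be pre-processed.
* The dendrogram is a similarity clustering of codon-usage profiles;
  nothing about it is a phylogenetic estimate.
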