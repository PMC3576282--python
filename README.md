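# scubkit

Synonymous codon usage bias (SCUB) analysis stratified by gene architecture:
intron number and exon position.

## The problem

Synonymous codons — alternative codons encoding the same amino acid — are not
used uniformly, and in plant genomes the bias co-varies with gene structure:
genes with few introns tend to prefer C/G at the third codon position, while
intron-rich genes drift toward A/T; within a gene, interstitial exons differ
systematically from the first and last exon (arched, "cap"/"cup" profiles);
and the depletion of CpG dinucleotides at codon junctions links the bias to
methylation-driven C→T deamination. `scubkit` is a reusable pipeline for
measuring all of this from a genome FASTA plus GFF3 annotation, for
comparing genomes by clustering and ordination of their SCUB profiles, and —
because real genomes are large and their annotation messy — for generating
synthetic genomes with *planted* composition structure so that every stage
can be validated against known ground truth.

## What it computes

Statistics are defined over the 59-codon synonymous universe (64 codons
minus the three stops, ATG and TGG), covering 18 amino acids:

* **per-codon SC frequency** — count of a codon / count of all synonymous
  codons of its amino acid;
* **NNA / NNT / NNC / NNG** — frequency of codons with a given
  third-position nucleotide among all 59-codon occurrences (NNC + NNG is the
  classic GC3);
* **NNA/T : NNC/G ratio** — per amino acid, (A+T)-ending over (C+G)-ending
  counts, and its mean over the 18 amino acids;
* **dinucleotide context tables** (16 cells each) — within-codon
  second–third and first–second pairs, and the codon-junction pairs
  (third nucleotide | next codon's first) and (previous codon's last |
  first), used to probe CpG/CHG-context substitution;
* **stratification** — all of the above pooled per intron-number bin (0–9)
  or per (exon-total 2–10, exon-index) cell, with codons interrupted by an
  intron attributed to an exon by the split rule: a codon split after its
  first nucleotide belongs to the downstream exon, after its second to the
  upstream exon;
* **trend and shape analysis** — Spearman (or Pearson) correlation of any
  statistic against intron number; cap/cup/flat classification of
  exon-position profiles; first-exon conservation (coefficient of variation
  across exon-total groups);
* **multivariate comparison** — hierarchical clustering (Newick export) and
  PCA with varimax rotation of the first two components over per-genome
  profile matrices.

## Worked example

Simulate a 500-gene genome with a planted land-plant-like trend (third
position shifting from C/G toward A/T by 0.02 per intron), then run the
pipeline on the emitted FASTA + GFF3:

```python
from scubkit import (SyntheticSpec, generate_genome, read_fasta,
                     read_gff3_transcripts, select_primary_transcript,
                     extract_gene_models, assign_codons, filter_sc_records,
                     build_genetic_code, count_codons, compute_profile,
                     correlate_with_intron_number, stratify_by_intron)
from scubkit.scub_stats import merge_tables

spec = SyntheticSpec(n_genes={k: 50 for k in range(10)}, third_class_slope=0.02)
fasta, gff3, truth = generate_genome(spec, "demo", seed=1)

code = build_genetic_code()
genome = read_fasta(fasta)
transcripts, _ = read_gff3_transcripts(gff3)
models, rejections = extract_gene_models(
    select_primary_transcript(transcripts), genome)
print(f"{len(models)} gene models retained, rejections: {sum(rejections.values())}")

bins, _ = stratify_by_intron(models)
profiles = {}
for k, genes in bins.items():
    tables = [count_codons(filter_sc_records(assign_codons(m), code), code)
              for m in genes]
    profiles[k] = compute_profile(merge_tables(tables), code)

for k in (0, 3, 6, 9):
    f = profiles[k].third_class_freq
    print(k, profiles[k].n_codons, f.round(3).to_dict(),
          round(profiles[k].at_gc_ratio_mean, 3))
print(correlate_with_intron_number(profiles, which=("third_class", "at_gc_ratio")))
```

prints

```
500 gene models retained, rejections: 0
0 1485 {'NNA': 0.17, 'NNT': 0.241, 'NNC': 0.352, 'NNG': 0.237} 0.716
3 6051 {'NNA': 0.218, 'NNT': 0.316, 'NNC': 0.284, 'NNG': 0.183} 1.17
6 10616 {'NNA': 0.269, 'NNT': 0.38, 'NNC': 0.21, 'NNG': 0.141} 1.917
9 15212 {'NNA': 0.319, 'NNT': 0.445, 'NNC': 0.141, 'NNG': 0.095} 3.343
           rho  pvalue  n_bins
NNA        1.0     0.0      10
NNT        1.0     0.0      10
NNC       -1.0     0.0      10
NNG       -1.0     0.0      10
atgc_mean  1.0     0.0      10
```

i.e. the pipeline recovers the planted decline of NNC/NNG with intron number
(ρ = −1 across the ten bins) and the rising NNA/T : NNC/G mean ratio
(0.72 → 3.34), exactly the qualitative structure the simulation planted.

The same analyses are available from the shell:

```bash
scubkit simulate --out sim --seed 1 --genes-per-bin 50 --slope 0.02
scubkit extract  --fasta sim/genome.fasta --gff3 sim/genes.gff3 --out ext
scubkit scub     --fasta sim/genome.fasta --gff3 sim/genes.gff3 --out prof
scubkit scub     --fasta sim/genome.fasta --gff3 sim/genes.gff3 \
                 --out prof_exon --scheme by_exon_position
scubkit shapes   --profiles prof_exon/profiles_by_exon.tsv --out shp
scubkit cluster  --profiles spA prof/profiles_by_intron.tsv \
                 --profiles spB other/profiles_by_intron.tsv --out clu
```

## Layout

```
src/scubkit/
  genetic_code.py     the 59-codon / 18-amino-acid universe
  genome_io.py        FASTA + GFF3 reading, primary-transcript selection
  codon_extraction.py CDS assembly/validation, split-codon exon attribution
  stratification.py   intron-number bins and exon-position cells
  scub_stats.py       frequencies, ratios, context tables, correlations
  profile_shapes.py   cap/cup/flat classification, first-exon conservation
  multivariate.py     clustering (Newick) and varimax PCA
  synthetic_data.py   planted-structure genome simulator
  cli.py              subcommand pipeline
```

See `docs/methods.md` for the statistical model, parameter choices and
limitations.
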