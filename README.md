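# codonharmony

Codon harmonization and codon-usage scoring for heterologous gene design.

When a gene is moved into an expression host such as *Escherichia coli*,
the common strategy — codon *optimization* — replaces every codon with a
frequent one. But clusters of rare codons in the wild-type gene are
thought to slow the ribosome where nascent membrane proteins and other
difficult folds need time, so erasing them can hurt functional yield.
Codon *harmonization* instead recodes the gene so that each position is
about as frequent in the expression host as the original codon was in
the native host, reproducing the wild-type's landscape of frequent
**and** rare codons.

This package is for protein-expression and synthetic-biology labs that
want to generate harmonized (or baseline most-frequent) coding
sequences, build the required codon-usage tables from genome CDS sets,
and quantify how well a variant mimics its native codon landscape.

## The model

For host usage counts `X_ij` (codon *j* of amino acid *i*, summed over
all annotated CDS of the genome), the **relative codon adaptiveness** of
a codon is

    RCA = X_ij / X_imax

where `X_imax` is the count of the family's most frequent codon, so the
preferred codon of every family scores 1. A gene of *N* codons is then
scored by

* **CAI** (codon adaptation index): the geometric mean
  `CAI = (prod_i RCA_i)^(1/N)` of its per-codon RCA values in one host;
* **CHI** (codon harmonization index):
  `CHI = (1/N) * sum_i |RCA_i − RCA_i,native|`, the mean absolute
  per-position difference between a variant's RCA series in the
  expression host and the wild-type's series in the native host.

CHI near 0 means the codon landscape is well mimicked. Harmonization
picks, at every position, the synonymous codon whose expression-host RCA
is closest to the native RCA of the wild-type codon — and because CHI is
a sum of independent per-position terms, that greedy choice is the exact
CHI minimizer over all synonymous variants. Restriction sites can be
removed afterwards by stepping offending codons to the next-closest RCA
alternative.

## Worked example

Two synthetic hosts stand in for a native organism and an *E. coli*-like
expression host (real genome CDS FASTAs drop into `table build` the same
way):

```
codonharmony simulate host --seed 7 --skew 2.0 --n-cds 500 \
    --pseudo sharp_half --out-table native.tsv --out-cds native_cds.fasta
codonharmony simulate host --seed 8 --skew 2.0 --n-cds 500 \
    --pseudo sharp_half --out-table ecoli_like.tsv
codonharmony simulate gene --table native.tsv --length 300 --seed 3 --out gene.fasta

codonharmony harmonize --gene gene.fasta --native-table native.tsv \
    --expr-table ecoli_like.tsv --avoid-motifs GAATTC,GGATCC \
    --out gene_harmonized.fasta --report trace.tsv
```

which prints

```
CHI 0.369 -> 0.037; CAI 0.258 -> 0.631
```

Read: in the expression host the wild-type gene's codon landscape
deviates from its native landscape by a mean RCA difference of 0.369 per
codon; the harmonized variant brings that down to 0.037 (a CHI below 0.1
indicates a well-harmonized gene), while its CAI rises from 0.258 to
0.631 — higher than wild type, but deliberately below the 1.0 a
most-frequent recode (`codonharmony recode-frequent`) would reach,
because rare codons are reproduced on purpose. Scoring and landscape
profiling work on any variant:

```
$ codonharmony metrics --gene gene_harmonized.fasta --table ecoli_like.tsv \
      --native-table native.tsv --native-gene gene.fasta
gene_label	n	cai	chi
synthetic_gene_seed3	300	0.630631	0.036717

$ codonharmony landscape --gene gene_harmonized.fasta --table ecoli_like.tsv \
      --out land.tsv --plot land.png
```

The landscape TSV holds one row per codon (position, codon, amino acid,
RCA, moving average over 5 codons); the PNG is the familiar bar-plus-
black-line landscape figure.

Tables for real hosts are built from a genome's CDS collection:

```
codonharmony table build --cds GCF_000005845_cds.fna --host-label "E. coli K-12" \
    --pseudo sharp_half --out ecoli.tsv
```

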