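# Methods

## Scores

All scoring rests on relative codon adaptiveness (RCA). For one host,
codon counts `X_ij` (amino acid *i*, codon *j*) are accumulated over
frame 1 of every CDS in the supplied collection; `X_imax` is the largest
count within a synonymous family, and `RCA = X_ij / X_imax ∈ [0, 1]`.
Counts deliberately come from *all* protein-coding genes of the genome,
not from a curated high-expression reference set as in the classical
codon adaptation index; with genome-scale counts the distinction between
"usage" and "adaptiveness" reference sets matters little, and no gene
list has to be chosen.

For a gene of N scored codons:

* CAI = geometric mean of the RCA series, computed as `exp(mean(log RCA))`
  for stability; any zero entry short-circuits to exactly 0 with a
  logged hint.
* CHI = mean absolute per-position difference between a variant's RCA
  series in the expression host and the wild-type's RCA series in the
  native host. CHI is a scaled L1 distance: symmetric, triangle
  inequality, zero iff the series coincide. It requires positionally
  paired, synonymous sequences; the implementation verifies residue-by-
  residue identity of the translations and reports the first mismatch.

### Stop codons and single-codon families

Both formulas run over "the number of codons in the gene", so the
default scores every codon, including the stop (counted as a
three-member family in the tables) and the single-codon families
Met/Trp (whose RCA is 1 by construction). Classical CAI practice
excludes stop/Met/Trp; `include_stop` / `include_single_codon_aa` flags
reproduce that convention, and `reference.FLAG_CONVENTIONS` enumerates
all four combinations for sweeps when matching externally published
numbers whose convention is unknown.

### Unobserved codons

`pseudo_rule="zero"` (default) applies the count ratio literally: an
unobserved codon has RCA 0, and any gene using it has CAI exactly 0.
`"sharp_half"` assigns `0.5 / X_imax`, the classical remedy that keeps
geometric means finite; recommended whenever CAI on small or skewed
CDS collections is of interest. The rule is recorded in the table file
header and survives round-trips. A family observed zero times (possible
only in toy inputs) gets uniform RCA 1 with a warning.

## Harmonization

At each position the output codon minimizes
`|RCA_expr(candidate) − RCA_native(wild-type codon)|` over the
synonymous family. Since CHI is an average of independent per-position
terms, this greedy rule attains the global CHI minimum over all
synonymous variants (verified in the tests by exhaustive enumeration on
small genes). Ties are broken toward the higher expression-host RCA,
then toward keeping the input codon, then alphabetically. The
keep-the-input level is this package's choice: it makes harmonization
against the gene's own host an exact identity (and re-harmonization
against the same native profile a fixed point) instead of shuffling
between equally frequent codons; among genuinely different candidates
the less-rare codon remains the safer default. Everything is
deterministic.

The most-frequent baseline (`recode-frequent`) substitutes every codon
with its family's RCA-1 codon (ties alphabetical), giving CAI exactly 1.
It is a transparent stand-in for commercial multi-parameter optimizers,
which also weigh GC content, mRNA structure and more; results from it
are not comparable to any specific commercial algorithm and the CLI help
says so.

### Motif avoidance

Forbidden motifs (typically restriction sites, scanned on both strands
by default since recognition sites act double-stranded) are removed
after recoding. The sequence is scanned left to right; for the leftmost
occurrence, the overlapping codons are tried left to right and the
first one with remaining synonymous alternatives is stepped to the
next-closest-RCA codon (then third-closest, and so on). A substitution
is accepted only if it strictly lowers the total motif count — this
also catches substitutions that would create a new site elsewhere — so
the pass terminates; if no single-codon substitution at any overlapping
codon helps, a `MotifUnavoidableError` names the motif and position
(unavoidable in truth when a motif runs through Met/Trp codons).
Which codon to alter when a motif spans two codons is not dictated by
the method itself; leftmost-first is this package's documented
convention. Translation is never altered.

## Landscapes

A landscape is the per-position RCA series (1-based positions, all
codons included — a landscape is positional, so nothing is dropped)
smoothed by a centered moving average, window 5 by default (odd
windows only). At the gene ends the window is clipped to the available
codons rather than padded, so the smoothed line spans the full gene;
clipping also keeps every position's total weight ≤ 1, which is what
makes the documented bound |mean landscape difference| ≤ CHI hold.

## Synthetic hosts

The generator draws, per synonymous family, codon probabilities from a
symmetric Dirichlet with concentration `1/skew` (`skew = 0` is exactly
uniform; larger values concentrate usage on one dominant codon per
family, stop codons included so stop-handling paths are exercised). A
CDS collection is sampled codon-wise — ATG start, uniform amino-acid
interior, sampled stop — and the returned table is rebuilt from the
emitted CDS, so it is self-consistent by construction. Defaults
(`skew=2.0`, `n_cds=500`, `mean_len_codons=300`, Poisson lengths) give
~150,000 codons, pinning family fractions to within a few percent —
the scale at which table noise stops mattering for CHI — while a full
table build stays around a second. `simulate_gene` draws interior amino
acids proportional to the host's family totals and codons proportional
to counts, so long genes converge to the table's family fractions.

What the generator emulates: per-family codon bias of controllable
strength and its consequences for RCA/CAI/CHI and recoding. What it
does not: realistic amino-acid composition, GC gradients, codon-pair
preferences, length distributions, or any correlation between codon
rarity and protein structure. Green tests therefore demonstrate the
algorithms' correctness and internal consistency, not biological
performance of harmonized genes.

## Problem sizes

Tests run on hosts of 40–500 CDS and genes of 3–300 codons; exhaustive
CHI-minimality checks enumerate all synonymous variants of random genes
of up to 8 codons (capped at 20,000 variants per gene, resampling
larger draws). The acceptance script uses two 500-CDS hosts and one
300-codon gene — the scale of the membrane-protein genes the method is
aimed at.

## Known limitations

* Harmonization considers per-codon frequency only: no GC targeting,
  5'UTR mRNA-structure avoidance, repeat or Shine-Dalgarno handling,
  and no tRNA-gene-copy-number variant of the method.
* Tables are only as good as the supplied CDS collection; different
  assembly/annotation versions of the same organism shift third-decimal
  CHI/CAI values, which is why none is bundled or hard-coded.
* CDS files are taken at face value (frame 1, pre-extracted): no ORF
  re-detection, and internal stops are counted as stops in lenient
  mode rather than rejected.
* The motif pass substitutes one codon at a time; a site removable only
  by a coordinated two-codon change is reported as unavoidable.
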