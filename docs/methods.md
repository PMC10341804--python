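# Methods

## Scope and data flow

`allostate` analyzes binned chromatin tracks for an allotetraploid genome
with A and D subgenomes, in two conditions (e.g., a wild and a
domesticated accession). The chain is: fragment binning -> binarization ->
HMM learning and decoding -> state/element/TE composition -> promoter
state assignment -> cross-condition transition ledger -> differential
expression and Fisher association -> homoeolog pairing and subgenome-bias
decomposition. All coordinates are 0-based half-open; GFF3 is converted on
read, so BED round-trips are bit-exact.

## Binarization

Counts are fragment midpoints per 200-bp bin (the last bin of each
chromosome is kept at reduced width; RPKM uses the nominal width). For
each mark the expected rate per bin is the mock-control count scaled to
ChIP depth and floored at the global ChIP mean; the bin is called present
iff the Poisson upper tail `P(X >= c | lambda)` is at most `1e-4`.
Replicates are pooled before binarization to maximize depth. With no (or
empty) control the global mean alone is the rate.

## The hidden Markov model

`BernoulliHMM` is a K-state HMM over the binarized bins with independent
Bernoulli emissions per mark given the state; chromosomes are independent
observation sequences. Defaults: K = 6, 10 random restarts, convergence
when the log-likelihood improves by < 1e-4 or after 200 iterations.
Numerical choices:

- scaled (linear-space) forward/backward with per-position normalization;
  numba-compiled inner loops;
- emission probabilities clipped to `[1e-6, 1 - 1e-6]` after each M-step
  to avoid degenerate zeros (explicit 0/1 initializations are honoured in
  the likelihood: a conflicting observation gets probability zero and the
  sequence log-likelihood is -inf);
- restarts draw from seed-derived substreams (`SeedSequence.spawn`), so
  the same seed reproduces the model bit for bit; the restart with the
  highest final log-likelihood wins, ties going to the first;
- EM per-iteration log-likelihood monotonicity is asserted in tests over
  randomized instances, and forward/Viterbi agree with exhaustive-path
  enumeration on all tiny instances (T <= 8, K <= 3, M <= 2).

State labels from EM are arbitrary. `relabel_states` canonicalizes by
descending lexicographic sort of emission rows (ties broken by original
index; idempotent). For cross-condition work one model is trained on
condition 1 and decode-only applied to condition 2, so state identities
match by construction; `match_states` (Hungarian assignment on
total-variation distance between emission rows) supports the alternative
of independently trained models, and is how learned states are mapped
onto planted states when evaluating synthetic runs.

## Peaks

The broad-peak caller is deliberately simple: per bin,
`lambda = max(depth-scaled control, global ChIP mean)`; a bin is enriched
when the Poisson upper tail is below `1e-10` *and* count/lambda exceeds 5;
enriched bins within `merge_gap` bins are merged, with the peak p-value
the minimum bin p and the fold change the maximum bin ratio. Replicate
consensus keeps each rep-1 peak that overlaps rep 2 by >= 1 bp, widened to
the union span. Peak annotation is by midpoint with precedence
gene > TE > intergenic. The 50%-overlap statistic is asymmetric (fraction
of A peaks covered >= 50% by B), and the boundary is inclusive.

## Elements and TEs

Promoter = the 500 bp immediately upstream of the TSS, strand-aware,
clamped at chromosome ends. The element map partitions every base with
precedence promoter > exon > intron > intergenic; within a precedence
level the first gene by sorted coordinate wins on overlaps. Composition
tables are descriptive proportions with an explicit Background row (the
element or TE-class composition of the whole genome/TE set). TEs are
assigned to the state under their midpoint for the count view and
apportioned by bases for the base view. Element maps are materialized as
per-base label arrays, which is intended for the desk-scale genomes the
generator produces (a few Mb).

## Gene states and transitions

A gene carries the state covering the most bases of its promoter; on a
tie, the state at the promoter's 5'-most base (in gene orientation) wins,
falling back to the lowest-indexed tied state when that base belongs to a
non-tied state. A zero-length promoter after clamping yields
"unsegmented", and such genes are excluded from transition percentages
(the denominator is assignable genes; both this and the all-genes
denominator are easy to report from the ledger). The transition ledger
pairs per-gene states across conditions; Fisher's exact test (two-sided)
compares DEG frequency in transition genes overall and per from->to
group, with the genome-wide DEG fraction reported as background.

## Differential expression

The NB test is a transparent stand-in for heavyweight count-model
packages, fully specified so results are reproducible from this package
alone: median-of-ratios size factors (total-count fallback when no gene
is positive everywhere), per-gene method-of-moments dispersion pooled
across the two conditions and floored at 1e-6, a Wald test on
`log2(mean_alt / mean_ref)` with delta-method variance
`(1/mu + alpha)/n` per condition, and Benjamini-Hochberg adjustment.
Calls require FDR <= 0.05 and |log2FC| > 1. Tests validate empirical
type-I control under a global null and >= 95% power at a planted 8-fold
change (n = 3 vs 3, dispersion 0.01, mean 500) rather than equality with
any specific external implementation. Homoeolog pair bias reuses the same
test with the two pair members as pseudo-conditions (D member as
reference, so an "up" call reads A > D).

## Homoeologs and subgenome bias

Best hit per query is the lowest E-value (ties: higher identity, then
lexicographic target). A pair is kept iff the best hits are mutual and
both pass E < 1e-5, coverage >= 50%, identity >= 50%. A gene with no
cross-subgenome hit, or only hits failing the coverage/identity cuts, is
subgenome-unique. Genes that are neither — e.g., best-hit asymmetry with
passing similarity — form a reported-but-unanalyzed third class. Group
comparisons (A-unique vs D-unique expression, per-mark gene-body signal)
use the two-sided Wilcoxon rank-sum test: exact enumeration when both
groups have <= 10 observations and no ties, tie-corrected normal
approximation otherwise. Gene clustering k-means-zscores each mark column
first, uses k-means++ initialization with a fixed seed, and relabels
clusters by descending size.

## The synthetic generator

The generator defines the study conditions at desk scale (~3 Mb, ~10 s
end-to-end):

- **Genome**: 2 A chromosomes of 1 Mb and 2 D chromosomes of 0.5 Mb
  (A:D length ratio 2), 700 A genes and 600 D genes of 1 kb with >= 500 bp
  upstream clearance (gene *content* is similar between subgenomes even
  though lengths differ, as in real allotetraploids), ~150 TEs/Mb drawn
  from a Gypsy-dominated class mixture.
- **States and tracks**: a planted sticky 6-state Markov chain per 200-bp
  bin (self-probability 0.97 for the unmarked state, 0.85 otherwise)
  whose stationary distribution makes the unmarked state cover ~75% of
  the genome. Per state and mark, a Bernoulli latent ("biologically
  marked") fires with the planted emission probability; counts are then
  Poisson with rate 25 where the latent is on and 0.5 otherwise (mock:
  rate 1), two replicates sharing the latent. Poisson-per-bin (not
  read-level) generation is sufficient for binarization and HMM testing.
- **Condition 2**: identical hidden states except for a planted 15% of
  genes whose promoter bins (padded by 2 bins so Viterbi cannot smooth
  over the switch) are set to a new state — 40% of switches are
  unmarked -> open (S2->S3), 20% open -> unmarked, the rest random.
- **Expression**: per-gene log-normal baselines (log-mean log(100),
  log-sd 1), NB dispersion 0.05, 2 replicates per condition. Homoeolog
  pairs share their baseline (balanced); A-subgenome-unique genes are
  multiplied by 2.5 (a realistic subgenome-bias effect that is detectable
  with the toy's ~100 unique genes); 20% of genes change 4-fold between
  conditions, with S2->S3 (S3->S2) switch genes forced up (down) with
  probability 0.8.
- **Similarity table**: planted pairs get mutual hits with E-values
  10^-50..10^-20 and passing coverage/identity; unclassified genes get a
  passing but asymmetric hit to an already-paired gene; unique genes get
  at most a sub-threshold hit. RBH at default cuts provably recovers the
  planted structure exactly.

Everything derives from `SeedSequence([seed, stage])` substreams, so each
component and the whole study are byte-reproducible given the seed, and
all truth labels (segmentations, switches, pairs, unique sets, DE
directions) are exported for recovery tests.

What passing tests on this generator do **not** show: robustness to
GC/mappability bias, fragment-length effects, copy-number variation,
overlapping genes and nested TEs, isoform structure, or biological
replicate variability beyond Poisson/NB noise. Genome-scale numbers from
real data (absolute coverage percentages, genome-wide transition counts)
depend on the real genome and are not reproduced at toy scale; the
package reproduces the *qualitative* findings (which group is enriched,
which bias is significant) plus exact arithmetic on published count
tables.

## Problem sizes used in verification

Parameter recovery uses 2x10^5 bins with the planted 6-state/6-mark model
and 10 restarts (per-entry emission and transition error < 0.05 after
state matching; typically < 0.01). Oracle equivalence uses 200 random
instances with T <= 8, K <= 3, M <= 2 at 1e-8 tolerance. DE calibration
uses 200 replicates of 2000 null genes and 200 replicates with planted
8-fold genes. The end-to-end synthetic study is the default ~3 Mb / 1300
gene configuration.

## Known limitations

- The per-base element map and expanded per-base state arrays scale
  linearly with genome length and are not meant for gigabase genomes;
  a run-length implementation would be the natural extension.
- The NB Wald test is anti-conservative for very low counts at n = 2-3
  replicates; the |log2FC| > 1 call threshold masks this in practice, and
  calls — not raw p-values — are the downstream currency.
- The peak caller has no local-lambda sliding windows and no q-values; it
  is a desk-scale stand-in, not a reimplementation of a production
  caller.
- Binarization treats the "-f 2" style fragment-shift/extension concern
  as handled upstream at the fragment level (a no-op on midpoint-binned
  fragment input).
- Joint (cross-condition) binarization-and-training is supported by
  pooling inputs manually, but the default and tested path is
  train-on-condition-1, decode-both.
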