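# Methods

## Trailer and leader architecture

A tRNA locus is represented in transcript orientation: the spliced mature
body runs from +1 to the discriminator base N73 (its 3'-most nucleotide;
the CCA end is added post-transcriptionally and never appears in genomic
sequence), the upstream flank ends at the last leader base N−1, and the
downstream flank starts immediately 3' of N73. Minus-strand loci are
reverse-complemented on extraction so both flanks read 5'→3' along the
transcript. Internal coordinates are 0-based half-open; BED12 is consumed
natively (gaps between blocks become introns) and GtRNAdb-style 1-based
inclusive tables are converted on ingest.

The 3'-trailer length is the offset of the first run of at least *k*
consecutive T in the downstream flank — the genomic template of the Pol III
terminator's uridylate stretch. A run may be longer than *k* (only the
start matters) and may not span an ambiguous N. *k* = 4 by default, with
5–7 available for sensitivity analyses. Trailers longer than 20 nt are
recorded but excluded from summary statistics, as are genes whose
terminator is not found within the downstream window; both groups are
counted separately. Default flank windows are 20 nt upstream and 60 nt
downstream — the downstream window must cover the 20-nt trailer cap plus a
terminator run, with headroom for the longer trailers that the exclusion
rule then removes.

Summaries use the sample (n−1) standard deviation. The modal trailer
length breaks ties toward the smaller length so reports are deterministic.
Entries with undetermined anticodon ("NNN") or isotype ("Und") are kept in
the catalog but excluded from statistics by default, and both totals are
available.

Cross-species comparisons use classic one-way fixed-effects ANOVA computed
from sums of squares (so F and both degrees of freedom are reported
directly), with Tukey's HSD (studentized-range distribution, via scipy)
for pairwise post-hoc tests.

Leader composition is summarised as a base × position count/frequency
matrix over N−W..N−1 with W = 10 by default; the window is configurable
because annotation-derived leader boundaries are not generally available,
so a fixed upstream window is used. The matrix can be conditioned on the
discriminator base; conditioned counts sum to the unconditioned counts.
Pairing avoidance is quantified per discriminator base *b* as the fraction
of genes whose N−1 is the Watson–Crick complement of *b* (DNA alphabet,
A–T and C–G), next to the fraction expected under independence (the
marginal N−1 frequency of complement(*b*)). DNA bases (T, not U) are used
throughout, matching genomic sequence.

## Read fishing and 3'-end binning

Each isoacceptor is identified by a bait: the B-nt 3'-terminal suffix of
its spliced mature sequence (B = 36 by default), ending at N73. Baits must
be unique across the set; identical-sequence isodecoders collapse to one
entry first, and an isoacceptor whose distinct isodecoder sequences
disagree at the suffix raises the same collision error as two isoacceptors
sharing a suffix — the remedy in either case is a longer bait or a curated
per-gene subset. A read is assigned to an isoacceptor iff it contains the
bait as an exact substring (no mismatches, matching a zero-mismatch
alignment philosophy); reads matching two or more baits are discarded as
ambiguous and counted, unmatched reads are counted separately.

The rightmost bait occurrence anchors classification, guarding against
bait-like sequence earlier in a long read. The suffix after the bait
determines the bin: `CCA` → mature; T×n → Un for 1 ≤ n ≤ 10, with longer
uridylate runs capped into U10 rather than dropped; anything else
(including an empty suffix) → UNCLASSIFIED. Reads are handled in DNA
space, so uridylates appear as T.

CPM normalisation divides by the total number of fished reads in the
replicate (classified + unclassified) over 10⁶, so each replicate's CPM
sums to exactly 10⁶; a per-bin denominator (each 3'-end bin scaled to 10⁶
independently) is available behind a flag. Premature CPM is summed over
U1..U10 *before* the IP/input ratio. Enrichment is reported as
log2(fold + 1) — the alternative reading log2(fold) + 1 is undefined at
fold 0, which occurs in real data — with a pseudocount ε (default
0.01 CPM) added to numerator and denominator to guard zero input; if both
sides are zero at ε = 0 the fold is reported as 0. When several input
replicates exist their CPM tables are averaged arithmetically before the
ratio.

Cumulative tail tables use the ≥-length convention (the entry at Un
accumulates all tails of length ≥ n), which makes rows non-increasing in
tail length; an ==-length variant is available. Tail presence is scored
per isoacceptor and tail length as CPM strictly greater than θ = log10(2)
≈ 0.30103. Condition comparisons (e.g. wild type vs knockout) use a
two-way ANOVA (condition × tail length) on per-replicate counts of
isoacceptors scored present, fitted by OLS with type-II sums of squares so
main effects remain meaningful under mildly unbalanced replicate
structures, plus per-tail-length Welch comparisons with Bonferroni
adjustment (raw p multiplied by the number of tail lengths, capped at 1).
Expression/copy-number correlations are Pearson r on log2-transformed CPM.

## Conservation annotation

Alignment cells are classified against the reference row (not a column
consensus): identical if equal; conserved if distinct but in the same
side-chain group — {D,E,N,Q}, {K,R,H}, {F,W,Y}, {V,I,L,M}, {S,T}; G, A, C
and P belong to no group, so e.g. G/A is not conserved. Gaps never count
as identical or conserved; columns where the reference itself is gapped
are flagged unalignable. Classification is symmetric in its two arguments.
The alignment itself (Clustal Omega or similar) is consumed pre-computed.

## Synthetic data generator

The genome generator emulates exactly the features the analysis measures:
per-locus trailer lengths drawn from a configurable family (point mass,
geometric, histogram, discretised normal) placed in front of a terminator
run; leader bases drawn from a marginal distribution, with N−1 drawn from
a conditional that removes a `pairing_avoidance` fraction α of the
Watson–Crick complement of N73 (α = 1 → the complement never occurs);
discriminators from a configurable distribution (default A 50%, G 25%);
mature lengths ≈ N(74, 3.4) discretised; introns with probability 0.1 and
length 8–30 nt; optional copy-number structure in which loci of an
isoacceptor share one mature sequence while flanks stay locus-specific.
Two deliberate simplifications make ground truth exact rather than
distributional: the synthetic trailer itself contains no T, so the placed
terminator is always the first T-run at any *k*, and intergenic filler is
uniform random sequence. Real genomes violate both (trailers contain
uridylates; upstream T-runs can pre-empt the annotated terminator), so
passing recovery tests demonstrates correctness of the measurement
machinery, not robustness to mis-annotation.

The read generator draws reads from a per-(isoacceptor, 3'-end) cell
mixture: an isoacceptor's weight is the sum of its loci's lognormal
expression weights (σ = 0.2 by default; fixed per sample so IP and input
replicates share them), a fraction `mature_fraction` of its reads end in
CCA and the rest carry a uridylate tail drawn from a condition-specific
length distribution (the knockout default shifts mass toward longer
tails). The IP condition amplifies the premature class's share of the
library by `ip_enrichment_factor` f, with mature reads filling the
remaining fraction — the generative picture of an immunoprecipitation
where precursors are pulled down and mature tRNAs are residual background.
Under per-replicate CPM normalisation this makes the expected premature
IP/input ratio exactly f for every isoacceptor while depleting the mature
class, as observed in real IP libraries; it requires
f·(1 − mature_fraction) < 1. The default mature_fraction of 0.8 represents
a size-selected library that retains a substantial nascent-precursor
population; it also gives each isoacceptor enough premature reads at the
default depth of 10⁵ for the recovery contracts (fold within 0.1,
proportions within binomial error) to be sharp. Sequencing errors are off
by default (the matching stage is exact-match by design); a substitution-
rate knob exists. All outputs are pure functions of (inputs, parameters,
seed); identical seeds give byte-identical files.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on generated data:
a 500-gene species for architecture recovery, a 686-gene ciliate-like
species for the headline quantities, and 2 input + 2 IP replicates of 10⁵
reads for the read pipeline. Terminator scanning is validated against a
brute-force all-offsets oracle on 10⁴ random 60-nt flanks for k ∈ 3..7;
tail classification against an exhaustive suffix oracle on 10⁵ random
reads. Statistical code is cross-checked against independent references
(scipy's F test, statsmodels' Tukey HSD, explicit least-squares projection
fits for the two-way design). Frequencies are exact ratios of integer
counts; the only tolerance-bearing comparisons are the stochastic recovery
checks, which use standard-error bounds derived from the generating
distributions.

## Known limitations

- The per-species published summaries can only be reproduced with the
  original genome scrapes (GtRNAdb / UCSC), which are too large to
  distribute here; `tests/data/species/README.md` documents the expected
  layout for running that comparison locally.
- Fishing requires one unique bait per isoacceptor; genomes with deeply
  diverged isodecoders need curated per-gene baits.
- No modelling of reverse-transcriptase misincorporation at modified
  bases, polymerase slippage at terminators, or leader/trailer duplex
  thermodynamics.
- Logo output is count/frequency matrices; graphical rendering is left to
  external tools.
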