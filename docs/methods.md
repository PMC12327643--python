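# Methods

This note documents the models, conventions and numerical choices behind
`protrep`, in the spirit of a methods appendix: what each component
assumes, which defaults matter, and what the synthetic benchmarks do and
do not demonstrate.

## Representations

**Trigram histograms.** A sequence of length *L* is split into its
*L* − 2 overlapping 3-residue windows; the Hist-8000 vector counts each of
the 20³ = 8000 possible trigrams, so entries always sum to *L* − 2. Counts
are raw by default — occurrence counting, not frequency estimation — with
L1 normalisation available behind a flag for length-invariant use. The
vocabulary order is lexicographic in the declared alphabet order
(`ACDEFGHIKLMNPQRSTVWY`), fixed so that feature indices are portable
across runs, files and machines. Sequences containing anything outside
the 20 standard one-letter codes (including U/O and ambiguity codes) are
dropped up front by `filter_standard`.

**Reduced alphabets.** `AlphabetGrouping` is any partition of the 20
standard residues into ≥ 2 named single-character groups; reduction
recodes the sequence and counts trigrams over the G³-bin reduced
vocabulary. The shipped SDM12 partition — {A} {C} {D} {G} {H} {KER}
{LIVM} {N} {P} {TSQ} {W} {YF} — follows the structure-derived
substitution-matrix clustering literature; 12 groups give the 1728-d
Hist-SDM12 representation. The reduced histogram equals the group
projection of the full histogram exactly (a tested invariant), so
reduction never has to be recomputed from sequences.

**Embedding representations.** SoT sums a pre-trained per-trigram
embedding vector over all overlapping windows; it is algebraically the
histogram times the embedding matrix, which the test suite verifies to
floating tolerance. Trigrams missing from the table raise by default; an
explicit "skip" policy treats them as zero vectors and logs the count,
because silently zeroing would bias the sum. Mean pooling averages an
externally computed per-residue matrix row-wise; the row count must equal
the sequence length. No embedding training or transformer inference
happens in this package — tables and matrices are consumed as inputs.

**Region restriction.** A trigram window covers residues *i..i+2* and is
assigned to the region (domain or non-domain) containing its centre
residue *i+1*. The rule is deterministic, handles boundary-spanning
windows without arbitrary splitting, and makes the domain and non-domain
histograms an exact entrywise partition of the full histogram — the
property the region analyses rely on. Domain intervals are 0-based
half-open, sorted, non-overlapping; multiple intervals per protein are
pooled into one "domain" region whose length is the sum of interval
lengths.

## Feature selection

The selection pipeline per bootstrap resample: (a) keep the 2000 features
with the largest total count over proteins (total occurrences, not
document frequency; ties break toward the earlier vocabulary index so
results are deterministic); (b) score survivors with the two-class Fisher
ratio (μ₊ − μ₋)² / (σ₊² + σ₋² + ε), using population (ddof = 0) moments
and ε = 1e−12 purely to stabilise constant features; (c) keep the top
200. Fifty class-stratified bootstrap resamples (with replacement, at the
original class sizes — stratification makes degenerate single-class
resamples impossible) yield 50 top-200 sets, and each feature is ranked
by its membership count.

The consensus rule deriving the final Hist-N set is membership in at
least B/2 = 25 of the 50 sets, with the threshold configurable; frequency
consensus is the natural reading of ranking features "by how often they
are found" across the sets, and N then falls out of the data rather than
being fixed a priori. `final_indices` is ordered by (frequency
descending, vocabulary index ascending). The seed, ε and threshold are
recorded in the `SelectionResult` for reproducibility.

**Random-feature null.** R (default 1000) subsets of N features drawn
uniformly without replacement are each scored by a supplied evaluator —
by convention mean stratified 10-fold logistic-regression AUC — and the
observed set's percentile is 100 · #{null < observed}/R, i.e. strictly
below, so ties never inflate the percentile. Under exchangeability this
percentile is uniform, which the acceptance suite verifies with a
Kolmogorov–Smirnov test.

## Evaluation

Stratified k-fold (default 10) cross-validation shuffles once with the
given seed, splits preserving class proportions within ±1, fits per fold
and scores AUC from predicted probabilities (decision values for SVMs —
AUC is rank-based, so the two are equivalent fold by fold). Classes
smaller than k raise with advice rather than silently degrading. The
hyper-parameter grids have fixed cardinalities — 10 (logistic regression:
C over 10 log-spaced values in 10⁻³..10³), 30 (SVM: 5 linear C values
plus a 5 × 5 C-by-γ RBF grid) and 27 (random forest: trees {100, 300,
500} × depth {None, 10, 20} × min-leaf {1, 3, 5}) — with contents
configurable; the no-tuning baseline is each family's library default.
Grid winners are chosen by mean AUC, then smaller sd, then grid order.
Single-split evaluation covers curated benchmarks: multinomial logistic
accuracy for multiclass tasks, ordinary-least-squares Spearman ρ for
regression tasks; constant predictions make ρ undefined and are returned
as NaN with a warning, never coerced to 0.

## Similarity concordance

Needleman–Wunsch global alignment scores come from Biopython's pairwise
aligner in global mode; the default scheme is BLOSUM62 with affine gaps
(open −10, extend −0.5; the first residue of a gap run costs the open
score, each further residue the extend score, terminal gaps included).
The scheme is fully configurable, and toy match/mismatch/linear-gap
schemes are first-class. Raw scores are used without length
normalisation; since the concordance statistic is a Spearman rank
correlation between the pairwise NW scores and the pairwise
representation cosine similarities, any monotone rescaling of either
score would leave it unchanged, which makes the conclusions robust to the
exact parameterisation. The study samples sets without replacement
(defaults 10 × 1000 at production scale; tests and the acceptance script
use one 60-protein set, i.e. 1770 pairs, which keeps the full run under a
minute on one core while leaving the statistic well determined).

## Region enrichment

Per feature and per protein, region occurrence counts (centre-residue
rule) are divided by the protein's domain or non-domain residue length
and the resulting coverages summed over proteins, giving two totals per
feature; the feature is enriched wherever the total is larger, with exact
ties reported as a third category rather than forced into a side. Raw
fractions are used (the argmax is scale-free, so multiplying by 100 would
change nothing). Only proteins with at least one domain interval *and* at
least one non-domain residue participate; `eligible_records` filters and
logs the exclusions.

## Synthetic data

The generator produces the study conditions the rest of the package is
validated under. Sequences are i.i.d. draws from a background
distribution (uniform over the 20 residues by default, configurable to
skewed compositions); lengths are uniform on a range; each protein gets
one contiguous planted domain interval covering `domain_fraction` of its
length at a random offset. Class signal is planted by overwriting
non-overlapping windows with trigrams from a signal set: insertion counts
are Poisson(rate · L/100) with per-class rates, and each insertion lands
wholly inside the domain with probability `signal_in_domain_prob`.
Overwriting (rather than mixture emission) gives exact ground-truth
occurrence positions, which the recovery and enrichment tests score
against; if a protein cannot accommodate its insertions the length is
resampled with a log message. The defaults — 100 + 100 proteins, lengths
200–400, rates 8 vs 0 insertions per 100 residues, domain fraction 0.5,
in-domain probability 0.9, five signal trigrams built from rare-ish
residues (WWW, CHC, MWM, HCW, WMH) — define a strong-signal regime in
which near-perfect classification and full recovery are the correct
outcome.

Toy embedding tables are i.i.d. standard normal per trigram, or
"signal-aligned": signal trigrams share a common unit direction plus
Gaussian noise so a summed-embedding representation can separate the
planted classes. Mutation ladders copy one random parent and substitute
each residue independently (uniformly over the other 19 letters) at rates
{0.05, 0.15, 0.3, 0.5}, producing families whose alignment scores and
histogram cosines decay together.

What the generator does **not** emulate: realistic residue composition
and correlation structure, indels, evolutionary rate heterogeneity,
multi-domain architectures, or label noise. Passing tests therefore
demonstrate that the machinery is correct and calibrated — recovery of
planted signal, uniform nulls, concordant similarity rankings — not that
any particular representation wins on real proteins.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.default_rng` seeds;
  generators are pure functions of (config, seed) and reruns are
  byte-identical. The pipeline expands one global seed into per-stage
  seeds as (seed · 101 + stage index) mod 2³¹.
* Tie-breaks everywhere (occurrence filter, Fisher top-m, grid winners)
  are deterministic and documented above.
* The acceptance suite and script run the null percentile with R = 300
  and the calibration KS check with 50 runs of R = 60 on an 80-protein
  no-signal set with a 5-fold evaluator — sizes chosen to keep a full
  desk run in minutes while leaving the statistics comfortably resolved.
* Degenerate inputs fail loudly: empty sequences, overlapping intervals,
  ragged embedding tables, single-class labels, zero-norm vectors and
  constant rank inputs all raise or return NaN with a warning, as
  documented per function.

## Known limitations

* The Fisher ratio is the two-class form; multiclass selection is out of
  scope.
* Alignment is global score only (no traceback, no local alignment).
* The consensus-threshold rule for N is one reasonable choice among
  several; it is exposed as a parameter precisely because different
  datasets may warrant different consensus strictness.
* Embedding quality is taken as given — the package evaluates
  representations, it does not learn them.
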