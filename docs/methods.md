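# Methods

## Relative expression orderings

For a gene pair (G<sub>i</sub>, G<sub>j</sub>) within one profile, the REO is
the strict order relation G<sub>i</sub> > G<sub>j</sub> or
G<sub>i</sub> < G<sub>j</sub>. Ties (including the two-zeros case common in
single-cell data) witness no direction and are treated accordingly
everywhere: they never make a pair "stable", they count against consistency
under the default tie policy, and they never cast a classification vote.
All REO quantities are invariant under any strictly increasing per-sample
transform of the expression values, which is the formal content of their
robustness to amplification distortion, batch effects and platform
differences.

Ranks are ascending (rank 1 = lowest expression) with average ranks at
ties; every rank-difference quantity uses magnitudes, so the convention
never affects results.

### Stable pair sets

Two stability rules are implemented as one parametrised predicate:

* **replicate identity** — the pair orders identically (strictly) in both
  technical replicates of one sample;
* **frequency** — one direction holds in more than *f* of a cohort
  (strict, the default, matching a "more than 99%" reading with
  *f* = 0.99), or in at least *f* (non-strict; *f* = 1.0 non-strict is the
  unanimity rule used for signature discovery). *f* ≤ 0.5 is rejected
  because the majority direction would be ambiguous.

A stable-pair set is stored either *materialized* (explicit index arrays;
default up to 3,000 genes ≈ 4.5 M pairs) or *implicitly* as the defining
profiles plus the rule, evaluated by walking the upper triangle of the pair
lattice in fixed-size row chunks. A 20,000-gene universe (~2×10⁸ pairs) is
scored in O(chunk × G) memory without ever materializing pair records. The
two representations agree exactly; both are validated against a naive
double loop in the test suite, and the full-pair consistency score is
cross-checked against an independent Kendall-tau implementation through the
identity score = (1 + τ<sub>a</sub>)/2 for tie-free profiles.

### Consistency score and rank-difference exclusion

Given a reference set of *n* stable pairs and a query profile, the
consistency score is *k/n* with *k* the pairs whose strict query ordering
matches the reference direction. The default tie policy counts a query tie
as discordant (the reference direction is not maintained); `drop` removes
query-tied pairs from both *k* and *n* for sensitivity analysis.

Pairs with nearly equal expression flip first under noise, so the reference
can be thinned: each pair is scored by the mean over the defining profiles
of |rank<sub>i</sub> − rank<sub>j</sub>|, and the ⌊x·n⌋ lowest-scoring pairs
are removed. Ties at the cut are broken by canonical (gene<sub>i</sub>,
gene<sub>j</sub>) lexicographic order so the result is deterministic; the
implicit representation realises the same rule with a cutoff value plus a
tie budget consumed in canonical pair order.

## Fold-change bias evaluation

The headline fold change compares the replicate-averaged low-input profile
with the replicate-averaged paired high-input profile, per gene. "At least
2-fold" is assessed on the *symmetric* fold change max(r, 1/r), since
distortion in either direction is distortion; the directional ratio is also
reported. Zeros are handled by a policy: the default excludes genes with a
zero on either side (counted as undefined rather than inventing a
magnitude); a pseudocount mode ((low+c)/(high+c)) is available.

The coefficient of variation uses the directional fold changes of every
(low replicate × high replicate) pairing. The default axis computes each
gene's mean FC over the pairings and takes sd/mean (sample sd, n−1
denominator) across genes — one number per condition and input level; an
alternative axis averages per-gene CVs across pairings instead. Both are
exposed because the aggregation direction is a genuine modelling choice.

## Reversal signatures

Discovery keeps every pair whose ordering is stable within each class
(unanimity by default) with opposite directions between classes. Each
reversal pair carries the class-wise mean absolute rank differences, and
candidates are sorted by descending reversal degree — their geometric mean
— with ties broken lexicographically.

Panel selection walks odd k = 1, 3, 5, …, classifies the training samples
by majority vote and keeps the smallest k attaining the maximal geometric
mean of sensitivity and specificity (a geometric mean of 1.0 ends the walk,
since it cannot be exceeded and smaller k wins ties). The whole k-path is
retained on the signature for inspection. For dropout-riddled queries a
small panel is fragile, so `k="all"` uses every reversal pair, mirroring
the design choice real tumor/normal applications need.

Classification drops unmeasurable pairs (absent gene, tied values — in
particular double zeros) from the vote; a sample with an exact vote split
is labelled `unclassified`, which evaluation scores as wrong for its true
class. Sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP); a metric
whose denominator is empty is reported as undefined, never fabricated.
Signature filtering removes the union of the ⌊x·n⌋ pairs most weakly
rank-separated in *either* class.

## Pseudo-bulk pooling

Cells are partitioned uniformly at random into groups of fixed sizes; the
default sizing gives n_groups−1 groups of round(n/g) cells with the last
group taking the remainder, which reproduces the published splits 272 →
10×25 + 22 and 157 → 10×14 + 17. Pseudo-bulk expression is the per-gene sum
over member cells (the grand total is conserved exactly). The repeated
experiment draws fresh plans for both classes each repeat from separate
deterministic seed streams (the two classes re-randomise independently),
classifies every pseudo-bulk sample per filter fraction and reports the
arithmetic mean of sensitivity and specificity over repeats.

## Synthetic data model

* **Baseline expression** — per-gene truth drawn log-normal(4, 2) on the
  natural-log scale: a wide, heavy-tailed dynamic range typical of
  transcriptomes. Only ratios and ranks matter downstream.
* **Technical noise** — multiplicative log-normal. High-input replicates
  use σ = 0.05, an order of magnitude below any dilution level. The
  dilution ladder (1000/100/50/25 pg) uses σ = 0.60/1.00/1.35/1.80,
  calibrated once so the fraction of genes at symmetric FC ≥ 2 spans
  roughly 0.1–0.65 across the ladder — bracketing what serial-dilution
  studies report — with the consistency score then falling from ~0.91 to
  ~0.75.
* **Dropout** — a gene is zeroed with probability base × w, where w falls
  linearly with expression rank from 1 (lowest-expressed gene) to 0
  (highest): the simplest monotone model of the observation that
  amplification loses lowly expressed genes first. Dilution levels use
  base = 0.02/0.05/0.08/0.12. Single cells instead calibrate the weight
  scale by bisection so the expected per-cell zero fraction equals the
  target (default 0.90), with per-cell noise σ = 1.0.
* **Two-class cohorts** — class B's truth equals class A's except that each
  of 50 planted pairs (truth-rank separation 200, by default) has its two
  genes' levels swapped, guaranteeing opposite strict orderings. The swap
  necessarily also reverses every (planted gene, bystander) pair whose
  truth lies between the swapped levels; those induced reversals have
  smaller reversal degrees than the seed pair (≤ half the separation for
  bystander genes) and are enumerable exactly by running discovery on the
  two truth vectors. Seed-pair exclusivity therefore only holds at
  separation 1.
* **Determinism** — every generator is a pure function of (config, rng);
  named stage streams are derived from the master seed so adding stages
  never shifts existing ones.

### What the generator does and does not emulate

It reproduces the statistical footprint the analysis relies on —
ratio-scale distortion growing as input mass shrinks, expression-dependent
dropout, ~90% single-cell zeros, class-reversed pair structure — but not
amplification chemistry (no 3′ bias, GC or length effects), no biological
covariance between genes, and no class-asymmetric measurement artefacts.
One visible consequence: in the pooling experiment the planted signal is
clean enough that mean sensitivity and specificity saturate at 1.0 for
every filter fraction, whereas real tumor/normal single-cell data shows a
specificity deficit at fraction 0 that rank-difference filtering repairs.
The properties checked — sensitivity 1.0, specificity non-decreasing in the
filter fraction — hold in both regimes, but passing tests here do not
demonstrate the *size* of the filtering benefit on real data.

## Numerical choices

* Frequency thresholds compare integer agreement counts against f·S with a
  1e−9 guard, so "more than 99% of 69 samples" excludes 68/69 exactly.
* Stable-pair universes are sorted lexicographically at construction, making
  chunked row-major pair enumeration identical to the canonical
  (gene<sub>i</sub>, gene<sub>j</sub>) order used for deterministic
  tie-breaks.
* Delimited matrices are written with round-trip float formatting and read
  with round-trip parsing, so write∘read is exact.
* Problem sizes: the shipped studies use 2,000 genes, 20 samples per class,
  20 simulation seeds for ladder medians and 100 pooling repeats — large
  enough that every qualitative contrast is stable across seeds while the
  whole reproduction stays interactive.

## Known limitations

* The CV axis and the zero policy are modelling choices, not recoveries of
  a unique published definition; both alternatives are exposed as flags.
* Consistency is evaluated per low-input replicate against the high-input
  stable set (stable-vs-stable comparison of two low-input replicates is
  available but not the default reading).
* Probe-level collapsing of array data is out of scope: matrices must
  arrive with one row per gene, and duplicate gene rows are an error rather
  than being aggregated silently.
* Gene identifiers are opaque strings; cross-namespace joins use an
  explicit two-column mapping, never a network lookup.
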