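# Methods

## Entropy of finite DNA words

For a word ω over {A,C,G,T}, let p_ω(n) be the number of distinct
length-n subwords. The maximal admissible subword length n_ω is the
largest n with 4ⁿ + n − 1 ≤ |ω|; a prefix of exactly 4ⁿ + n − 1 bases
contains 4ⁿ sliding windows, so at n = n_ω the distinct count can, in
principle, saturate. The package implements four variants:

* **topological** — log₄ p_ω(n_ω) / n_ω, with p counted over the
  truncated prefix of 4^{n_ω} + n_ω − 1 bases. Exactly 0 on
  homopolymers, exactly 1 on de Bruijn words.
* **generalized** — the mean of log₄ p_ω(i)/i over
  i = n_ω − k + 1 … n_ω, with p counted over the *whole* sequence (the
  definition refers the count to ω itself, not to a prefix; whether the
  per-length prefix truncation should also apply is not specified
  anywhere we know of, and counting over ω is the reading we fixed).
* **modified (both)** — identical except each census is first passed
  through the low-frequency filter below. If the filter empties a
  census, p is floored at 1 so the term contributes 0, consistent with
  "no repetition structure observed".

All values lie in [0, 1] because p_ω(i) ≤ 4ⁱ. Windows containing N are
skipped and never counted; entropy is an error only when no valid
window exists (e.g. an all-N prefix).

## The low-frequency filter

The filter is the method's contribution: subwords seen *less often than
expected* under a uniform i.i.d. background are noise for the purpose
of detecting repetition, so they are removed from the census before the
distinct count. Two rules are implemented:

* `expected_count` (default) — drop length-n subwords with occurrence
  count < L/4ⁿ, where L is the length of the region the census scanned
  (the truncated prefix for the topological variant, the whole sequence
  otherwise). L/4ⁿ is the expected count of any fixed n-word in a
  uniform sequence of length L, so the rule keeps exactly the
  over-represented (repeated) subwords.
* `literal_relative` — drop subwords whose relative frequency
  (count / scanned windows) is below 4^{n_ω}/L. This is the literal
  transcription of the published criterion. Taken as a raw-count
  threshold, 4^{n_ω}/L < 1 for any admissible L and never filters;
  taken as a relative-frequency threshold it removes nearly every
  subword once L ≫ 4^{n_ω}. Neither degenerate reading can produce the
  modest distribution shift the method is meant to produce, which is
  why `expected_count` — the same quantity with numerator and
  denominator per subword class — is the default. The literal rule
  remains selectable for comparison.

## Sliding-window digitization

A window of 100 bp (default) is centered on each base and clamped at
the sequence ends, so every base receives a full-size window and the
profile covers every coordinate. Within a window, the entropy at
*explicit* subword length k is log₄(distinct k-mers)/k — here k is a
direct subword length, not the averaging depth of the generalized form,
because for a 100 bp window n_ω = 3 while the profile deliberately uses
k up to 6; windows cannot saturate 4⁶ distinct 6-mers, so high-k values
sit below 1, and no renormalization is applied. The default per-window
variant is `modified_topological` with the `expected_count` rule (at
window 100 the thresholds are 6.25 for k=2, 1.5625 for k=3, and ≤ 1 —
i.e. inactive — for k ≥ 4).

Stacking k = 2…6 gives a K×L matrix A (modes × positions); each base
carries a 1×5 entropy vector. The implementation slides each window
incrementally (one k-mer retired, one admitted per step), so a profile
costs O(KL) regardless of window size. All-N windows yield missing
entries, filled by nearest-finite-in-row imputation with ties broken
leftward; leading/trailing window placements are available via
`placement=`.

## SVD position score

A = U S Vᵀ (thin SVD via LAPACK through numpy). Signs are fixed by
requiring each left-singular vector to have a non-negative entry sum
(ties: first nonzero entry made positive), with the paired right vector
flipped alongside, so the factorization — and everything downstream —
is bitwise deterministic. The per-base score is the column mean of the
rank-r reconstruction U_r S_r V_rᵀ, r = 1 by default: the five entropy
rows are strongly correlated, so the leading singular direction carries
their shared complexity signal and the column mean returns it to the
entropy scale. r = K reproduces the plain column means of A exactly.

## Calling and evaluation

A base is called exon when its score is at or below the cutoff
(`low_is_exon`, default — exons sit in the low-complexity troughs of
the curve; the opposite direction is available). The tie at the cutoff
is inclusive so the boundary is deterministic. Runs of exon labels
merge into intervals. Evaluation is per-nucleotide: confusion counts
and standard accuracy (tp+tn)/total within a stated region, plus a ROC
built by sweeping every distinct score value with trapezoidal AUC (for
`low_is_exon` the score is negated before the standard
higher-is-positive sweep). Tied scores contribute ½ per discordant
pair, matching the Mann–Whitney identity.

**On the 0.012 default cutoff:** the historical cutoff was defined on a
score curve whose analytic form was never published; relative to this
package's reconstruction convention the informative score range is
roughly 0.3–0.8, so 0.012 calls nothing. It is kept as the documented
default for continuity, but a cutoff inside the observed score range
(the worked example uses 0.6) is what a user should choose; AUC is
threshold-free and unaffected.

## Group comparison

`group_entropies` computes one entropy value per sequence (default
variant `modified_generalized`, k = 2) after discarding sequences
shorter than 200 bp — below that length the subword census is too
sparse for a stable estimate, and 200 bp is the filter the method's
reference analyses used. The Kruskal–Wallis statistic is implemented
directly from the rank formula with mid-ranks and the tie correction
1 − Σ(t³−t)/(N³−N); the p-value refers H to χ²(groups−1) through the
regularized incomplete gamma function (scipy.special.gammaincc). An
all-identical pooled sample is rejected as degenerate (H is 0/0 after
tie correction). Global and pairwise modes are both exposed since
either design is defensible for a three-class comparison.

## Synthetic benchmark

`build_benchmark` embeds repeat segments (a seeded random motif,
default 4 bp, tiled) in i.i.d. background (default GC 0.5) and labels
them exon, the complement intron. Short-motif repetition is used as the
exon surrogate because depressed local complexity is the one property
of exons the method actually detects; no codon-usage or splice-site
structure is modeled. The default layout places six segments of
57/18/60/279/94/180 bp at the annotated offsets of the 7,001 bp region
(positions 3500–10500) of GenBank entry AJ229040, the method's
published single-gene benchmark, so the synthetic task has the same
class imbalance (688 exon bases of 7,001) and segment-length spectrum.

What passing the synthetic benchmark shows: the pipeline recovers
*low-complexity* segments of realistic exon lengths against an i.i.d.
background (AUC ≈ 0.99 here). What it does not show: performance on
real genes, where the exon/intron complexity gap is far smaller (real
mean entropies differ in the third decimal place), background is not
i.i.d., and isochores/repeat families confound the signal — real-gene
AUCs near 0.7 are the realistic expectation, and reproducing them
requires the actual sequences, which this package deliberately does not
download.

## Problem sizes and numerical choices

Default problem sizes: 100-seed benchmark batteries at 7,001 bp; 2,000
replicates of 3×20 for the Kruskal–Wallis null calibration; 1,000 seeded
draws for the modified-≤-unmodified ordering check — sizes at which
every quantity is stable to well inside the asserted bands. Logarithms
are base 4 throughout. SVD contracts are asserted to 1e−8 (Frobenius,
relative); entropy oracle agreement to 1e−12. All generators are pure
functions of their seed; identical inputs give bitwise-identical
scores.

## Known limitations

* The entropy gap driving the synthetic benchmark is much larger than
  on real genomic sequence; treat synthetic AUCs as a correctness
  check, not a performance claim.
* k up to 6 at window 100 cannot saturate, so profile rows have
  different dynamic ranges; the rank-1 SVD absorbs most of this, but
  the rows are not renormalized.
* The literal filter rule is provided for fidelity, not for use; see
  above.
* Strand is ignored; coordinates are resolved on the given sequence
  only.
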