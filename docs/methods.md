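# Methods

## The screening model

The pipeline implements the in-silico stage of a drug-repurposing screen
for compounds that restore a youthful ("bone-stemness") expression program:
extract a differential-expression signature from a two-condition bulk
RNA-seq design, then rank a compound library by how strongly each
compound's predicted transcriptional response *reverses* that signature.

A compound's response is a **CTP** (change in transcriptional profile): a
rank list over a fixed gene universe of size *n*, rank 1 being the gene the
compound is predicted to upregulate most. Real CTPs come from an upstream
deep-learning predictor; this package treats that predictor as a black box
and either loads its output (ranks or continuous change scores, the latter
rank-transformed on load with ties broken by ascending gene identifier) or
emulates it with the synthetic generator.

## Differential-expression signature

For each gene, with group A the reference condition and B the other:

* **fold change** = mean(B) / mean(A) on linear-scale group means — not
  medians, not log-space means, no pseudocount. A gene with reference mean
  0 and non-reference mean > 0 gets fold change +∞ and its call is decided
  by the P value as usual; a gene at 0 in both groups gets fold change 1.
  Units (counts, FPKM, TPM) are the caller's responsibility; only the ratio
  enters.
* **P value** from the two-sided pooled-variance (equal-variance) Student's
  *t*-test with n₁ + n₂ − 2 degrees of freedom. Welch's correction is
  deliberately not used: the procedure being reproduced specifies Student's
  test. Degenerate variance is resolved explicitly — zero pooled variance
  with equal means gives P = 1, with unequal means the smallest positive
  float (warning logged) — so noiseless synthetic input cannot crash the
  caller.
* **calls**: up ⇔ fold change > 2 **and** P < 0.05; down ⇔ fold change
  < 1/2 **and** P < 0.05; both inequalities strict, so a fold change of
  exactly 2 is never called. Thresholds are parameters (`fc_threshold`,
  `p_threshold`); the defaults are the screen's published rule. No
  multiple-testing correction is applied by default because the rule is a
  raw-P cutoff; Benjamini–Hochberg adjustment is an opt-in flag.

The signature is the pair of called gene sets, each sorted by identifier.
The up-set is oriented as "higher in the reference-young condition is what
we want back"; a `flipped()` method / `--flip-orientation` flag swaps the
sets for the opposite reading.

## Enrichment statistic

The unweighted two-sided rank-KS ("connectivity-map") statistic. For a
query set with *t* members present in the universe and ascending sorted
ranks *V*(j):

    a = max_{j=1..t} ( j/t − V(j)/n )
    b = max_{j=1..t} ( V(j)/n − (j−1)/t )
    ES = a  if a > b;   −b  if b > a;   0 on a tie.

Properties relied on (and property-tested): |ES| ≤ 1; ES equals the
supremum deviation between the set's empirical rank-CDF and the uniform
CDF (verified against a full scan over all n positions); reversing a
profile (rank r → n+1−r) maps (a, b) → (b − 1/n, a + 1/n), so strong top
enrichment reflects to strong negative scores; promoting any single member
to a better rank never decreases ES.

Numerical choices: the tie a = b yields ES = 0 to avoid sign flapping;
query members absent from the universe are dropped with a warning and
reported (t is the post-intersection count), mirroring screens where the
signature comes from a larger genome than the profiled universe; an empty
intersection is an error, not a zero. The statistic is unweighted — only
ranks enter — because the screen it reproduces is defined on ranks alone;
GSEA-style weighted running sums and permutation-normalised ES are out of
scope.

## Bone score and ranking

With a = ES(up-set) and b = ES(down-set) per compound:

* **signed mode** (default): bone score = a − b. A reverser (up-set genes
  pushed to the top, down-set genes to the bottom) approaches +2; a
  mimicker approaches −2. This is the orientation that matches the goal of
  reversing the signature.
* **absolute mode**: bone score = |a − b|, provided because the published
  selection rule is phrased on |a − b|; it scores mimickers and reversers
  alike, which is exactly what the planted-mimicker tests demonstrate.

Compounds are ordered by the chosen score descending with ties broken by
ascending compound identifier (a stable sort, so input order never leaks
into the result), and the top k (default 10, the published candidate count)
are selected. The ambiguous "intersection of the top-ranked" reading is
available as `intersect_modes=True`: selected = compounds in the top k of
*both* orderings. Library scoring is a single vectorised pass over the
shared universe; tests pin it to the scalar per-compound path and to a
brute-force re-scoring oracle.

A Monte-Carlo null (`permutation_null`) draws disjoint random up/down sets
of the signature's sizes against a fixed random profile and returns the
empirical bone-score distribution with a quantile function — a calibration
aid for choosing k, since the screening procedure itself prescribes none.

## Synthetic data: what it emulates and what it does not

**Expression**: per gene, a baseline log2 expression ~
Normal(`baseline_log2_mean` = 6, `baseline_log2_sd` = 2); planted up genes
add log2(`effect_fc`) to the non-reference group (down genes subtract it,
one symmetric effect knob); observation noise ~ Normal(0, `noise_sd`) on
the log2 scale; values are exponentiated. Defaults — 1,000 genes, 50 + 50
planted DEGs, 3 replicates per group, linear fold change 4, noise SD 0.25
log2 units — represent the small-replicate bulk design the pipeline
targets, with a planted effect comfortably above the 2-fold calling
threshold and noise typical of clean bulk RNA-seq. Exponentiating a normal
gives exact planted fold changes in expectation and strictly positive
values.

**CTP library**: null compounds are independent uniform random permutations.
A planted reverser forces ⌈strength·|up|⌉ randomly chosen up-set genes onto
the top-most ranks and ⌈strength·|down|⌉ down-set genes onto the bottom-most
ranks, the rest permuted over the remaining ranks; a mimicker is the mirror
image. Placement is by displacement, not swapping, so every profile is a
valid permutation regardless of construction order. Default dimensions
mirror a realistic screen (12,328-gene universe, 961 compounds); tests use
scaled-down universes (typically 1,000 genes × 100 compounds) to keep the
suite fast.

Not modelled: bead-level assay structure, dose/time response, correlated
gene modules, compound chemistry, or the behaviour of any particular
neural-network CTP predictor. Passing tests therefore show that the
*scoring machinery* recovers planted signal under known conditions — not
that any real compound ranking is reproduced; the real screen's library is
not publicly available, which is also why acceptance checking is
property-based rather than value-based.

## Determinism and degenerate inputs

Every stochastic operation takes an integer seed and is a pure function of
its configuration (`numpy.random.default_rng`); the CLI chain with fixed
seeds produces byte-identical output files. Degenerate inputs have defined
behaviour rather than exceptions wherever a meaningful answer exists
(empty DEG sets are legal until scoring; strength 0 plants nothing but
still labels the nominal reversers, giving a proper null calibration
check), and configuration errors name the violated bound.

## Known limitations

* The exact analytic form of the published enrichment and bone-score
  formulas is not machine-readable in the source material (they are typeset
  as images); the two-max rank-KS form and both bone-score modes documented
  above are this package's explicit interpretation, consistent with the
  declared variables t, n, V(j) and the KS framing.
* Fold change on linear group means with no pseudocount makes low-count
  genes volatile; real count data should be normalised upstream.
* The unweighted statistic ignores effect magnitude; two compounds moving
  a set to the same ranks score identically regardless of amplitude.
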