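# Methods

`hstlkit` re-implements, as a tested pipeline, the integrative genomic and
transcriptomic analysis used to characterize hepatosplenic T-cell lymphoma
(HSTL) cohorts: derivation of common chromosome-7 copy-number regions from
per-case aCGH segments and karyotypes, multi-comparison differential
expression with consistency selection, minimal gene-signature search by
cluster-integrity-preserving elimination, and downstream filtering of fusion
calls. A synthetic-cohort generator stands in for the raw study data so the
whole pipeline is reproducible offline.

## Copy-number model and common regions

Segments are per-sample calls `(sample, chromosome, start, end, state)` on
1-based inclusive coordinates (hg19 scale, matching how breakpoints are
printed in cytogenetic reports); BED export converts to 0-based half-open.
States are `biallelic_loss, loss, neutral, gain, amplification`; when copy
numbers are provided, `amplification` means ≥ 4 copies, otherwise the state
column is authoritative.

A cohort-level *common region* (common deleted region CDR on 7p, common
gained region CGR on 7q, smaller amplified region SAR inside the CGR) is the
maximal interval carried in a qualifying state by **every** defining sample.
Each sample's footprint is the union of its qualifying segments, merged into
maximal runs (book-ended intervals merge, since their base coverage is
contiguous); footprint run-lists are intersected across samples and the
longest common run is reported, ties broken toward the smaller start. The
defining set defaults to all samples in the input and is configurable: for
CGR-style questions, whole-arm gain cases are uninformative for boundaries,
so the sub-arm gain cases are passed explicitly. *Recurrent regions* are
maximal genome-wide intervals where at least `min_cases` distinct samples
carry the state, found by a coverage sweep; the supporting-sample list of an
emitted region names only samples whose footprint covers the whole interval,
so a region's support is always fully covering.

Karyotype-level events expand to explicit segments through an `ArmModel`:
an isochromosome of the q arm — i(7)(q10) — loses one p arm and gains the
q arm; a ring chromosome with breakpoints `(b_p, b_q)` — r(7) formed by
illegitimate TCRG–TCRB rearrangement — loses both terminal regions distal
to the breakpoints; whole-chromosome gains span end to end. Centromere
coordinates are not printed in cytogenetic reports, so the chromosome-7
fixture places the p-side boundary at 57.9 Mb and the q-side at 61.9 Mb
(hg19 scale; the p-side is consistent with the largest printed 7p loss end,
57,883,626 bp) and is overridable wherever an `ArmModel` is accepted.

All region operations are verified against brute-force per-base-pair
oracles on toy genomes (≤ 10 samples, ≤ 200 kb) in the test suite.

## ISCN parsing and the aneuploidy tally

The parser covers the token kinds that occur in HSTL karyotypes: numeric
gains/losses (`+8`, `-Y`), isochromosomes, rings, derivatives, additions,
deletions and markers. Modal-number prefixes and sex designators are
consumed; clone-count brackets (`[cp7]`) and `inc` are stripped with a
warning; anything unclassifiable becomes `kind="unknown"` with its raw token
preserved, so tokenization is lossless. Full ISCN grammar is deliberately
out of scope.

Trisomy evidence has two independent channels — a `+N` karyotype token or an
`aCGH+N` annotation — because array profiling detects gains that cytogenetics
misses in low-tumor-burden samples. The cohort rate is reported to one
decimal, *truncated* toward zero (8/9 → 88.8), matching the reporting
convention of the source cohort.

## Differential expression and consistency selection

Per-gene inference is a general linear model fit by ordinary least squares:
intercept plus a group indicator, optionally plus lab-of-origin dummies to
absorb batch offsets in multi-laboratory designs. Without the covariate this
is algebraically the pooled-variance two-sample t-test (asserted against
`scipy.stats.ttest_ind`). Zero-residual-variance genes with equal means get
p = 1 by convention. The signed fold change is `+2^d` for `d ≥ 0` and
`-2^(-d)` otherwise, so FC never falls in (−1, 1) and downregulation prints
negative. False-discovery rates use Benjamini–Hochberg step-up
(`statsmodels`), applied **per comparison**, not pooled across the suite.

The default comparison suite has ten members: the tumor group versus six
microarray references (PTCL-NOS, NK/TCL, AITCL, normal T-cells, activated
γδ T-cells, spleen) and four RNA-seq references (PTCL-NOS, T-ALL, spleen,
thymus). The exact pairs are configuration, since eight named reference
groups with two platforms admit several layouts. RNA-seq comparisons run on
`log2(FPKM + 1)` (pseudocount configurable) through the same linear model;
FPKM is `count / ((length/1e3) · (mapped/1e6))`. Cutoffs are inclusive:
a gene passes a comparison iff `|FC| ≥ abs_fc_min` and `q ≤ fdr_max`,
defaulting to 2.0 and 0.05 — the strict end of the cutoff grid used in the
source analysis (the grid ran to |FC| ≥ 3.5 and FDR ≤ 0.1; both knobs are
flags). Passing signed FCs are merged into a gene × comparison grid;
a gene is *consistent at k* if it is significant with one sign in ≥ k
comparisons and never significant with the opposite sign.

## Signature selection by cluster integrity

The discriminative value of a geneset is judged on a complete-linkage
dendrogram over samples, built from Pearson-correlation distance
`d = 1 − r` on per-gene robust-center-scaled values
(`(x − median) / (MAD · 1.4826)`; zero-MAD genes are centered, left
unscaled, and flagged). The clustering is hand-rolled (O(n³), fine at
cohort scale) so that ties break deterministically by the lexicographically
smallest member pair; merge heights are non-decreasing and cross-checked
against `scipy.cluster.hierarchy` on tie-free instances.

"The tumor cluster stays intact" — a visual judgment in the original
workflow — is formalized as the parameter-free exact-clade predicate: some
dendrogram node's leaf set equals the target-group samples exactly. A
relaxed predicate (all targets under one node at purity ≥ θ) is available
behind a flag but is not the default. Known outlier samples (the cohort's
derived cell line behaves this way) can be exempted per dataset.

`minimal_signature` performs greedy backward elimination: candidates are
visited weakest-evidence-first (ascending minimum |signed FC| across
comparisons; ties and missing scores fall back to gene id), a removal is
accepted iff the clade survives in **every** dataset, and passes repeat
until none is accepted. The result is 1-minimal — removing any single
retained gene breaks the clade somewhere — which the tests verify by
exhaustive single-gene knockout. Global minimality is not claimed: the
search is greedy by design, the visit order is configurable, and different
orders can yield different (all 1-minimal) sets. If even the full candidate
set fails integrity, the result is an explicit "no valid signature", not an
exception.

Numerical choices worth knowing:

* Pearson distance degenerates below three genes (undefined on one-gene
  profiles, identically ±1 on two-gene profiles), so integrity evaluation
  switches to Euclidean distance on the scaled values for genesets of size
  one or two. Without this, one- and two-gene signatures would be
  unreachable regardless of how well a single gene separates the groups.
* Pearson profile correlation is location-invariant per sample, so a
  signature whose genes all shift the *same* direction is invisible to it;
  discrimination comes from mixed up/down patterns, which is also how the
  real 11-up/13-down signature works. The synthetic generator plants both
  directions for this reason.

## Fusion-call filtering

Externally discovered fusion calls pass a fixed-order cascade: read
support, adjacent-gene removal, removal of calls seen in nonmalignant
controls, then recurrence (same unordered gene pair with the same 5′/3′
orientation in ≥ 2 samples). The read-support sentence "fewer than 8
spanning reads and fewer than 5 split reads were filtered out" is ambiguous:
the default `conjunction` rule reads it literally (removed only when *both*
counts are low); `disjunction` requires both thresholds (removed when
*either* is low). Every removal is logged with its stage.

## The synthetic cohort

The generator's defaults encode the study conditions: nine cases (six
isochromosome-7q, three ring-7), one of the isochromosome cases carrying a
complex profile whose monoallelic 7p loss (3,506,316–57,883,626 bp) sets the
proximal CDR boundary; ring cases with terminal losses at the TCRG
(38,406,226 bp) and TCRB (142,502,221 bp) breakpoints, sub-arm 7q gains
arranged so their intersection is exactly the common gained region, and an
amplified interval at the SAR; trisomy 8 at rate 8/9 with three of the eight
positive cases evidenced only by the aCGH annotation. Optional uniform
breakpoint jitter (default 0) perturbs interior endpoints; the truth
manifest is recomputed from the jittered intervals so closed-loop checks
remain exact.

The expression arm plants, on a 2,000-gene baseline (log2 means N(7, 1.5)),
24 consistent signature genes (11 up, 13 down, ±2 log2), dosage effects tied
to region state (−1 log2 for CDR genes, +1 for CGR, +0.585 for chromosome 8,
i.e. one-copy loss and 3:2 gains), and one dosage-*discordant* CDR gene
planted +2 log2 — deletion does not imply downregulation, emulating the
CHN2 phenomenon central to the source analysis. Microarray noise is
Gaussian (sd 0.5 log2) with optional per-lab gene-wise batch offsets
(default off; a dedicated test switches them on to show the lab covariate
absorbs them). The RNA-seq arm draws negative-binomial counts with mean
`(2^x − 1) · length_kb · depth_M` and dispersion 0.1 (a typical bulk
RNA-seq overdispersion), gene lengths uniform 0.5–10 kb, depths 20–40 M;
group sizes default to 10 per group on both platforms. Fusion tables mix
truth-labeled calls spanning every filter stage; because the two
read-support rules legitimately disagree on split-only calls, the manifest
carries one truth set per rule.

What the generator does **not** emulate: probe-level microarray artifacts,
GC/length biases and normalization residue, gene–gene correlation beyond the
planted group structure, mixed tumor purity, and count–covariate
confounding. Passing tests therefore demonstrate correctness of the
*procedures* under the stated statistical structure, not performance on the
original arrays; the literal 24-gene list and the full-cohort gene counts
require the deposited data and are out of scope.

## Problem sizes and runtimes

The default test suite runs the property batteries at 2,000 genes × 10
samples/group × 20 seeds (type-I control and planted-recovery), with the
elimination search exercised on three full cohorts plus small planted
fixtures; the whole suite completes in well under a minute on one CPU. The
acceptance script recomputes only the printed-input regressions and runs in
about a second.

## Known limitations

* The ISCN subset does not resolve band coordinates of `der/add/del` tokens
  to base pairs; such events never enter region derivation.
* Greedy 1-minimal signatures depend on the elimination order (documented,
  configurable), and very small signatures can overfit a single cohort —
  the held-out replicate test quantifies this on synthetic data.
* The per-gene OLS treats genes independently; no shrinkage or empirical
  Bayes moderation is applied, matching the source workflow's plain GLM.
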