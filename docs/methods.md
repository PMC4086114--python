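# Methods

## The problem

RNA-binding proteins (RBPs) regulate splicing, stability, localization and
translation by binding short (3–30 nt) degenerate sequence elements on
mRNAs and non-coding RNAs. Scanning a transcript for matches to an
experimentally defined motif — a PSSM or IUPAC consensus — produces many
spurious hits, because the motifs are short and information-poor. `rbpscan`
reduces the false-positive load with three context-aware devices: (i)
per-motif, per-genomic-region empirical calibration of match scores,
(ii) a clustering-aware Weighted-Rank (WR) site score that rewards anchors
surrounded by suboptimal matches, and (iii) an optional conservation filter
for sites in mid-intron/intergenic sequence.

## Match score

A motif of width *k* is a column-stochastic matrix `p_i(b)` over (A,C,G,U).
Entries below 1e-3 are pinned to that floor and the remaining mass of the
column rescaled, keeping log-odds finite; the pre-floor matrix is retained
for consensus motifs so their information content reflects the exact
degeneracy pattern. Each window `b_1..b_k` receives the raw log-odds score
against a uniform 0.25 background,

    S = sum_i log2( p_i(b_i) / 0.25 ),

min–max normalized with the columnwise best/worst achievable raw scores so
that every motif's scores live on [0, 1] with the optimal k-mer at exactly
1. Windows containing ambiguous bases are skipped. An all-uniform motif is
degenerate (S_max = S_min); its windows all score 1 by convention and can
never reach significance.

## Background calibration and stringency

For each motif and region class — splice-site flank, internal exon, 5′ UTR
exon, 3′ UTR exon, ncRNA, mid-intron/intergenic — a background corpus is
scanned exhaustively. The sorted sample of all window scores gives the
empirical upper-tail p-value with the finite-sample correction
`p = (1 + #{bg >= s}) / (1 + n)`, which is never 0 and monotone in `s`.
Stringency levels fix the two p-value thresholds (significant anchor,
suboptimal support): high (0.001, 0.01), medium (0.005, 0.01; default),
low (0.01, 0.02). The score threshold for a target p is the smallest score
whose corrected empirical p-value is below it; if the sample cannot support
the target p the threshold is +inf and no anchor is callable.

## Weighted-Rank score and the Z-test

Anchors are windows at or above the significant threshold. With window
centers `c(q) = offset(q) + k/2`, the cluster of an anchor `a` is

    C = { q != a : |c(q) - c(a)| <= 25, score(q) >= t_suboptimal },

inside the 50-nt window, and

    WR = score(a) * (1 + sum_{q in C} score(q) / N),   N = 50 - k + 1.

WR equals the anchor score for an isolated anchor and at most doubles it.
The WR background is built by running this same anchor→WR procedure on the
background corpus itself, yielding the region- and motif-specific mean μ
and standard deviation σ. A candidate is reported iff the one-tailed
normal p-value of `z = (WR - μ)/σ` is strictly below 0.05. Overlapping
called anchors of one motif (closer than k nt) are collapsed to the
highest-WR representative.

The exact functional form of the original clustering score is not public;
the form above is an approximation chosen to satisfy its documented
properties — it reflects clustering propensity, weights neighbours by
their match score, reduces to the anchor score in isolation, and is
bounded and monotone in every input score.

## Other-genome (annotation-free) mode

Without a genome-specific background corpus, thresholds come from the exact
distribution of the match score of a random i.i.d. k-mer, computed by
per-column convolution of the raw-score atoms on a 1e-4-wide grid
(validated against exhaustive 4^k enumeration for k ≤ 8). This
distribution encodes motif length (number of columns convolved) and
complexity (per-column score spread), so higher-information motifs receive
higher absolute cutoffs. Sites report their WR score against the
theoretical cutoff — the WR of a bare anchor scoring exactly the
significant threshold — and no Z/p, since no region-specific μ/σ exists.

## Region classification and conservation filter

Positions are classified at the site midpoint with priority
ncRNA > 5′ UTR exon > 3′ UTR exon > internal exon > splice flank >
mid-intron/intergenic; a splice flank is an intronic midpoint within 100 nt
(configurable) of an annotated exon edge, and anything outside annotated
genes is mid-intron/intergenic. The conservation filter applies only to
mid-intron/intergenic sites: a site is removed iff the mean conservation of
its 50-nt environment (site extended symmetrically; matching the WR window
width) is strictly below the pooled mean over all splice-flank positions
with data. Sites whose environment is under 50% covered are kept — the
filter acts only on positive evidence of non-conservation — and disabling
the filter is the identity.

## Synthetic data

The generator emulates the study conditions rather than any particular
genome:

* **Background corpora** — 1000 sequences × 250 nt per region class, i.i.d.
  with class-specific base composition (exons and 5′ UTRs GC-richer, 3′ UTR
  and intergenic sequence AU-richer, splice flanks pyrimidine-rich). This
  reproduces the one property the calibration consumes (region-dependent
  score distributions) but none of the positional structure of real introns
  or exons.
* **Binding sets** — CLIP-like fragments of 100 nt. "Strong binder" sets
  plant the motif consensus in 80% of sequences with two one-mismatch
  copies within ±25 nt of the anchor; "weak binder" sets plant at 5% with
  no clustering. Rates follow the spike-in design the enrichment check is
  defined over.
* **Gene model and conservation** — a fixed toy locus exercising all six
  region classes, and a piecewise-constant track (exons/ncRNA 2.0, splice
  flanks 1.0, elsewhere 0.0) that pins the intronic reference level at 1.0.

Passing tests on these fixtures demonstrate correctness of the machinery
and the direction and rough size of each stage's contribution; they say
nothing about sensitivity/specificity on real CLIP data, where binding
sites cluster with different geometry, backgrounds are not i.i.d., and
conservation is continuous.

The bundled default motif is a 7-nt UGCAUGU-preferring PSSM (Fox-1-family
-like) with ~5.8 bits of information: informative enough for planted sites
to be recoverable, soft enough that its score distribution is nearly
continuous, which the empirical calibration needs.

## Numerical and design choices

* Match scores are min–max-normalized log-odds so that per-motif score
  scales are commensurable and the best/worst k-mers are exact test anchors.
* The +1/(n+1) correction keeps empirical p-values positive; thresholds are
  placed one float ULP above the boundary sample value so "score ≥ t"
  realizes exactly the admissible count.
* The analytic convolution bins raw scores at 1e-4; the accumulated
  rounding is below k·5e-5 on the raw scale and tail probabilities agree
  with enumeration to 1e-9 away from atom boundaries.
* The 50-nt WR window is centered on the anchor's k-mer midpoint
  (center-to-center distance ≤ 25 nt), avoiding k-dependent asymmetry; the
  windowing of the original implementation is not documented.
* Suboptimal hits overlapping the anchor's own k-mer count as cluster
  members when their offsets differ; excluding them would introduce an
  arbitrary extra parameter.
* Queries from FASTA are not aligned to a genome; coordinate (BED) input is
  the supported path to genomic context. FASTA-only records are treated as
  mid-intron/intergenic for background selection and are exempt from the
  conservation filter (no coordinates, hence no track evidence).
* WR scores use raw match scores, not ranks; the rank-based variant is not
  recoverable from public descriptions.
* Sensitivity and specificity are per-sequence (a sequence counts once
  however many sites it has), consistent with the 2×2 Fisher construction.

## Calibration caveat and problem sizes

The final Z-test assumes normality of the anchor-WR background, but that
distribution is the upper tail of the match-score distribution times a
clustering boost and is right-skewed; under the null the realized
final-call rate is therefore slightly above the nominal 0.05 (≈0.04–0.07
on the bundled fixtures), which is why the calibration check allows up to
0.075 at ≥5000 anchors. Standard problem sizes used throughout the test
suite and the acceptance script: 1000×250 nt backgrounds, 4500×250 nt null
corpora (≈5000 anchors), 500+500-sequence spike-in sets, 100 enrichment
replicates.

## Known limitations

* The WR functional form is this package's own reconstruction (see above).
* i.i.d. backgrounds understate the local repetitiveness of real genomic
  sequence, so real-data thresholds would differ from fixture thresholds.
* No multiple-testing correction is applied across motifs or sequences.
* RNA secondary-structure accessibility is not modelled.
* Strand handling assumes sense-strand RNA; minus-strand coordinate input
  is reverse-complemented before scanning.
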