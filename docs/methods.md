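# Methods

## Problem setting

Two groups of samples are assayed on a methylation array; each probe i
reports a beta value in [0, 1] (the methylated fraction at a CpG site).
Differentially methylated regions (DMRs) between the groups range from a
few basepairs (a single promoter or enhancer) to whole chromosomes (X
inactivation), and no single window width can capture that range.  The
caller therefore slides windows defined by a *count of adjacent CpGs* —
not a genomic width, so the scan is agnostic to probe density — and runs
the scan iteratively with increasing window sizes (default 4, 8, 16, 32,
64 adjacent CpGs).  Each pass produces a *layer* of candidate DMRs; layers
are integrated so that every DMR called with a smaller window nests inside
exactly one DMR of the next layer.  The top layer is the primary output;
the hierarchy itself is informative (e.g. gaps inside a chromosome-scale
DMR that persist across several layers mark subregions, such as genes
escaping X inactivation, that lack the surrounding differential signal).

Inputs are a probe manifest, a normalized beta matrix, and either a sample
sheet (the package runs an exact Wilcoxon rank-sum or Welch t-test per
CpG) or a precomputed per-CpG p-value table, so any study design that can
produce per-CpG p-values can feed the caller.

## Significance ranks and the individual-CpG cutoff

Probe i receives the rank `K_i = #{j : p_j <= p_i}`; tied p-values share
the maximal count.  This convention makes the rank double as the number of
"success" CpGs at least as significant as probe i in the whole track,
which is what the hypergeometric bookkeeping below requires.  Ties are not
an edge case: the exact two-sided Wilcoxon at 8 vs 8 samples has a p-value
floor of 2/C(16,8) ≈ 1.55e-4, and every strongly differential probe sits
on that atom, so thousands of probes can share one rank.

Type-I control is anchored at the individual-CpG level: the user supplies
a p-value cutoff, or the package estimates one by permuting the group
labels (default 20 permutations), estimating FDR(c) = (mean permuted count
below c) / (observed count below c) over the observed p-values,
monotonizing with a running maximum, and returning the largest cutoff with
estimated FDR at or below the target (default 0.10).  The count of probes
below this cutoff, `n_tests`, is also the number of tests used for
region-level correction.

## The region score

For a window of w adjacent CpGs, the single most significant member is
excluded as a conditioning draw — a window must never become a DMR on the
strength of one extreme CpG — and the remaining m = w − 1 members are
processed from least to most significant (K_1 >= ... >= K_m).  Two
member-rank enrichment statistics are computed, each a valid p-value under
the null that ranks are randomly assigned to positions:

**Sequential hypergeometric chain.**  Factor i is the upper tail
P(X >= k_i) of a hypergeometric draw with population N_i, success count
K_i and draw count n_i, where k_i counts remaining members with rank
<= K_i, n_1 = m, n_i = k_{i−1} − 1, N_1 = N (the track size) and
N_i = K_{i−1} − 1.  The variable updates spend the information of each
step, making the factors independent: factor i is the conditional
distribution of the next order statistic evaluated at its observed value,
i.e. Uniform(0,1) under the null (sub-uniform for discrete ranks).  The
raw product of m independent uniforms concentrates near e^−m — for a
64-CpG window *every* random window would have a raw product near e^−63 —
so the product is a test statistic, not a p-value.  It is calibrated
against its null law: −log q ~ Gamma(m', 1), giving

    p_chain = P(Gamma(m') > −log q) = q · Σ_{k<m'} (−log q)^k / k!

with the shape m' equal to the number of *informative* factors (factors
< 1).  Rank ties collapse their trailing factors to exactly 1; counting
those degenerate factors would only dilute the combination, and with the
shape reduced this way the score of a window whose members all share one
tied rank reduces to the single exact hypergeometric tail, which is
exactly uniform under a null of randomly placed tied ranks.

**Prefix enrichment minimum.**  The chain's population update makes it
brittle: one moderately ranked null CpG just above a tied significant
block conditions the population down to that null's rank and the block
becomes unremarkable.  The companion statistic tests, for each prefix
j = 2..w of the full member set sorted by rank (a_2 <= ... <= a_w),
whether at least j members rank within a_j:  P(X >= j) for a
hypergeometric with population N, successes a_j, draws w.  Starting at
j = 2 preserves the no-single-CpG rule.  The minimum over the w − 1
prefixes is Bonferroni-corrected by w − 1.

The region score is `p_region = min(1, 2·min(p_chain, p_prefix))` (both
components are valid p-values, so the Bonferroni-2 combination is; for
windows of two members the two coincide and no factor is paid).  The
score is super-uniform under the null by construction, which is what
keeps large windows quiet on random data, and it is computed entirely in
log space with an exact finite-series Gamma tail, so it never underflows
to zero.  The raw sequential product remains available
(`score_region(..., calibrate=False)`).

Numerical note: hypergeometric tails are summed directly from
gammaln-based log-pmfs — the lower tail when the mean exceeds the
threshold (at most k terms, no cancellation because the tail is >= 1/2),
otherwise the strictly decreasing upper tail with early truncation.  This
is exact to float precision and orders of magnitude faster than generic
library survival functions at scan shapes (~10^6 tails per layer).

## Selection, merging, integration

Windows slide at stride 1 and are candidates only if they contain at
least one probe below the individual-CpG cutoff.  Candidate scores are
corrected within the layer — Bonferroni, or Benjamini–Yekutieli step-up
(default) — with the number of tests equal to `n_tests`, the count of
sub-cutoff probes, not the number of windows: stride-1 windows are almost
wholly overlapping and each sub-cutoff probe contributes about one
window's worth of independent evidence.  Windows with adjusted p below
the region threshold (default 0.01) are kept; overlapping or abutting
kept windows are unioned, trimmed to their outermost individually
significant CpG (windows otherwise pad up to w − 1 non-significant
flanking probes, which in sparse regions would inflate extents by tens of
kilobases), and rescored as regions.

From the second layer on, each tentative region is integrated with the
previous layer: for every overlapping previous-layer DMR *individually*,
that DMR's member CpGs are removed and the remainder rescored.  The
candidate survives only if *every* remainder is still significant — i.e.
no single previous DMR is responsible for the candidate's score — in
which case it absorbs its overlapping previous DMRs; otherwise the
previous DMRs replace it.  Previous DMRs overlapping no candidate carry
through unchanged, so regions are expanded, added or consolidated but
never lost, and each layer nests inside the next.  The remainder is
compared against the layer's *realized* step-up critical value (or the
raw region threshold if looser): the retest is a conditional
decomposition check on one already-selected candidate, not a fresh
genome-wide scan.  Correction is applied within each layer only; layers
reuse the same per-CpG evidence, so cross-layer correction is not
attempted.

## Tunable parameters

| parameter | default | meaning |
| --- | --- | --- |
| `window_sizes` | (4, 8, 16, 32, 64) | adjacent-CpG counts, one layer each |
| `locs_pval_cutoff` | `"auto"` | individual-CpG p threshold; `auto` = permutation estimate |
| `locs_fdr` | 0.10 | target FDR for the permutation cutoff |
| `region_signif_cutoff` | 0.01 | adjusted region-level threshold |
| `correction` | benjamini-yekutieli | within-layer multiple-testing procedure |
| `n_perm` | 20 | label permutations for the cutoff estimate |

## The synthetic benchmark

The simulator injects ground-truth DMRs into a beta matrix — a
user-supplied normalized matrix, or the package's synthetic backbone.
Regions are drawn log-uniformly within four size classes (0.1–1 kb,
1–10 kb, 10–100 kb, 0.1–1 Mb; at least 3/6/9/12 member CpGs
respectively), snapped to their first/last member probe, placed at least
10 probes from one another, 25 per class by default.  Two groups of 8
samples are drawn at random; a *noise* fraction (default 0.5) of each
region's interior CpGs is masked (first and last members never); the
group with the higher regional mean beta gets +Δβ (default 0.2) at every
non-masked member; any probe pushed above 1 has **all** of its beta
values divided by the probe maximum, which slightly shrinks the
uninflated group as well — the realized group difference is therefore a
little below the nominal Δβ, and the tests track that loss.  Mask counts
round half-up.

The synthetic backbone emulates an Illumina-style array: ~50,000 probes
on 4 chromosomes laid out as a three-component mixture — dense CpG-island
runs (~14 probes at ~30 bp spacing), gene-body/shore runs (~5 probes at
~1.5 kb), and solitary open-sea probes — separated by ~30 kb background
gaps (~370 Mb of genome); per-probe baselines from a bimodal Beta mixture
with modes near 0 and 1; per-sample Gaussian jitter with per-probe sd
around 0.03, clipped to [0, 1].  Island density is at the EPIC-like end
so that sub-kilobase regions carry enough members to remain detectable
after 50% masking.  What the backbone does **not** model: SNP-overlapping
probe artifacts, batch effects, cell-composition structure, spatial
correlation of beta values between neighboring probes, and chromosome-
scale features (the X-inactivation analogue is exercised with constructed
rank tracks in the tests instead).  Passing benchmarks on this backbone
therefore demonstrate the windowing/integration machinery under realistic
geometry and noise, not robustness to array artifacts.

## Evaluation statistics

Called regions (any caller's BED) are compared with truth regions by:
width pairs (all overlapping truth/called combinations; Pearson r on
log10 widths, raw-scale r also reported); the per-truth mapping value
(`a` called regions on one truth → a; one called region shared by `b`
truths → 1/b; whichever is farther from 1 on the log scale; exactly 1 =
one-to-one recovery, with unmatched truths kept in the one-to-one
denominator); a stepwise-inclusion feature-level precision–recall curve
in which each called region contributes its fraction overlapping truth
and each truth region its fraction covered by the included calls — equal
weight per truth region, so megabase features do not dominate — with
AUCPR by trapezoid over recall after prepending (0, first precision); and
confusion metrics at basepair and CpG level over an explicit evaluable
domain.  At the feature level, specificity and the negative side of MCC
are computed over the complement gap features of the truth within the
domain (each gap weighted equally, like each truth region), and MCC is
assembled from the four rates as sqrt(TPR·TNR·PPV·NPV) −
sqrt(FNR·FPR·FDR·FOR); a perfect caller attains 1 everywhere and an
empty call set scores 0.  A printed-formula feature-level false-negative
definition that duplicates the true-positive wording is implemented as
the complement (1 − coverage), the only reading that keeps recall in
[0, 1].

## Enrichment analyses

CpG-membership contingency tables compare two region sets (or a layer's
*gaps* against an annotation) over a user-specified probe universe.
Fisher's exact test supplies the p-value; the odds ratio is reported both
as the sample cross-ratio and as the conditional maximum-likelihood
estimate with an exact central 95% CI — the convention that yields very
wide rather than degenerate intervals for sparse tables.  Gap sets are
the maximal intervals of a span not covered by a layer's DMRs; gaps and
DMRs partition the span exactly.  Cross-condition reports count region
pairs with any overlap and genes hit by at least one DMR in each
condition, which catches genes shared through non-overlapping parts of
the gene body.

## Known limitations

* The region score needs at least two significant members after the
  conditioning exclusion; regions whose differential signal reduces to
  one or two probes (e.g. 3-CpG regions with half the interior masked)
  are at the edge of detectability, and more so the smaller the track
  (the per-CpG evidence of a tied block scales with log(N / tie count)).
* Two genuinely separate DMRs closer than one window's probe span can be
  merged: the integration rule retains a broad candidate whenever no
  single child accounts for its score, and two real neighbors satisfy
  that.  At 50,000 probes and 100 injected truths ~10% of truth pairs sit
  within a 64-CpG window's reach, which bounds the achievable width
  correlation and one-to-one fraction of the scaled-down benchmark; on
  full-size arrays the collision rate is an order of magnitude smaller.
* No cross-layer multiple-testing correction is attempted (layers reuse
  the same base evidence); the hierarchy should be read as one analysis,
  not as independent discoveries.
* Fixed-genomic-width windows are deliberately out of scope; window
  membership is a probe count, so extents in probe deserts are coarse.
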