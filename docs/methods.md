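# Methods

## Study design being modelled

The pipeline implements the analysis pattern of divergent-selection feed-efficiency
studies in growing cattle: a cohort (~148 steers) is phenotyped for total body-weight
gain and total dry-matter intake over an 84-day feeding trial, the most phenotypically
divergent animals in each gain × intake quadrant are sampled for tissue transcriptomics,
and the selected animals' expression profiles are analysed for quadrant effects,
validated by qPCR, and cross-referenced against copy-number-variable genes detected
from read depth in a reference population.

## Phenotypes and selection

Body weight is regressed on days on study with a quadratic polynomial per animal
(OLS); total gain is the fitted difference `b1·84 + b2·84²`. The fit requires at
least four distinct weigh days including anchors within 7 days of both trial ends;
with the simulated 2-kg measurement noise across seven weigh days the fitted gain is
within ±5 kg of truth for ≥95% of animals.

Selection standardizes gain and intake and ranks animals by the Mahalanobis distance
of the standardized pair under the sample correlation r. "Standardized distance from
the bivariate mean assuming a bivariate normal" is read as the Mahalanobis form —
the only standard reading that uses the stated correlation; with r = 0 it reduces to
the Euclidean norm (a tested property). Ranking on d or d² orders identically, so
the choice is immaterial. Selection is greedy per quadrant by descending d, skipping
an animal whose dominant breed (argmax of breed fractions, lexicographic ties)
already has `max_per_breed` (default 2) selections in that quadrant; health-excluded
animals are dropped before ranking. Reported group means use round-half-to-even at
integer kg — the rule consistent with all four pooled rows of the reference group
table simultaneously.

## Quadrant differential expression

"Quadrant as a fixed effect and animal as residual" with one array per animal is an
ordinary one-way ANOVA per gene: 3-df F against (n−4)-df residual, least-squares
means equal to arithmetic group means in the balanced layout (asserted to 1e−10
against a sums-of-squares oracle). Contrasts are linear functions of the quadrant
means — gain `(HH+HL)/2 − (LL+LH)/2`, intake `(HH+LH)/2 − (HL+LL)/2`, interaction
`((HH+LL) − (HL+LH))/2` — each tested as a 1-df t contrast against the residual
mean square, so estimates stay in log2 units. Genes with zero residual variance are
reported with p = 0 (or p = 1 when entirely flat) and a logged warning rather than
NaN.

BH FDR is computed by an explicit step-up with an `m` parameter that defaults to the
platform gene count (24,431) even when fewer genes were tested, matching how array
studies correct against the full platform; statsmodels reproduces the q-values
exactly when `m` equals the vector length (tested). Under a global null at α = 0.05
the expected nominal discovery count is α·m = 1221.55 for the full platform; the
package reports the formula value, not a rounded historical figure.

## qPCR concordance

Livak relative quantification: replicate Cq values are averaged per gene × sample,
ΔCt = Cq(target) − Cq(reference), ΔΔCt is differenced against a pooled control
sample, and the reported value is `log10(2^−ΔΔCt)` — base 10 so magnitudes sit on
the conventional printed scale. Concordance is the Pearson correlation across the
four quadrant means between the qPCR and array scales; it is invariant to the log
base (tested), so the base choice cannot affect classification. Classes are strict:
high r > 0.85, moderate 0.5 < r ≤ 0.85, opposite r < 0, otherwise "other"; zero
variance on either scale yields an undefined r and class "other" with a warning.
A per-animal correlation is available as an option but the quadrant-mean form is
the default, being what printed validation tables reproduce.

In the simulator, Cq is inversely linear in log2 expression with slope −1; the
pooled control's expression is the per-gene **median** across samples, so a single
divergent quadrant leaves the control at baseline and a +1 log2-unit quadrant effect
appears as exactly −1 in that quadrant's mean ΔΔCt. The reference gene is generated
with no group structure and passes a one-way ANOVA at p > 0.2 under default noise.

## Copy-number decomposition and segmentation

Within each genomic window the counts of the S samples follow a mixture over integer
copy numbers cn ∈ {0..8}: `count_j ~ Poisson(λ s_j cn/2)`, with cn = 0 mapped to a
small relative rate ε = 0.05 (residual mapping noise), mixture weights shared across
samples within the window, and per-sample size factors s_j estimated by
median-of-ratios (robust to a minority of copy-variable windows) and normalised to
mean 1. The EM fit is MAP with a Dirichlet pseudo-count (default 1) on the diploid
component and a floor of 0.01 on mixture weights. The floor matters: without it, EM
collapses rare components to numerical zero, the log-weight penalty for a true
carrier grows unboundedly, and single-copy changes become undetectable mid-event.
With the floor, the maximal prior penalty is ~4.5 nats, against per-window
log-likelihood advantages of ≈6 (cn 1), ≈4 (cn 3), ≈15 (cn 4) and ≈38 (cn 0) nats at
the default 40-read diploid depth. A window's informativeness is 1 − α₂, the weight
mass off the diploid configuration; all-zero windows are returned as uninformative
diploid rather than NaN.

This is a deliberate simplification of full multi-sample read-depth callers: there
is no across-window shrinkage of the weight estimates (cn.MOPS's I/NI prior), no GC
correction and no base-pair breakpoint refinement. Accuracy is therefore assessed by
recovery of implanted truth on synthetic panels, not by matching any external tool's
output.

Segmentation pools evidence across adjacent windows — the role segmentation plays in
read-depth callers generally: log-posteriors (floored at 1e−6 so one saturated
window cannot outvote its neighbours) are summed over a centred 3-window sliding
window, per-window modes are taken with ties resolved toward diploid, maximal runs
of non-diploid modes are bridged across gaps of ≤2 windows, each span's copy number
is the non-diploid state maximising the pooled log-posterior over the span, span
edges are extended while the raw per-window mode still agrees with that state
(recovering boundary windows the smoothing eroded), and spans of ≥`min_windows`
(default 3) become calls. On the default 16-sample, 10⁴-window panel at ~20×
(λ = 40) this recovers 93–95% of implanted CNVs with the correct integer copy number
at ≥50% reciprocal overlap across seeds, with essentially zero false calls on an
all-diploid panel (≤2 calls per 160,000 sample-windows). The hardest state is cn = 3
(single-copy gain), whose per-window evidence is weakest; pooling across windows is
what makes it recoverable.

## CNVR construction

Two calls are linked when their reciprocal overlap — overlap length divided by each
call's own length — reaches the threshold t (default 0.5) in **both** directions.
CNVRs are the connected components of this link graph evaluated on the original
calls (single linkage, not iterative re-merging of grown spans): this is
deterministic, order-independent (tested over shuffles), equals a brute-force
all-pairs oracle, and naturally allows two distinct CNVRs to overlap physically
without being merged — which is why the sum of CNVR sizes can exceed their unique
union span, a signature real CNVR tables show. Whether historical analyses used
single linkage or iterative re-merging is usually unstated; single linkage is the
reproducible choice. Gene overlap counts any ≥1-bp intersection, ignores strand
(copy number is strandless), and converts GFF3's 1-based closed coordinates to the
package's internal 0-based half-open convention at the file boundary.

## Expression activity

Each sample's log2 intensity distribution is standardised and fitted with a
two-component Gaussian mixture by a deterministic 1-D EM initialised from the 25th
and 75th percentiles; the activity score u is the posterior probability of the
higher-mean component. Standardisation plus quantile initialisation makes scores
exactly invariant to shifting or rescaling a sample (tested at 1e−6) and removes
any dependence on a random seed. When the fitted components are not separated
(means within 0.2 pooled sd) the sample falls back to rank-based scores with a
warning. This replaces platform-covariate activity models (UPC/SCAN) with the same
score semantics — a number in [0, 1], threshold rule "u > 0.3 in at least one
sample", strict inequality per the usual wording. On matrices with a planted
active/inactive structure (means 10 vs 6, sd 1) classification accuracy at u > 0.5
exceeds 95%.

## Over-representation

The classic binomial test: for a list of n genes from a reference of N with K in
the category, E = nK/N, FE = k/E, and p is the upper binomial tail P(X ≥ k) for
over-represented categories and the lower tail for depleted ones (k < E) —
era-appropriate for annotation tools and reproducing printed p magnitudes (the
protein-folding-style row: binomial tail within 10% of the printed value, and
within 5% of the Poisson tail at λ = E). A hypergeometric option is provided.
Bonferroni correction uses m = categories actually tested (K > 0).

## Synthetic-data generator: what it does and does not emulate

Defaults are the study-shaped conditions: 148 animals, gain mean 150 ± 25 kg and
intake 950 ± 180 kg with correlation 0.6 (the realized gain–intake correlation is
not a published quantity; 0.6 is a typical value for growing cattle and is
configurable, not a claim), which places top-ranked quadrant extremes near the
reported group means; 24,431 genes on 16 arrays with 2% DE at 1–2 log2 units
against 0.3 log2-unit residual sd; a 16-sample panel of 10⁴ contiguous 300-bp
windows (3 Mb of targets on a 30-Mb genome — an exome-like 10% target fraction) at
40 reads/window (the yield of a 20× exome with 150-bp reads), CNVs of 4–12 windows
drawn from copy numbers {0, 1, 3, 4}, shared by 2–4 samples with probability 0.4,
totalling 0.45% of the genome; qPCR noise 0.15 Cq per replicate. A single integer
seed drives named substreams, so each generator is reproducible in isolation and
regeneration is byte-identical.

Not emulated: probe-level array signal and normalization chemistry, GC and capture
bias in coverage, overdispersion beyond Poisson (a negative-binomial stress switch
was considered and left out of scope; counts are Poisson by construction), breed
genetic structure, and linkage between the expression matrix and the read-depth
panel (in the real design the CNV reference population is a different animal set
anyway). Passing tests therefore demonstrate correctness of the statistical
machinery under the stated models, not robustness to platform artefacts.

## Numerical choices and degenerate inputs

- BH step-up uses a stable mergesort ordering; q capped at 1 and monotone by a
  reverse cumulative minimum.
- |r| ≥ 1 − 1e−12 in the bivariate ranking raises (degenerate normal) rather than
  producing infinite distances.
- ANOVA sums of squares guard tiny negative within-group values from cancellation.
- EM stopping: relative log-likelihood change < 1e−6 per window or 200 iterations.
- Posterior-mode ties resolve toward diploid; empty call sets, empty quadrants and
  malformed annotation rows raise or warn explicitly instead of propagating NaN.
- Problem sizes in tests and the acceptance script (10⁴ genes / 10⁴ windows /
  2×10³-gene demo runs) are the package's chosen desk-scale defaults; they keep the
  full suite under a minute while leaving every statistical property measurable.

## Known limitations

- The CNV caller's absolute calling behaviour depends on the diploid depth; below
  ~20 reads/window single-copy gains become hard to segment with 3-window pooling.
- Fold change in the DE output is reported as the maximum pairwise LS-mean
  difference (log2), a definition that should be stated when comparing against
  tables that define fold change differently.
- The enrichment module tests annotations the user supplies; it ships no ontology
  database.
- CNVR acceptance covers the merging rule and summary arithmetic; reproducing any
  specific study's CNVR count would require its raw read data.
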