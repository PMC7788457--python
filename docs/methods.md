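# Methods

## The separation-run test

### Model

A grouped time course consists of *T* ordered timepoints, each carrying
n₁ + n₂ real-valued replicate measurements with fixed group membership
(A/B). The null hypothesis is exchangeability of the group labels at
every timepoint, with timepoints treated as independent. Under this
null, and assuming continuous data (no ties), the probability that one
particular group occupies all the top ranks at a single timepoint is
P₁,ᵤ = 1/C(n₁+n₂, n₁); perfect separation in either direction has
probability P₁,ᵦ = min(1, 2·P₁,ᵤ). Both are computed in exact rational
arithmetic (`fractions.Fraction` over `math.comb`) and converted to
float only at the API boundary.

The test statistic is the longest run of consecutive timepoints that
perfectly separate in one common direction. Its closed-form scan
p-value fixes the run's direction at the first run timepoint
(bidirectional probability) and uses the unidirectional probability for
each continuation; each of the T−k non-initial start positions is
weighted by (1 − P₁,ᵤ) for the preceding timepoint not separating:

    P = P₁,ᵦ · P₁,ᵤ^(k−1) · (1 + (T−k)(1 − P₁,ᵤ))

For n₁ = n₂ = 3 this evaluates to 29/40000 = 0.000725 at (T,k) = (5,3)
and 0.0004875 at (4,3).

### Oracles and their relationship to the closed form

Two independent routes check the closed form:

* an exact dynamic program over the state (current run direction,
  current run length capped at k), with each timepoint up/down/neither
  with probabilities (P₁,ᵤ, P₁,ᵤ, 1−2P₁,ᵤ), run in rational arithmetic;
* a Monte-Carlo simulator that draws fresh continuous values per
  timepoint and applies the actual rank comparison, thereby also
  validating the single-timepoint probabilities themselves.

For k = T the closed form and the DP coincide exactly. Away from that
boundary the closed form is in principle an approximation (it weights
non-initial starts by "previous timepoint does not separate in one
direction" rather than conditioning on the full history), but across
the short-series regime n₁ = n₂ = 3, 3 ≤ k ≤ T ≤ 10 the two agree
within 2% relative — and at the designs of interest, (5,3) and (4,3),
they agree *exactly*, as full enumeration of all 3^T state sequences
confirms. The closed form is what the test reports as its p-value; the
DP value is carried alongside in every result.

An alternative reading of the start-position weight — (1 − P₁,ᵦ)
instead of (1 − P₁,ᵤ) — cannot be excluded on theoretical grounds; the
printed formula with (1 − P₁,ᵤ) is implemented because it is the one
that reproduces both published values, and the DP oracle bounds the
difference.

### Decisions on degenerate data

* Any tie across the two groups voids separation at that timepoint
  ("none"): the rank argument assumes continuous data, so ties are
  resolved conservatively.
* A series with no separating timepoint reports k = 0, direction
  "none", and p-values of 1.
* The longest run wins; on ties in length, the earliest run.
* Unequal per-timepoint group sizes are rejected, not accommodated.
* P-values are displayed rounded to four decimals (the reporting
  convention); full precision is retained internally and in JSON
  output.

## Enrichment

DEG filtering uses strict inequalities: padj < α (default 0.05) and,
when a strong-signal filter is requested, |log₂FC| strictly above the
cutoff (default 0.5 when used). The hypergeometric overlap test
restricts both the DEG set and the gene set to an explicit background
and reports the inclusive upper tail P(X ≥ x); x = 0 returns p = 1
exactly. Backgrounds are always caller-supplied because different
comparisons legitimately use different universes (all measured genes
versus the genes assignable to a given transcriptome assembly).

The directional layer tests, within the DEG/set overlap, whether more
genes are regulated in one direction than the DEG universe as a whole
would suggest: d successes among m directed overlap genes against
X ~ Binomial(m, p₀) one-sided (P(X ≥ d)), with the ground probability
p₀ equal to the empirical directional fraction over all DEGs. Genes
with log₂FC exactly 0 carry no direction and are excluded from both
numerator and denominator (the symmetric choice).

Benjamini–Hochberg adjustment is implemented directly as the step-up
definition (sort, scale by m/i, cumulative minimum from the top, cap at
1, restore order) and cross-checked against statsmodels. Note that the
step-up map is *not* idempotent in general — (0.1, 0.3) adjusts to
(0.2, 0.3), which re-adjusts to (0.3, 0.3); re-adjustment is
inflationary, and constant vectors are its fixed points.

Both tail probabilities are evaluated through scipy's exact
distribution functions; the test suite pins them against combinatorial
enumeration (all K-subsets for N ≤ 12; all 2^m outcomes for m ≤ 12).

## ID mapping

Coordinates are 0-based half-open everywhere inside the package; GFF3
(1-based inclusive) is converted at a single site in the reader.
Alignment filters are inclusive (coverage ≥ 0.9 AND identity ≥ 0.9 by
default, matching "min-" threshold semantics). Reciprocal overlap at
fraction f requires a strictly positive shared length that is ≥ f of
*each* interval's length; strand is ignored, as with the default
behaviour of interval-intersection tools when no strand flag is given.

A transcript's candidate genes are collected over all of its alignment
records (so a multi-record/chimeric transcript straddling two genes is
ambiguous). Exactly one candidate → assigned; several → dropped
entirely (the strictest reading of discarding duplicated gene
assignments); none → unassigned. An optional `keep_best` mode instead
keeps the candidate with the largest overlap length and drops exact
ties; it is off by default. Gene-level duplication after set
translation is handled separately by de-duplicating mapped ids, and
unmapped ids are reported rather than silently dropped. The interval
index (an interval tree per chromosome) is checked against an
all-pairs brute-force scan in the tests; results are independent of
input order.

The isoform-appendix normalizer strips one trailing
underscore-plus-digits suffix by default; the exact appendix format
varies between assemblies, so the pattern is a configurable argument
rather than a hard-coded truth.

## Normalization and quantification

*Size factors* follow the median-of-ratios convention: the per-gene
reference is the geometric mean across samples computed on genes with
strictly positive counts everywhere; each sample's factor is the median
ratio to the reference. A matrix with no all-positive gene is an error.
Because the reference itself includes every sample, multiplying one
sample by c rescales *all* factors by c^(1/m) in addition to the scaled
sample's factor by c — the invariant that holds exactly (and is tested
at 1e-12) is therefore equivariance of factor *ratios*.

*Row z-scores* use the sample standard deviation (n−1). Constant rows
are mapped to zeros with a warning rather than NaN, so downstream
heat-map matrices stay finite. Single-column input is an error.

*ΔΔCt*: ΔCt = Ct(target) − Ct(reference) per sample; ΔΔCt subtracts the
arithmetic mean ΔCt of the control group; fold change is E^(−ΔΔCt) with
amplification efficiency E = 2 (perfect doubling) by default, or the
two-efficiency ratio form (each primer's Ct centred on its control
mean) when per-primer efficiencies are supplied. Control folds have
geometric mean 1 by construction.

*X1 fraction*: 100·X1/(X1+X2+Xins) over the FACS gate percentages.

## Synthetic data

The generators emulate the statistical structure the analyses consume,
with every quantity of interest planted and recorded in a truth object:

* **Time courses**: group A ~ N(0, σ²), group B shifted by the
  per-timepoint effect in σ units; defaults T = 5, n₁ = n₂ = 3 — the
  design of the expression series the run test was built for — with all
  effects 0 (the null). A batch variant generates 10⁵ series in one
  vectorized draw for calibration studies.
* **DEG tables**: defaults of 6,339 true DEGs with down-proportion
  0.5534 in a 20,000-gene universe (the scale of the planarian X1
  comparison; the universe size is of the order of the genes assignable
  to one transcriptome assembly). True DEGs draw p ~ Beta(a, 1) with
  a = 0.1 — a conventional enriched-small-p model, declared rather than
  inferred, since the analysis only consumes sign and threshold — and
  log-normal fold-change magnitudes; nulls draw uniform p and small
  symmetric fold changes. Adjusted p-values come from the package's own
  BH step-up. At these defaults BH detects roughly two thirds of the
  true DEGs, so calibration checks that condition on the *detected* set
  carry correspondingly more sampling noise than the planted K would
  suggest.
* **Gene sets**: null sets are uniform draws without replacement from
  the universe (exact hypergeometric sampling, so the null-calibration
  check is clean); enriched sets draw their DEG-member count from
  Binomial(set_size, ρ·K/N) — the per-member DEG probability inflated
  by ρ, infeasible ρ rejected with the maximal feasible value — and a
  directional-bias parameter δ fixes the down-fraction among DEG
  members. The default set size of 800 matches the scale of the largest
  single published stem-cell set used for overlaps (~823 genes); a
  discrete test's attained level only approaches the nominal 0.05 for
  sets of this size, which is what makes a nominal-level calibration
  check meaningful.
* **Genome fixtures**: non-overlapping genes on a toy chromosome;
  unique transcripts get jittered intervals (jitter ≤ 10% of gene
  length, which keeps reciprocal overlap well above 0.5 and below it
  for every neighbour); sub-threshold transcripts draw coverage or
  identity in [0.5, 0.89]; ambiguous transcripts span exactly half of
  each gene in a contiguous equal-length pair — the only geometry in
  which one interval reciprocally overlaps two disjoint genes at
  f = 0.5 (on the inclusive boundary).

What the generators deliberately do **not** model: read-level noise,
count distributions (negative binomial dispersion), correlated genes,
exon structure, or assembly-specific artefacts. Passing tests therefore
demonstrate correctness of the statistics and bookkeeping on data
satisfying the tests' own assumptions, not robustness to the violations
real data exhibit (dependent timepoints, correlated gene sets,
mis-assembled transcripts).

All randomness flows through `numpy.random.default_rng` with explicit
seeds, one stream per generator call; emitted files are byte-identical
across runs.

## Problem sizes in the test suite

Monte-Carlo checks use 10⁶ simulations per design point; null
time-course calibration uses 10⁵ series; enrichment calibration uses
2,000 sets over a 20,000-gene universe; interval-index cross-checks use
a few hundred intervals; the end-to-end pipeline test runs a reduced
universe (hundreds of genes). These sizes keep every binomial
3-standard-error band decisively narrower than the effects being
checked while the whole suite runs in well under a minute per heavy
test.

## Pipeline and CLI

The library is the primary interface; the CLI is a thin click layer.
Pipeline runs are described by one declarative YAML config (unknown
keys rejected; all violations reported together), execute stages in the
fixed order simulate → idmap → enrich → septest → normalize (+ ddct,
x1), and end with a JSON report containing the version, the config
echo and the seed — sufficient to reproduce the run. Logging goes to
stderr; data go to files or stdout.
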