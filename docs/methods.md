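# Methods

## Design

`triohet` analyses a trio design: one hybrid group and its two parent
species, with ≥2 replicates per group (3 by default in simulations), in one
or more tissues. Samples are addressed by *role* (hybrid / paternal_parent /
maternal_parent), never by species name, so a mule trio (horse sire, donkey
dam) and a hinny trio (donkey sire, horse dam) run through identical code.

All genomic intervals are 0-based half-open everywhere — in memory, in the
event table, and in BED12 (natively 0-based, so no conversion exists
anywhere in the code base).

## Differential expression

A deliberately minimal self-contained negative-binomial test:

- **Normalization** — median-of-ratios size factors over genes positive in
  every sample, rescaled to geometric mean 1. The median is taken on the
  linear ratio scale (the definition), not on log ratios: the two differ
  when an even count of reference genes forces the median to average two
  values. If no gene is positive everywhere the computation refuses and
  suggests a pseudo-reference fallback rather than silently degrading.
- **Dispersion** — per-gene method of moments under Var = μ + αμ². The
  pooled within-group variance has expectation
  Σ_g (n_g − 1)(μ_g + α μ_g²) / Σ_g (n_g − 1), so the moment equation
  divides by the dof-weighted mean of *squared group means*; dividing by
  the squared overall mean (the more commonly quoted form) is biased
  upward exactly for the genes with real between-group effects, costing
  power where it matters most. Because raw moment estimates at 2–3
  replicates are extremely noisy and a downward-noisy α̂ makes the Wald
  test anti-conservative, every estimate is floored at the median of the
  positive per-gene estimates. This floor is the package's one-number
  stand-in for the dispersion-shrinkage curves of full-featured DE tools;
  it deliberately sacrifices power for genes with genuinely low dispersion
  in exchange for honest type-I error at small n (measured ≈ 0.05 at
  nominal 0.05 on conserved-only simulations; see
  `tests/test_acceptance.py`). In the trio classifier the dispersion is
  estimated once per gene from all three groups and shared by every
  contrast — more degrees of freedom, and the gene's variance model cannot
  disagree between contrasts.
- **Test** — Wald statistic on log2 of the normalized group-mean ratio with
  a delta-method standard error, two-sided normal p, BH adjustment within
  each comparison. A group mean of exactly zero is floored at half a count;
  a gene all-zero in both groups gets p = 1, log2fc = 0. The *reported*
  fold change adds a 0.5 pseudocount for display stability; the statistic
  itself uses the unpadded fitted means.
- **Calling** — up if padj < 0.05 and log2fc > 1; down if padj < 0.05 and
  log2fc < −1; both inequalities strict, matching the printed convention.
  "Up" always means hybrid above parent (or paternal above maternal).

Not modeled, by intent: covariates, shrunken fold changes, outlier
refitting.

## Differential alternative splicing

ψ = (I/lI) / (I/lI + S/lS), where I and S are junction reads supporting
the inclusion/skipping forms and lI, lS the effective lengths (read
positions able to support each form). A sample's ψ is *missing* when
I + S < 10 (configurable); an event is untestable in a group when every
replicate is missing.

The two-group test treats replicates as exchangeable binomial draws: the
success probability is the length-weighted inclusion rate
p(ψ) = ψ·lI / (ψ·lI + (1−ψ)·lS), which is a monotone reparameterization of
ψ, so the group MLE is the pooled count fraction p̂ = ΣI/Σ(I+S) in closed
form and ψ̂ follows by inversion — no numeric search is needed, and with
lI = lS the MLE reduces to the pooled inclusion fraction. The
likelihood-ratio statistic 2(ℓ1 − ℓ0) (free ψ per group vs one shared ψ)
is referred to χ²₁; BH across testable events; an event is called when
|Δψ| > 0.10 (strict) and FDR ≤ 0.05 (inclusive), exactly the printed
boundary conventions. Replicate-level overdispersion in ψ is *not*
modeled; this is the main simplification relative to hierarchical splicing
models, and on data with strong biological replicate scatter the test will
be anti-conservative. Folding length normalization into the success
probability (rather than rescaling counts) keeps the likelihood an exact
integer-count binomial.

## Gene-action classification

Relations come from BH-adjusted tests: "equal" means not significant at α
(default 0.05) — the only operational reading of the =, >, < comparisons
when the inputs are DE/DAS results. An untestable contrast (NaN p) is
"equal". The decision sequence (conserved → over → under → high-parent →
low-parent → additive → other) makes classification a total, deterministic
function; the order resolves the overlaps the verbal definitions leave
open (e.g. H = P with P > M while H > M satisfies both a dominance and no
other reading — precedence makes the outcome unique). The classification
is symmetric under relabeling the parents by construction, verified
exhaustively over all 3⁴ relation combinations.

The mid-parent test backs the "additive" call: for expression, a Wald test
of log2 mean_H against log2 ½(mean_P + mean_M) with the delta-method SE
under the NB fit; for ψ, a likelihood ratio pinning the hybrid's ψ at
½(ψ̂_P + ψ̂_M). Mid-parent p-values are BH-adjusted across features like
any other contrast family.

Summaries count only non-conserved ("classified") features; percentages
are per-mode shares of that denominator, rounded half-away-from-zero to
one decimal at print time only. Aggregates reported: non-additive total,
over+under (outside the parental range) and high+low (parent-tracking)
sums.

## Long-read verification

A called event claims two expressed isoforms. A read *matches* a chain
when its intron junctions, restricted to the event span, equal the chain's
junctions with every donor/acceptor boundary within ±10 nt (long reads
carry alignment wobble at splice sites; the tolerance is configurable). A
junction-less chain (retained-intron inclusion form) matches when one read
block covers the whole span. Genes roll up from their called events: a
gene is *covered* when any read overlaps any called event's span on the
same chromosome and strand, *verified* (default `both_isoforms`) when at
least one called event has each chain supported by ≥1 read. The laxer
`any_isoform` criterion — either chain suffices — is available as a flag
for sensitivity analysis and is never stricter. The headline percentage is
round(100·verified/covered), half away from zero, undefined (not zero)
when nothing is covered.

## Enrichment

Upper-tail hypergeometric P(X ≥ k) for a query of n genes against a set of
K in a universe of N — identical to one-sided Fisher's exact on the 2×2
table (asserted to 1e-12 in tests) — with BH across sets. Gene sets come
from local GMT files; whatever ortholog mapping the caller needs is theirs
to apply before building the GMT, which keeps results independent of any
web service's database snapshot. Universe defaults to the count matrix's
genes; sets below 3 members are skipped (configurable).

## Correlation clustering

Expression correlations use log2(normalized count + 1); ψ correlations use
the PSI matrix as-is with pairwise-complete handling of missing values.
Pearson correlation, average-linkage clustering on 1 − r. The transform
and linkage are package choices (commonly used, not canonical). A
zero-variance sample is an error naming the sample, not a NaN propagated
into the tree.

## Synthetic data

The generator emulates the trio study at desk scale:

- **Counts** — NB(mean = s_j · μ_{g,group} · t_{g,tissue}, dispersion α)
  with variance μ + αμ². Per-gene baselines are log-normal (default median
  200, log-sd 1); library factors s_j log-uniform in (0.8, 1.25); α = 0.1.
  Group means encode the planted mode: additive puts the hybrid on the
  arithmetic mid-parent of parents separated by the full planted effect
  (default 2 log2 units, which parent is high being random); high-/low-
  parent dominance pin the hybrid to one parent; over-/under-dominance
  move the hybrid one full effect beyond equal parents; conserved genes
  have identical means. With more than one tissue every gene gets an
  independent per-tissue log2-normal offset (sd 2 by default) shared by
  all groups, making tissue the dominant axis of variation as in real
  multi-tissue designs.
- **Splice events** — planted group ψ values follow the same mode logic on
  the ψ scale with separation `delta_psi_planted` (default 0.3), kept
  inside (0.02, 0.98) by construction so the planted separation survives
  clipping. Per sample, total junction coverage is Poisson (default mean
  200) and the inclusion count binomial with the length-weighted rate.
  Chains are structurally valid skipped-exon layouts by default (all five
  event classes available), spaced along one synthetic contig.
- **Long reads** — per event, a Bernoulli "uncovered" draw, then
  Poisson(depth) reads copying the inclusion chain with probability ψ_H
  and the exclusion chain otherwise.

One master seed feeds named substreams (counts / events / reads), so each
stage is reproducible in isolation and adding one stage never perturbs
another. Everything the generator does *not* emulate bounds what passing
tests show about real data: no sequence content or mapping error, no GC or
length bias, no replicate-level ψ overdispersion, no correlation between
genes, no isoform structure beyond two chains per event. Recovery rates on
this generator are therefore upper bounds for real tissue.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` measure calibration at 2000
genes/events with 3 replicates per group and recovery at mean coverage
1000 (log-sd 0.35, i.e. essentially all genes ≥ 500 normalized counts) —
sizes at which the measured quantities are stable across seeds yet the
whole suite runs in seconds. Dispersion floors at 1e-8; BH is the textbook
step-up with enforced monotonicity; ψ likelihood kernels use 0·log 0 = 0;
percentages round half away from zero. The mid-parent mean in the
expression test is floored at a quarter-count to keep the log defined for
all-zero parents.

## Known limitations

- The Wald test's normal reference is optimistic at 2 replicates; the
  dispersion floor compensates empirically at 3, which is where the
  calibration is verified.
- The splicing test ignores replicate-level ψ variance (see above).
- "Additive" recovery is intrinsically weaker than the other modes: with a
  mid-strength hybrid, one of H-vs-P / H-vs-M is often borderline, and the
  precedence rules then route the gene to a dominance class. The planted-
  recovery guarantees target over-/under-dominance and high-/low-parent
  dominance.
- Enrichment results depend entirely on the supplied GMT; no database is
  bundled.
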