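# Methods

## Mark mixture model

The annotation model treats the genome, one tissue at a time, as a mixture
of functional and non-functional basepairs.  A latent indicator Z (prior
π = P(Z = 1)) selects one of two product-Bernoulli distributions over the
eight binary mark indicators (seven histone modifications plus DNase I
hypersensitivity), giving 17 free parameters per tissue.  Conditional
independence of marks given Z is an explicit modeling assumption: marks are
certainly correlated along the genome, but the mixture only needs the
*pattern* of co-occurring marks to separate annotation-rich from
annotation-poor positions, and the posterior P(Z = 1 | A) is driven by the
likelihood ratio of the two components.

Because observations are 8-bit patterns, all likelihood computation is done
on the ≤256 distinct patterns with basepair multiplicities.  This is an
algebraic identity with per-site computation, not an approximation, and it
makes EM iterations O(256 · 8) regardless of genome size.  The test suite
asserts exact (bitwise) agreement between pattern-table evaluation and naive
per-bp evaluation.

**Training data.**  Parameters are fitted on windows around seed positions
(by default 1 kb windows: 500 bp flanks on each side, the symmetric reading
of "1 kb around a position").  Overlapping windows are merged so each
basepair contributes exactly one observation.  In real use the seeds are
trait-associated SNPs from a GWAS catalog — a sampling scheme that enriches
for functional neighbourhoods while still containing plenty of background —
and in the synthetic workspace the simulated GWAS table plays the same role.

**EM details.**  Initialization draws p₁ ~ U(0.5, 0.9) and p₀ ~ U(0.05, 0.3)
per mark with π = 0.5; five random restarts are run and the best final
log-likelihood kept (the likelihood surface is mildly multimodal, and
restarts are cheap at 256 patterns).  Convergence is declared when the
relative log-likelihood change drops below 1e-8, with a 1000-iteration cap.
Rates and π are clipped to [1e-6, 1 − 1e-6] after each M-step so that no
pattern ever gets zero likelihood.  After fitting, components are relabeled
if needed so that the "functional" component is the annotation-rich one
(mean p₁ ≥ mean p₀); without this the labeling is arbitrary.  Data
containing a single distinct pattern is rejected as uninformative.

**Score tracks.**  Genome-wide posteriors are stored run-length encoded;
positions not covered by any run score 0, matching the reading that absence
of any mark signal is evidence of non-functionality.  Binarized annotations
(score ≥ cutoff, default 0.5) can be exported as BED for downstream
heritability-partitioning tools.  Coordinates are 0-based half-open
everywhere in memory; all supported formats (BED, narrowPeak, bedGraph) use
the same convention so no conversion happens at boundaries.

## P-value mixture and SNP scores

A SNP is in exactly one of three states: trait- and tissue-functional
(case I), tissue-functional but trait-irrelevant (case II), or not
tissue-functional (case III).  The score of interest is the posterior of
case I given the SNP's GWAS p-value.

* The per-SNP prior t = P(Z_T = 1) is the mean tissue score over the
  surrounding 10 kb window (clipped at chromosome ends, uncovered bp = 0).
  The window mean, rather than the point score, absorbs local uncertainty
  about which SNP in an LD neighbourhood tags the functional element.
* SNPs are partitioned at a mean-score threshold of 0.1.  The low partition
  estimates the case-III p-value density f(p | Z_T = 0); the analogous
  partition on a *general* (non-tissue) functionality track estimates
  f(p | Z = 0), which by assumption also serves as the case-II density:
  tissue-functional but trait-irrelevant SNPs behave like any other
  trait-irrelevant SNPs.  When scores are well separated the priors are
  bimodal and the partition is insensitive to the exact threshold.
* Null densities are equal-width histograms on [0, 1].  The bin count is
  chosen by 10-fold cross-validation over candidate counts
  {5, 10, 20, ..., 200}, maximizing mean held-out log-likelihood, ties to
  fewer bins; each training histogram gets a +0.5 pseudocount per bin and is
  renormalized.  Folds are assigned per distinct p-value (grouped
  assignment) so tied or duplicated observations never appear on both sides
  of a split, which would bias selection toward overfine binning.
* Case-I p-values follow Beta(α, 1) with 0 < α < 1, density αp^{α−1} — the
  standard monotone-density approximation for association p-values under
  modest effect sizes.  On the high-prior partition an EM with closed-form
  updates (w = mean responsibility, α = −Σr / Σ r·log p) fits α and the
  global weight w = P(Z_D = 1 | Z_T = 1).  α is clipped into
  (1e-4, 1 − 1e-4); p-values are clipped to [1e-300, 1] before any density
  evaluation so log p stays finite.
* The GSP score is then
  f_sig(p)·w·t / [f_sig(p)·w·t + f_gnull(p)·(1−w)·t + f_tnull(p)·(1−t)];
  the three case posteriors sum to one by construction.  w is a single
  global constant per (trait, tissue) while t varies per SNP.  The NSFP
  score is the two-case analogue with prior g = prior_general · w_general.
* If no general track is supplied, the tissue track is substituted with a
  warning; NSFP then becomes a same-track baseline rather than an
  independent comparison.
* SNPs with p = 1 are retained (the beta density there equals α).

One modeling tension is accepted deliberately: f(p | Z_T = 0) is estimated
from a *hard* low-prior partition yet applied with the *continuous* per-SNP
weight (1 − t).  With bimodal priors the mismatch is negligible; with weakly
separated scores both the partition and the weighting blur together, and
the fitted w shrinks accordingly (visible in the synthetic workspace, where
10 kb window averaging over ~1 kb functional segments dilutes the prior).
The ranking behaviour — the property that matters — is robust to this, and
is what the acceptance checks measure.

## Locus analytics

Per risk locus and tissue, the *local maximum GSP* is the largest GSP among
SNPs inside the locus; the tissue attaining the overall largest value is the
predicted relevant tissue.  Maxima within 1e-4 of the top (the reporting
precision of the posterior) are declared ties and the locus is flagged
rather than assigned.  Rank comparisons use competition ranking (ties share
the minimum rank), take the best rank per locus, and compare two schemes
with an exact one-sided binomial sign test at 1/2, dropping loci whose
ranks are identical under both schemes.  Enrichment curves report
[(targets in top N)/N] / [targets/total] over a grid of N.

## Synthetic data

The generator is the package's study-condition definition, not a test rig:
it produces data *from the assumed models* so that estimator correctness can
be checked against planted truth.  Defaults: 1 Mb single-chromosome genome,
two tissues, functional fraction 0.10 in segments of geometric length
(mean 1 kb), mark rates p₁ = 0.7 / p₀ = 0.05 (well-separated components, as
consolidated peak calls are), 10,000 SNPs placed uniformly, α = 0.3,
w_cond = 0.3.  Marks are drawn block-wise (constant within a segment per
mark) so peak files contain realistic contiguous intervals; the per-bp
marginals are unchanged but effective sample sizes for marginal checks scale
with block count, which the tests account for.  A single seed drives
deterministically derived per-stage substreams, so workspaces are
byte-identical across runs.

What the generator does **not** emulate: linkage disequilibrium (p-values
are independent given functionality), minor-allele-frequency structure,
mark-mark correlation beyond what Z induces, chromatin-state diversity
(one functional state), and peak-calling noise.  Passing tests therefore
demonstrate estimator correctness under the model's own assumptions — not
performance on real consolidated epigenomes, where LD and model
misspecification matter.

## Numerical choices

* Mixture likelihoods are computed in log space with max-subtraction; exact
  equality between pattern-lookup and per-bp scoring is asserted, not
  approximated.
* EM monotonicity is tested at relative tolerance 1e-9.
* The Haldane–Anscombe +0.5 correction on all four cells keeps pairwise
  overlap log odds finite for identical or disjoint tracks.
* Score tracks serialize with `repr` floats, so write/read round-trips are
  bit-exact; the same holds for parameter and model files.
* Window means use prefix sums over runs; interval unions, thresholds and
  overlays are array operations on sorted endpoints, each cross-checked
  against dense per-bp oracles on toy genomes in the test suite.

## Problem sizes

Test-suite and acceptance computations use desk-scale inputs chosen to make
the statistical checks sharp but cheap: 100 kb–1 Mb genomes, 2,000–50,000
p-values, n = 200,000 mark vectors for parameter recovery.  At these sizes
the whole suite runs in seconds; all pattern-space algorithms are
genome-size-independent per EM iteration, so the same code runs at full
genome scale.
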