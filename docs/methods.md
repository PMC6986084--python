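# Methods

This note documents the statistical models, default parameters, numerical
choices and known limitations of `aponet`. Everything quantitative stated
here is computed by the test suite or `scripts/acceptance.py`; nothing is
asserted that the code does not measure.

## Study design and data model

The pipeline targets a multi-class clonal design: phenotypic classes
(default: sexual diploid `2X_sex` with 2 genotypes, apomictic tetraploid
`4X_apo` with 3, sexual tetraploid `4X_sex` with 1), three clone replicates
per genotype, one tissue (leaf). The primary container is a transcripts ×
samples matrix of non-negative values (counts or FPKM) with per-transcript
lengths; metadata assigns each sample a genotype, clone, tissue and class,
and each genotype belongs to exactly one class.

FPKM is `10⁹·C/(N·L)` with `N` the column sum of the count matrix. We use
raw column sums rather than effective mapped-fragment counts; quantification
internals are out of scope.

**Class specificity.** A transcript is *expressed in a class* when its value
exceeds `epsilon` (default 0, i.e. strict positivity) in at least one sample
of **every** genotype of the class. This within-class-consistency rule is
deliberate: a transcript detected in only one genotype of a class says more
about the genotype than the class. A looser any-sample rule is available
(`require_all_genotypes=False`). Each expressed transcript falls in exactly
one Venn cell (the subset of classes detecting it); singleton cells are the
class-specific sets.

## Empirical-Bayes differential expression

### Model

Counts `x_gi ~ NB(r_g·s_i, q_g)` with median-of-ratios size factors `s_i`
and a shared `Beta(α, β)` prior on `q_g`. Integrating `q` gives the
beta-negative-binomial marginal over a sample set `S`:

    log f(x_S) = Σᵢ [lnΓ(xᵢ+rᵢ) − lnΓ(rᵢ) − lnΓ(xᵢ+1)]
               + ln B(α+Σrᵢ, β+Σxᵢ) − ln B(α, β)

Equal expression shares one `q` across both groups (`f_EE` over all
samples); differential expression draws an independent `q` per group
(`f_DE = f(S_A)·f(S_B)`). A two-point mixture with weight `p_de` on DE is
fitted by EM:

* E-step: `PPDE_g = p·f_DE / (p·f_DE + (1−p)·f_EE)` in log space;
* M-step: `p_de ← mean(PPDE)`; `(α, β)` maximized on the log scale by
  bounded L-BFGS-B over the posterior-weighted sum of log marginals;
* convergence: `|Δp_de| < 1e-4` and relative Δlog-likelihood `< 1e-6`,
  at most 50 iterations; the observed-data log likelihood is asserted
  non-decreasing every iteration (generalized EM); non-convergence returns
  the last iterate with a warning.

Initial values: `α = β = 1`, `p_de = 0.05`.

### Dispersion estimation

The per-transcript sizes `r_g` are held fixed during EM. Dispersion
`φ = (v − m)/m²` is estimated by method of moments on size-factor-scaled
counts **within each condition** and combined by a df-weighted average —
pooling across conditions would absorb a genuine group shift into
overdispersion and mask the very signal being tested (in our harness that
failure mode collapses the EM to `p_de ≈ 0`). Because a handful of
replicates cannot pin down a gene's dispersion, gene-wise estimates are
moderated toward the ensemble median with prior weight equal to the
residual degrees of freedom before inverting to `r = 1/φ` (capped to
[1e-2, 1e3]; `v ≤ m` caps high, near-Poisson). On the 5,000-transcript
3 vs 3 harness this yields a null rate of PPDE ≥ 0.95 calls of ~0 and,
with 10% planted DE at |log2FC| = 2, a false-discovery proportion ≈ 0.01
at sensitivity ≈ 0.84 with fitted `p_de ≈ 0.13` (recomputed by
`scripts/acceptance.py`).

### Calls and the two-step workflow

DE status is posterior-based: `is_de ⇔ PPDE ≥ 0.95` (the mixture analogue
of FDR ≤ 0.05). The fold-change rule `|log2FC| ≥ 1.5` — computed as
`log2((m_A + 1)/(m_B + 1))` on size-factor-normalized group means with a
pseudocount of 1 — assigns the *overexpression direction* label
(`over_in_A` / `over_in_B`); a DEG whose attenuated fold change misses the
bar keeps `is_de` but no direction. Transcripts with all-zero counts across
both groups have no defined posterior and are excluded from the table with
a notice.

Step 1 tests every genotype pair within each multi-genotype class (clones
as replicates) and retains transcripts with PPEE ≥ 0.95 in **all** pairs —
the strictest reading of the pairwise scheme; a transcript all-zero in a
pair carries no evidence against equal expression and is retained by that
pair. Single-genotype classes skip step 1. The commonly expressed set is
the intersection over classes of retained-and-expressed transcripts; step 2
runs the pairwise class comparisons on it. Consistent DEGs are the
intersection of the DE sets of every comparison involving the focus class
(default `4X_apo`), i.e. DE against each sexual class regardless of ploidy.

When only FPKM is available the values are rounded to pseudo-counts so the
count likelihood stays valid; exact counts are preferred.

## Coexpression network

Built from FPKM after removing transcripts with zeros in more than half the
samples (strict inequality at the boundary). Pearson correlation uses the
signed cutoff `r ≥ 0.8` (an `|r|` option exists but is off by default);
constant transcripts are excluded. Candidate evaluation is chunked and
asserted equal to the full-matrix computation.

**HRR.** Each node ranks its candidate partners by descending `r`, ties
broken by ascending partner id (this makes the edge set deterministic and
input-order invariant); `HRR(i,j) = max(rank_i(j), rank_j(i))` and edges
with HRR ≤ 30 survive. HRR is symmetric by construction, and the limit
bounds node degree, keeping vicinities small.

**HCCA.** Every node seeds a 3-step node vicinity network; chiseling
repeatedly removes (in batch passes) every non-seed node with strictly more
edges leaving the current set than inside it, then keeps the connected
component containing the seed, which guarantees connected candidates. If
the chiseled set falls outside the size bounds the seed retries from
shallower vicinities (2, then 1 step) — the cluster-size control of the
chiseling approach; without it a dense graph whose 3-step vicinity spans
everything could only ever yield one cluster or none. Surviving candidates
are scored by internal-edge fraction `E_in/(E_in+E_out)` and accepted
greedily by descending score (ties: larger set, then lowest seed id),
skipping overlaps. Leftover nodes join the accepted cluster holding most of
their neighbors (ties: lowest cluster index) provided it is below `s_max`;
nodes with no clustered neighbor remain unassigned. Default bounds are
`s_min = 40`, `s_max = 200` for full-size networks; the synthetic tests use
10–100 via config since planted modules hold 30 transcripts.

**Subnetwork.** Seeds plus first neighbors with all induced edges; missing
seed ids are reported and skipped.

## Synteny candidates

Alignment hits in the 12-column tabular format are typed on parse;
malformed lines are collected with line numbers and only if more than 10%
of lines fail does parsing raise. Subject coordinates are 1-based inclusive;
`s.start > s.end` marks a minus-strand hit and the span is normalised before
overlap testing. A hit qualifies when its e-value is ≤ 1e-05 and its span
shares ≥ 1 bp with a marker-delimited interval on the same chromosome
(overlap, not containment — the flanking markers delimit a region, not
transcript bounds). Any qualifying hit makes its query an ACR transcript
(no best-hit collapsing). The marker pairs delimiting the region have no
published base-pair coordinates, so interval coordinates are user input;
the synthetic bundle fabricates its own. Seeds are
`ACR ∩ (specific ∪ DE)`, with provenance flags recording every
contributing source.

## Enrichment

One-sided hypergeometric upper tail `P(X ≥ k)` per GO term, exact via the
survival function; Bonferroni multiplies by the number of testable terms
(`K ≥ 1` in the background), and `p_adj ≤ 0.05` flags enrichment. The
background is selectable per call: the commonly expressed set for DEG
enrichment, the whole annotated transcriptome for the subnetwork. No
transcript-length probability weighting is applied; when lengths are
supplied and study/background mean lengths differ by more than 20% a
warning points out the uncorrected detection bias. GO-graph ancestor
propagation and semantic summarization are out of scope.

## Synthetic data generator

The generator is the package's benchmark instrument; its defaults are the
reference conditions for all recovery tests.

| parameter | default | rationale |
|---|---|---|
| n_transcripts | 2,000 | desk-scale stand-in for a 10⁵-transcript assembly |
| baseline mean | log-uniform on [5, 500] | spans low to high expression while keeping detection near-certain at 3 clones |
| nb_dispersion | 0.05 | moderate biological overdispersion (var = μ + 0.05 μ²) |
| genotype_sd | 0.1 (log scale) | mild but real genotype-level expression differences, so the within-class filter has genuine work |
| frac_specific | 0.10 / 0.02 / 0.005 (apo / 2X sex / 4X sex) | mirrors the ordering and rough proportions of class-specific sets in this kind of survey |
| frac_de, de_log2fc | 0.05, 2.0 | planted effects comfortably above the 1.5 reporting threshold before attenuation |
| n_modules × size | 5 × 30 | planted coexpression blocks |
| module_amplitude, noise | 1.0, 0.25 | expected within-module Pearson r ≈ 0.9 > 0.8 on the value scale |
| n_acr | 80 | half drawn from labelled (specific/DE) transcripts, half unlabelled, so the seed intersection is non-trivial both ways |

Counts are NB with a per-transcript log-uniform baseline, a per-(transcript,
genotype) log-normal effect shared by clones, zeroed means outside a
specific transcript's class, and ±`de_log2fc` shifts in each DE transcript's
target class (targets cycle over the classes; the apo-targeted ones are the
planted consistent DEGs). Fractions resolve to counts by floor; all sampling
is seeded; identical parameters give bit-identical output. Module members
are overwritten with `scale_g · exp(amplitude·z_s + ε)` sharing a latent
per-sample profile `z`; with zero noise, within-module correlations are
exactly 1. Annotation is uniform-random GO assignment (0–5 of 150 terms),
which makes enrichment a true null — the pipeline's enrichment stage is
expected to find nothing on synthetic data, and does.

What the generator does **not** emulate: read-level noise, assembly
artifacts and isoform redundancy, dropout, length-dependent detection bias,
correlated annotation structure, batch effects, and floret tissue (leaf
only by default). Recovery results on this benchmark therefore demonstrate
the pipeline's internal correctness and calibration, not performance on
real libraries.

## Problem sizes and runtime

The default suites use: 2,000 transcripts × 18 samples for the end-to-end
bundle; 5,000 × 6 for the EB operating-characteristics harness; 300
transcripts in 10 planted modules for clustering recovery; N ≤ 60 for the
exhaustive hypergeometric check. These sizes give stable statistics while
keeping the whole test suite under a minute of compute on one CPU; the
acceptance script completes in seconds.

## Known limitations

* The EB model fits a single (α, β) prior for all transcripts and a
  two-pattern (EE/DE) posterior only; multi-pattern designs and isoform
  uncertainty are out of scope.
* PPEE-based filtering with all-pairs stringency is conservative: ~15% of
  null transcripts per 3-genotype class fail at least one pair under
  genotype noise, and planted DEGs are subject to the same attrition.
* log2FC with a pseudocount of 1 attenuates fold changes of low-expression
  transcripts; direction labels can be missing for genuine DEGs near the
  detection floor.
* HCCA cluster bounds are configuration, not inference; the unassigned set
  can be large on sparse graphs (isolated nodes never cluster).
* Bonferroni is deliberately strict; with a random-GO null this is the
  correct behavior, but on real annotations a user may prefer FDR-based
  correction, which is not implemented.
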