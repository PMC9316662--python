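# Methods

## Background model for significantly mutated genes

Within one cancer type with `n_t` samples, the analysis unit is the vector
over genes of mutated-sample counts: `k_g` = number of samples with at
least one coding SNV in gene `g` (multiplicity within a gene does not
inflate `k_g`). These counts are overdispersed relative to Poisson —
per-gene mutability varies with sequence context, gene length and
chromatin state — and are modelled as negative binomial in the
"number of failures" parameterization (`scipy.stats.nbinom`):

    pmf(k) = C(k + r - 1, k) p^r q^k,   q = 1 - p,   mean = r q / p.

`r` is real-valued (gamma-function pmf), fitted by maximum likelihood with
`p` profiled out (for fixed `r` the MLE is `p = r / (r + mean)`), leaving a
1-D bounded optimization in `log r` started from the method-of-moments
estimate `r0 = m²/(v − m)`. The optimizer's log-likelihood is asserted
never to fall below the start. Degenerate inputs fail loudly: constant
vectors, and underdispersed vectors (`v ≤ m`, where the NB is not
identifiable and a Poisson model is advised).

Two diagnostics accompany every fit. The Cullen–Frey summary reports
sample skewness and raw (non-excess) kurtosis with a bootstrap cloud
(default 500 resamples) locating the data among candidate families;
Poisson and geometric log-likelihoods are reported alongside for
comparison, but the pipeline always proceeds with the NB — the diagnosis
is inspectable, not an automated model switch. Goodness of fit uses a
Cramér–von Mises statistic computed from the fitted discrete CDF at the
sorted data (`W² = 1/(12n) + Σ (F(x_(i)) − (2i−1)/(2n))²`); because the
parameters are estimated, the p-value comes from a parametric bootstrap
that redraws, *refits* and rescores under the fitted NB (default 199
replicates; fewer than 100 triggers a warning).

A gene is a candidate in a cancer type when its tail probability
`P(X ≥ k)`, computed through the NB survival function (regularized
incomplete beta), falls strictly below `alpha = 0.001`. The inclusive tail
`P(X ≥ k)` is the default (slightly conservative); `P(X > k)` is available
via `tail="gt"` since the choice between the two conventions is not
determined. Ties at the threshold are excluded. Genes with zero mutated
samples are included in the fitted vector by default (excludable by flag).
The clustering feature set is the union of candidates across cancer types.

No multiple-testing correction is applied at this stage: the 0.001 raw
cutoff *is* the selection rule. The background is also deliberately
covariate-free (no expression or replication-timing adjustment); it asks
only "is this gene mutated in extremely many samples of this cancer type",
which is the right question for building clustering features rather than
for nominating drivers.

## Recursive mixture-model clustering

Samples are clustered on the candidate union. The default representation
is the **binary** mutated/not profile. Raw counts and `log1p` counts are
options, but on integer-valued features a diagonal Gaussian mixture can
always buy likelihood by carving off samples at a single discrete level of
a single feature, and BIC then keeps splitting far past the planted
structure; the binary profile bounds every single-feature split's
log-likelihood gain below the BIC penalty while preserving the signal that
distinguishes subtypes (which genes are mutated). For the same reason the
variance floor for integer-valued data is `max(1e-6 × overall feature
variance, 1/12)` — 1/12 is the variance of rounding to the integer grid, so
no component can claim to resolve structure finer than one count bin.

Each node fits diagonal-covariance Gaussian mixtures for K = 1..9 by EM
(5 seeded k-means++ restarts, convergence at relative log-likelihood change
< 1e-7, best restart kept; K = 1 in closed form) and keeps the K maximizing
BIC in the Mclust sign convention `2 logL − #params · ln n`, ties broken
toward smaller K. Full covariance is not offered: with hundreds of
candidate-gene dimensions it is ill-conditioned at cohort-scale n, and the
diagonal model is the high-dimensional workhorse. The agglomerative
initialization used by Mclust is deliberately not replicated; k-means++
with restarts is simpler and seeded.

The node is split into its components (hard assignment by posterior
responsibility) and each child is clustered again. A node becomes a leaf
when (a) BIC selects K = 1, (b) the largest child would hold more than 95%
of the node's samples — the split is then discarded entirely, treating the
residual children as outliers rather than reassigning them, (c) the node
has fewer than 20 samples, or (d) an optional depth limit is reached
(unlimited by default). Leaves are labelled C1..Cn in depth-first order,
so labels are stable across reruns with the same seed. Per-node seeds
derive from one master `SeedSequence`, so subtrees are reproducible.

## Per-subtype characterization

*Mutational load* of gene g in subtype C is the fraction of C's samples
with at least `min_mutations` mutations in g; both the ≥1 and ≥3 variants
are emitted (the ≥3 variant separates look-alike subtypes that share genes
but differ in mutation intensity).

*Gene and gene-motif enrichment* uses one-vs-rest Fisher exact tests on
sample presence (a sample either carries ≥1 qualifying mutation or not;
raw counts would leave the 2×2 table ill-defined). A gene-motif is the
pair (gene, trinucleotide substitution class); the 96 classes come from
collapsing every NXN→NYN substitution onto the pyrimidine strand. The
default alternative is one-sided ("greater"): the analysis seeks
enrichment within a subtype. Top lists are ranked by p-value, then
descending odds ratio, then feature id — a fully deterministic order so
that top-100 overlap matrices between subtypes are reproducible. Both the
Fisher-ranked and the raw-load rankings are available, since "top mutated
genes" admits either reading.

*Consequence frequencies* are computed over mutations per subtype;
consequence strings missing from the user-supplied impact map (including
empty ones) are binned as "Unavailable".

## Mutational signatures

Signatures are extracted per subtype from per-sample 96-channel catalogs
(whole-genome SNVs, mitochondria excluded; for synthetic cohorts the
generator's motif table stands in). NMF uses multiplicative updates on the
Frobenius objective (KL by flag), with the objective asserted nonincreasing
and the signature matrix renormalized column-stochastic (exposures rescaled
compensatingly). The number of signatures N is scanned over 2..15:
for each N the reconstruction error is averaged over bootstrap resamples
of the samples, and a stability score is the mean cosine of optimally
assigned (Hungarian-matched) signatures across restarted fits. The chosen
N maximizes the second difference of the error curve (the elbow) among N
with stability ≥ 0.8, falling back to the most stable N; the full metric
trace is emitted for manual override, because no automatic rule is
authoritative here. "Angular similarity" to reference catalogs is cosine
similarity (the field's standard; the `1 − θ/π` form is a flag).

## Enrichment and survival

Gene-set over-representation of each subtype's top-100 genes uses the
hypergeometric upper tail against user GMT collections, with the universe
defaulting to the full coding-gene catalog of the run (a candidate-gene
universe would bias terms toward the selection itself), and
Benjamini–Hochberg FDR < 0.05 across each collection's terms. Zero-overlap
terms are reported with p = 1 and never flagged, keeping the BH denominator
well defined. Web-service rank corrections used by some enrichment tools
are not replicated.

Survival first drops donors whose samples fall in more than one subtype,
then computes Kaplan–Meier product-limit curves per subtype and a global
multi-group log-rank test (estimation via lifelines; deaths processed
before censorings at tied times; days stored, years reported). An optional
pairwise log-rank matrix with BH correction is provided since the global
test alone does not localize differences. No covariate adjustment (Cox) is
attempted.

## Synthetic cohorts

The generator emits the same ICGC-dialect TSVs the parser reads — concrete
SNV records with fabricated loci on a toy contig plus a matching FASTA, so
tests exercise the real I/O and motif code paths — together with clinical
tables, per-sample motif catalogs, a gene catalog with non-coding decoys, a
planted-set GMT, an impact map and a reference-signature matrix, and a
ground-truth JSON.

Generative model: per (cancer type, gene) a rate `λ_g ~ Gamma(r, q/p)` is
drawn and each sample is mutated with probability `λ_g / n_t` — the
gamma-Poisson construction of the negative binomial, so per-gene
mutated-sample counts are NB(r, p) up to a vanishing binomial correction.
Samples of planted subtype j have that probability multiplied by an
elevation factor (capped at 1) in j's elevated genes. Mutated
(sample, gene) pairs receive geometric extra within-gene multiplicity so
the ≥3-mutation analyses have signal. Motif catalogs are multinomial draws
from Dirichlet-weighted mixtures of planted signatures (drawn sparse and
rejection-sampled to pairwise cosine ≤ 0.3). Survival is exponential with
subtype-specific hazards and independent exponential censoring calibrated
to the configured censoring fraction. One master seed drives everything;
identical configs give byte-identical files.

Default study conditions: 500 samples, 2 cancer types, 5,000 genes,
NB(size = 40, p = 4/7) (mean 30 mutated samples per gene in a 250-sample
cancer type), four equal subtypes each elevating a disjoint 10-gene block
tenfold, three planted signatures, subtype survival medians of roughly
8/6/4/2 years with 20% censoring. These were fixed by a forward power
calculation: the elevated genes must land in the 0.001 tail of the fitted
background *including* the contamination the elevated genes themselves
inject into the fit, which requires moderate background dispersion. Real
somatic backgrounds are far more overdispersed (size near 1); under such
dispersion a 10× per-sample elevation is simply not detectable in a
500-sample tail test, so the generator trades that much realism for a
planted effect the method is actually powered to find. The clustering
recovery experiment uses a stronger variant (800 samples, 30-gene blocks,
20× elevation) and the demo pipeline a smaller one (240 samples, 1,200
genes, 3 subtypes).

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: covariate-dependent background mutation
rates, gene length and context heterogeneity beyond the gamma rate,
correlations between genes, cancer-type-specific signature exposures,
non-exponential survival, multi-sample donors, or realistic genome
coordinates. Recovery results on synthetic cohorts demonstrate
correctness of the machinery, not field performance.

## Pipeline and reproducibility

Stages exchange data only through serialized artifacts in the output
directory, so any stage can be rerun from files. Every run writes
`manifest.json` with a config snapshot, the seed, and SHA-256 hashes of all
inputs and outputs; two runs with the same inputs and seed produce
identical manifests. All thresholds (0.001 tail, 95% dominant-child rule,
Kmax = 9, min node 20, N range 2–15, FDR 0.05, load thresholds 1 and 3)
are surfaced in one YAML-loadable `RunConfig` with these values as
defaults. The `pansubtypes` CLI exposes each stage and `run-all`.

## Known limitations

- The NB background is fitted per cancer type on all genes including true
  positives; heavy contamination (many strongly elevated genes) widens the
  fitted tail and costs recall. No robust/trimmed fit is provided.
- BIC-guided Gaussian mixtures on binary profiles are a pragmatic choice,
  not a generative truth; with very weak separation the recursion can stop
  early (one leaf) rather than over-split.
- The NMF model-size rule (elbow + stability) is heuristic; the per-N
  trace is emitted precisely so a user can override the choice.
- Tail p-values, Fisher tests and enrichment are all unadjusted or
  BH-adjusted per collection as described; no global error control across
  the whole pipeline is attempted.
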