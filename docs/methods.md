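# Methods

This note documents the models, estimators and numerical choices behind
`fluidmix`, and what the synthetic data do and do not establish.

## Expression model and mixture semantics

Each body fluid f is described by a relative transcript abundance vector
π_f over a shared gene universe (Σ_g π_fg = 1). A mixture design assigns
each contributing fluid a read fraction w_f (Σ w_f = 1): the mixture's
read distribution over genes is the fraction-weighted average
P(g) = Σ_f w_f π_fg. Fractions are therefore fractions of sequenced
*reads*, not of molecules or cells — the quantity a deconvolution of raw
counts estimates directly. Mixtures are simulated at the count level as a
single multinomial draw of `total_reads` reads from P(g); this is
distributionally identical to subsampling reads from per-fluid FASTQ
files and mixing them, without touching read-level formats. The default
`total_reads` is 10⁶ (the benchmark design totals 180 mixtures; full
56 × 10⁶-read mixtures are supported via the `total_reads` argument but
add nothing statistically at this marker strength).

Reference panels draw each gene's count as negative binomial with mean
`library_size × π_fg` and dispersion α (variance μ + αμ²), α = 0.1 by
default — a typical bulk RNA-seq biological CV² — with per-sample library
sizes jittered lognormally (σ = 0.2). The Poisson limit is used below
α = 10⁻⁸.

Marker construction gives every fluid m marker genes whose normalized
abundance is exactly `marker_fold` times their abundance in the other
fluids (blocks are rescaled to equal mass so the fold is exact after
normalization). An option makes a fraction of saliva's markers shared
with vaginal secretion, emulating the buccal/vaginal mucosa expression
similarity that degrades saliva calls on real data.

## Differential expression and the signature

The DE engine is a vectorized negative-binomial Wald test: counts are
size-factor normalized (median-of-ratios) across the two groups; the
per-gene log2 fold change uses a 0.5 pseudocount; dispersion is a pooled
method-of-moments estimate α = (s² − m̄)/m̄², floored at 10⁻⁸; the Wald
statistic applies the delta method to log2 of the pseudocounted means;
q-values are Benjamini–Hochberg. This is deliberately simpler than
shrinkage-based DE engines — no fold-change moderation, no independent
filtering — and any external DE table (gene, log2fc, qvalue) can be
injected in its place.

Per pairwise comparison, genes with |FC| ≥ 2 and q < 0.05 are split by
fold-change direction, ranked by decreasing |log2FC| (ties: smaller q,
then gene id — a total order), and the top fraction of each direction's
list kept (default 4%; the benchmark sweep runs 30% → 1%). The "top x%"
is interpreted per comparison and per direction, so each pair contributes
markers for both of its fluids; the union over the ten pairs forms the
signature's gene set. Signature values are each fluid's arithmetic mean
of (identically normalized) replicate expression on those genes.

## Deconvolution solvers

All solvers regress the mixture vector on the signature restricted to
marker genes, in linear (never log) space:

* **NNLS** — active-set nonnegative least squares.
* **RLR** — Huber M-estimation via IRLS (tuning 1.345 × MAD scale,
  tolerance 10⁻⁶, ≤ 100 iterations); negative coefficients truncated.
* **FARDEEP-style trimmed NNLS** — alternate NNLS fits with dropping
  genes whose squared residual exceeds k (default 10) times the retained
  mean squared residual, to stability or `max_iter` (20), then refit.
  This keeps the adaptive least-trimmed-squares principle while omitting
  the original's tuning-parameter path search; the dropped-gene list is
  reported. A relative floor (10⁻¹² × mean m²) on the cutoff prevents
  spurious trimming when the fit is numerically exact.
* **QP** — least squares constrained to the probability simplex
  (w ≥ 0, Σw = 1), solved by SLSQP with analytic gradient; signature and
  mixture share one scale factor for conditioning, which preserves the
  solution. Per-column unit scaling was considered and rejected: with a
  sum-to-one constraint it redefines the coefficients and breaks exact
  recovery of noiseless mixtures.

Coefficients are finalized by simplex renormalization (the
pre-normalization values are retained for diagnostics). On noiseless
mixtures all four solvers recover the design fractions to 10⁻⁶; on
two-fluid problems each matches a 10⁻⁴-step exhaustive search over the
fraction simplex (with the overall scale profiled out for the
cone-fitting solvers) to within 10⁻³.

Composition calling uses a strict >5% fraction rule. The BFID override is
enabled by default for saliva only — the observed failure mode — and is
configurable per fluid; it vetoes a presence call when every BFID marker
of that fluid has raw counts below 10.

Accuracy is scored per fluid across mixtures (RMSE and Pearson R), the
convention matching per-fluid scatter plots; per-mixture scoring is
available by transposing the estimate table.

## SNP selection, RMP and LR

The variant cascade keeps biallelic autosomal SNVs with DP > 60 and
GQ > 40 (strict inequalities), drops SNPs in user-supplied imprinted-gene
and RNA-editing blocklists (A↔G / T↔C substitutions are only removed at
listed positions — no blanket transition removal), requires coverage by
the population panel, and applies a strict MAF > 0.1 filter (0.05
supported for minor-component rescue). For single-source samples, LD
pruning (panel-dosage r² > 0.2 within 1000 kb drops the lower-MAF SNP;
ties drop the downstream one; deterministic position-order scan) and a
Hardy–Weinberg screen (exact test, keep p > 0.05) follow. For mixtures,
linked SNPs within a gene are instead collapsed into one phenotype, so no
LD pruning is applied between them.

The HWE exact test enumerates heterozygote counts conditional on the
allele counts via the lgamma closed form of the conditional distribution
and sums the probabilities of outcomes no more likely than the observed
one; it agrees exactly with rational-arithmetic enumeration for totals up
to 200 (and beyond).

Donor assignment: with exactly two fluids present, the pair's significant
DEGs are split by direction and each fluid's donor receives SNPs in its
top-200 overexpressed genes — direction-aware assignment is the only
self-consistent reading, and it makes the two gene sets disjoint by
construction. With 3–4 fluids, a gene qualifies for a fluid only if
significantly overexpressed against *every* other present fluid, ranked
by the minimum |log2FC| across those comparisons, top-250 kept.

RMP is the plain product rule over phenotype-group frequencies — the
standard forensic definition under independence after LD handling — with
no theta/subpopulation correction. Singleton groups use HWE genotype
frequencies from the population allele frequency (clipped to
[10⁻⁶, 1 − 10⁻⁶]); multi-SNP phenotypes use the empirical fraction of
panel individuals matching the joint genotype exactly, floored at
1/(2N + 1) so an unseen phenotype cannot produce an infinite LR. LR =
1/RMP, computed and reported in log10 to survive underflow at hundreds of
SNPs. Reference matching assumes no allelic dropout or drop-in: groups
containing any discordant or missing SNP are excluded from the LR and
reported.

## Population panel and ancestry

The synthetic reference panel follows the Balding–Nichols model:
ancestral frequencies Uniform(0.05, 0.95), population frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F) at F_ST up to 0.3 (default 0.1–0.15), panel
genotypes drawn allele-wise under HWE within population, optional LD
blocks by copying adjacent haplotype alleles.

AISNPs require a maximum pairwise population *alt-allele* frequency
difference strictly above 0.3 (ΔAF, not MAF, differences — the standard
informativeness convention) and are LD-pruned with the identification
parameters; the MAF filter is deliberately not applied. Admixture is
estimated by supervised maximum likelihood: with panel frequencies p_ks
known and K fixed to the panel's populations, EM over allele-level
responsibilities maximizes Σ_s [g_s log Σ_k q_k p_ks + (2−g_s) log Σ_k
q_k (1−p_ks)] on the simplex from a uniform start (frequencies clipped to
[10⁻⁴, 1−10⁻⁴]). The log-likelihood is nondecreasing per iteration and
the estimator is deterministic. This is a supervised substitute for
unsupervised MCMC clustering: the reference populations are known, so no
K-selection or label alignment arises, at the cost of not discovering
structure beyond the panel.

## What the synthetic data do and do not show

The generator reproduces the *design* of the study — marker-driven fluid
separability, the mixture grids, expression-share-weighted allele depths,
HWE population structure — under clean conditions: no microbial read
loss, no RNA degradation, no mapping-rate variation, no pooled-sample
reference genotypes, and markers whose specificity is exact by
construction. Passing benchmarks here demonstrates the correctness of the
estimators and the internal consistency of the pipeline, not field
performance on degraded casework material; on clean data all solvers are
closer to truth than any real-data figure, which is why acceptance bounds
are upper bounds. The saliva cross-talk option and the outlier-injection
example exist to reproduce the qualitative failure modes (SA/VS
confusability; robust-regression advantage on raw counts) rather than
their real-data magnitudes.

## Problem sizes and determinism

Default benchmark sizes — 1000 genes, 20 markers/fluid, 5 replicates,
10⁶-read mixtures, 180-design grid, panels of a few hundred SNPs × 100
individuals/population — run the whole suite in seconds on one core
while keeping every statistical check well-powered. Every generator is a
pure function of (parameters, seed); the pipeline embeds the config hash
and seed in its report, and rerunning a config is byte-identical.
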