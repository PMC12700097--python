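# fluidmix

Body-fluid mixture deconvolution and donor identification from bulk
transcriptome data.

Forensic stains are often mixtures of several body fluids — venous blood
(VB), menstrual blood (MB), saliva (SA), semen (SE), vaginal secretion
(VS) — contributed by different people. `fluidmix` implements a two-step
computational workflow for such stains, aimed at forensic genetics and
transcriptomics researchers:

1. **Body-fluid deconvolution.** The mixture's expression profile *m*
   (gene-level read counts) is regressed on a signature matrix *S* of
   fluid-specific marker genes, *m ≈ S w*, and the nonnegative
   coefficients are renormalized to read fractions on the simplex.
   Markers come from all pairwise differential-expression comparisons
   (NB-Wald test; |fold change| ≥ 2, q < 0.05; top fraction per direction,
   default 4%). Solvers: NNLS, Huber robust regression (RLR), adaptive
   trimmed NNLS in the FARDEEP style, and a simplex-constrained quadratic
   program. A fluid is called present when its estimated fraction exceeds
   5%, with an expression-evidence veto from body-fluid identification
   (BFID) markers such as *STATH* (saliva): a presence call is overridden
   when all of the fluid's BFID markers have raw counts below 10.

2. **Donor SNP separation and identification.** SNPs called from the
   mixture mostly carry mixed genotypes — except those in genes expressed
   (nearly) exclusively by one contributing fluid. Quality-filtered SNPs
   (biallelic, autosomal, DP > 60, GQ > 40, imprinting/RNA-editing
   blocklists, panel MAF > 0.1) falling in the top fluid-specific genes
   (top-200 DEGs for two contributors, top-250 overexpressed-vs-all for
   3–4) are routed to that fluid's donor. SNPs sharing a gene are linked
   and treated as one multi-locus phenotype. The random match probability
   is the product of population phenotype frequencies, RMP = Π fᵢ, and the
   likelihood ratio LR = 1/RMP; LR > 10⁶ is "extremely strong" evidence.
   An ancestry extension selects ancestry-informative SNPs (pairwise
   population ΔAF > 0.3, LD-pruned) and fits admixture fractions with a
   supervised maximum-likelihood EM estimator.

Because real casework sequencing data are restricted, the package ships a
first-class synthetic-data generator (`fluidmix.simdata`): fluid profiles
with controllable marker specificity, negative-binomial reference panels,
multinomial read-level mixtures over the study's 180-design two-person
grid, Balding–Nichols population panels, donor genotypes under
Hardy–Weinberg equilibrium, and mixture variant calls whose allele depths
follow each donor's expression share.

## Worked example

`examples/02_deconvolve_mixture.py` simulates a 60/40 menstrual-blood /
vaginal-secretion mixture at one million reads, builds the top-4%
signature from a simulated reference panel and deconvolves with FARDEEP
on raw counts:

```
signature: 15 marker genes x 5 fluids
true fractions: MB=0.60 VS=0.40
  MB: estimated 0.609  -> PRESENT
  VS: estimated 0.341  -> PRESENT
  SE: estimated 0.020  -> absent
  VB: estimated 0.018  -> absent
  SA: estimated 0.012  -> absent
```

The two designed contributors are recovered within a few percent and only
they clear the 5% presence rule. `examples/04_identify_donors.py`
continues into step two on a balanced MB/SE mixture:

```
MB donor: 43 SNPs in 19 phenotype groups, concordance 100.0%, log10 LR = 14.8
SE donor: 48 SNPs in 20 phenotype groups, concordance 100.0%, log10 LR = 17.1
```

Each separated profile matches its true donor perfectly and the LRs sit
eight orders of magnitude above the 10⁶ evidential bar. The remaining
examples cover mixture simulation, the method × normalization benchmark
(including why robust fits on raw counts win once outlier transcripts
appear), single-source random match probabilities, and ancestry inference.

A thin CLI mirrors the library: `fluidmix simulate | build-signature |
deconvolve | compose | identify | ancestry | benchmark | run` (see
`fluidmix --help`).

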