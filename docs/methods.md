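# Methods

## The analysis problem

A pear breeding panel is a cultivar collection (here 106 individuals)
plus many biparental F1 full-sib families (17 families of 28–121,
1112 F1, 1218 total), genotyped at a few thousand tag SNPs on 17
chromosomes.  Two association models are run on ten fruit traits, a
single-marker kinship mixed model and a multiple-QTL variational Bayes
model, followed by per-locus effect characterisation and genomic
prediction evaluated the way a breeder would use it: predict a whole
unseen cross.  Everything below is implemented in `pearqtl` and
exercised on synthetic data from `pearqtl.simpop`.

## Synthetic populations (`simpop`)

**Founder haplotypes.** Per-marker allele frequencies are drawn from a
U-shaped Beta(0.5, 0.5) truncated to [0.05, 0.95].  Haplotypes follow a
first-order copying process: a latent standard-normal AR(1) along each
chromosome with correlation exp(−d/L) between markers d bp apart,
thresholded at Φ⁻¹(p_k).  L is calibrated by root-finding (bivariate-
normal orthant probabilities via Gauss–Legendre quadrature) so that the
*panel-level* expected pairwise r² at `ld_range_bp` = 250 kb equals 0.2;
the calibration target is corrected for the finite-panel sampling floor
1/(2·n_founders − 1), so small founder sets stay on target.  A first-
order chain is deliberate: it hits the single LD calibration target and
is orders of magnitude faster than a coalescent simulation; it does not
reproduce long-range haplotype blocks or recombination hotspots.

**Pedigree.** 13 founders are advanced two generations of random
crossing to make the cultivars (the true pedigree of such material is
unrecorded; this is a stand-in, not an inference), and each F1 family is
the full-sib progeny of a random cultivar pair.  Meiosis uses Poisson
crossover counts (rate = chromosome length in Morgans, default 1.0 M
per 30 Mb chromosome), uniform crossover placement, no interference
(Haldane), genetic position proportional to bp.

**Sugar-conversion trait model.** Rather than a multivariate-normal
effect matrix, traits are generated mechanistically:

- latent total sugar pool `T = μ_T + direct QTLs + polygenes + family
  deviation + noise` (μ_T = 130.7 mg/ml);
- a conversion score `c = logistic(η_c)` (sucrose → hexoses) and a
  hexose split `h = logistic(η_h)` (share of fructose), each carrying
  QTLs, polygenes and environmental noise on the logit scale;
- an independent sorbitol channel `SOR`;
- `SUC = (T − SOR)(1 − c)`, `FRU = (T − SOR)·c·h`,
  `GLC = (T − SOR)·c·(1 − h)`, and `TSC = SUC + FRU + GLC + SOR`
  exactly, by construction.

This reproduces the defining signature of the real material: one locus
that raises sucrose while lowering fructose+glucose with the total
nearly unchanged.  The genotype-class means of that locus also require
that stronger conversion tilts the hexose pool toward glucose, so η_h
carries a loading on η_c (`split_coupling`, default −0.95).  Without
that coupling the phenotypic corr(SUC, GLC) cannot reach the −0.6 to
−0.85 band observed in real panels; with it the default preset yields
≈ −0.65 to −0.72 at n = 1218.

**Default preset QTLs** (positions are snapped to the nearest simulated
marker): a conversion QTL on chromosome 7 (≈23.5 % of SUC variance), a
hexose-split QTL on chromosome 11 (≈21.7 % of GLC variance), a direct
fructose QTL on chromosome 4 (12.7 %), harvest-time QTLs on chromosomes
3 and 15 (16.5 %/20.3 %), an acidity QTL on chromosome 6 (13.1 %).
Conversion-QTL variance targets are translated to logit-scale effects by
a delta-method linearisation at the channel means; realised linear PVE
is therefore approximate for conversion loci (the nonlinearity eats
part of it), exact in expectation for direct loci.

**Heritability targeting.** Targets are SUC 0.64, FRU 0.69, GLC 0.71,
SOR 0.76, HarT 0.70, Aci 0.60 (TSC emerges at ≈ 0.26–0.33 because
conversion noise cancels in the sum — the same reason total sugar is
the hardest trait in real data).  Because noise enters nonlinearly
through c and h, each sugar's non-genetic variance is measured on the
simulated cohort (Var(y_raw − y_genetic)) and topped up with independent
Gaussian noise to reach Var_g(1−h²)/h².  Realised h² (squared
correlation of phenotype with the noise-free genetic value) is within
±0.1 of target, verified over 30 replicates in the test suite.

**`family_variance`** is the family-deviation share of each channel's
phenotypic variance (a fraction, default 0.05), not an absolute
variance — trait variances span five orders of magnitude.

**What the simulator does not emulate:** genotyping error and missing-
data patterns of real ddRAD data, imputation artefacts, multi-year
phenotype replication and G×E, the positive HarT–FruW correlation, and
a negative SOR–SUC correlation (the sorbitol channel is independent by
design).  Tests passing on this generator show the estimators are
correct and calibrated under realistic LD/family structure; they do not
certify performance on real orchard data.

## Mixed-model GWAS (`gwas_mlm`)

REML variance components of y = Xb + u + e (u ~ N(0, σ²_g G), G =
VanRaden) are profiled over δ = σ²_e/σ²_g on the eigenbasis of G: a
100-point log grid on [1e−5, 1e5] then bounded scalar refinement
(tolerance 1e−10 on log δ).  The scan holds V̂ fixed at the null
estimates (P3D) and tests each marker's GLS coefficient with a Wald
χ²(1) p-value; `exact=True` re-optimises per marker for validation.
Covariates default to the first three PCs of the (LD-pruned, centered,
unscaled) dosage matrix.  The scan path is verified against a dense
V̂⁻¹ GLS oracle to 1e−8.  Significance is Benjamini–Hochberg at
q = 0.05; the reported threshold is the largest rejected p (the
Manhattan-plot line).

## Variational BayesB (`gwas_vb`)

Model: y_i = μ + Σ_j x_ij δ_j a_j + f_fam(i) + e_i, δ_j ~ Bernoulli(π),
a_j | σ²_aj ~ N(0, σ²_aj), σ²_aj ~ scaled-inv-χ²(ν, S²),
f_k ~ N(0, σ²_f).  Mean-field factors: spike-and-slab q(δ_j, a_j),
conjugate scaled-inv-χ² q(σ²_aj) (updated immediately after its
marker), Gaussian q(f_k).  μ, σ²_e and σ²_f are point parameters
maximised in the same free energy (variational EM): every update is
then an exact coordinate maximisation, so the ELBO is non-decreasing —
asserted at runtime with 1e−6 relative slack; a decrease raises an
internal error.  The inclusion log-odds use the exact E[log σ²_aj]
(digamma) term.  The sequential residual-update sweep is numba-compiled.

Hyperparameter defaults (overridable, logged): π = 10/m (about ten
QTLs expected), ν = 4.2, S² set so the prior mean of σ²_aj equals
0.5·Var(y)/(π·Σ_k 2p_k(1−p_k)) — the standard BayesB scaling.
Convergence: relative ELBO change < 1e−6 or 1000 iterations.  A marker
is called at γ_j ≥ 0.85, inclusive (reported posterior probabilities in
comparable analyses include values printed at the threshold).

**Update order.** Default is genomic order, deterministic.  On dense
tag panels a single fixed-order CAVI pass can lock weak LD proxies into
the model before a strong causal marker is reached — a local optimum in
which the causal γ stays near 0.  The fitter therefore supports seeded
per-iteration shuffling and multiple restarts with best-ELBO selection
(`VBHyper(shuffle=True, n_restarts=4)`), which the recovery benchmarks
use; this is still bit-reproducible given the seed.  Progeny effects are
modelled as random with estimated σ²_f (a `families=None` switch drops
them); the cultivar collection forms one class, and single-class inputs
disable the term (it would be confounded with μ).

## Effect characterisation (`qtl_effects`)

PVE is the effect-based share 100·effect²·Var(x)/Var(y) with population
variances — the only reading consistent with "variance of the SNP";
a genotype-class-mean R² alternative sits behind `method="class_r2"`.
The per-family matrix re-estimates the effect by OLS inside each family
(configurable to reuse the global effect) and blanks cells where fewer
than two genotype classes, or any class with fewer than 2 members, are
present.

## Genomic prediction (`gs`)

GBLUP is the intercept-only kinship mixed model; predictions for a test
set are û = K_xt (K_tt + δ̂ I)⁻¹ (y − μ̂), with both kinship blocks
centred at *training-set* allele frequencies so folds stay honest.  The
implementation is verified against the marker-ridge (RR-BLUP)
formulation and a dense mixed-model-equation solve.  vBayesB predicts
ĝ = μ̂ + Σ_j x_j γ_j ã_j; progeny effects are never added (test families
are unseen).  Leave-one-family-out CV: each F1 family in turn is the
test set, the collection plus remaining families train; per-family
Pearson r (negative or undefined → 0), their mean, and the pooled r
over all tested F1 individuals are all reported.  The pooled value is
the headline figure; the per-family mean is the harder within-cross
(Mendelian-sampling) task and is systematically lower, especially for
traits with big between-family QTL differences.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` use: the full default preset
(1218 × 3485) for population fidelity, LD decay and CV; QTL recovery
with a 23.5 %-PVE locus (drawn from markers with MAF ≥ 0.3, matching
the genotype-class balance of real large-effect loci) plus a dense
polygenic background to total h² = 0.7, 20 replicates in the tests and
10 in the acceptance script, phenotypes redrawn per replicate on
populations regenerated every 5 replicates; null calibration on a
500 × 2006 panel with 200 (tests) or 100 (script) pure-noise scans for
the MLM+BH FDR and 20/10 vBayesB fits.  Kinship gets a 1e−8 diagonal
ridge; PCA is SVD-based with the largest-magnitude loading of each
component made positive; mode imputation breaks ties toward the smaller
dosage; BH on missing p-values never rejects them.

## Known limitations

The simulator's LD has a single calibration target (no hotspot
structure); cultivar relatedness is a guess at an unrecorded pedigree;
conversion-QTL PVE is linearised; vBayesB uses point estimates for μ,
σ²_e, σ²_f (no posterior uncertainty on those); the MLM uses χ²(1)
rather than F tests (large-n usage); per-marker exact REML is available
but slow.  Prediction accuracies on synthetic data are in the same
regime as, but not numerically comparable to, real-orchard results.
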