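# Methods

This note records the modelling choices, defaults and numerical decisions
behind the package, and what its simulation-based tests do and do not
demonstrate.

## The model family

All four models are special cases of one record-level animal model

    y = X b + P q + W u + e,  u ~ N(0, H su2),  e ~ N(0, I se2),

with `X` ordinary fixed effects, `P` the (fixed) pseudo-QTN covariates, and
`W` the record-to-animal incidence. `H` agrees with the blended genomic
matrix `G_omega = 0.95 G + 0.05 Agg` on genotyped animals and propagates
genomic information to relatives through the pedigree; only its inverse —
sparse `A^-1` plus a dense correction `G_omega^-1 - Agg^-1` on the
genotyped block — is ever formed for estimation. The dense four-block `H`
exists solely as a small-scale oracle for tests.

|                | D = I    | D = diag(PP) |
|----------------|----------|--------------|
| no pQTNs       | ssGBLUP  | ssGWABLUP    |
| pQTN covariates| ssGBLUP_pQTNs | ssGWABLUP_pQTNs |

## GWAS weighting

Variance components are estimated (or supplied) once; each marker is then
tested by generalized least squares with V fixed — the EMMAX
approximation, implemented on data rotated by the eigenvectors of the
kinship so the scan is linear in markers. The Wald statistic is converted
to LR = t²/2, smoothed by a moving average over the marker and its 20
neighbours (10 per side, truncated at chromosome ends — windows never
cross chromosomes, edge windows simply average fewer values), and mapped
to a posterior probability of association with prior π = 0.001. The PP
vector is rescaled to mean 1 before it weights `G`, so weighted and
unweighted `G` share a scale (raw PP average ≈ π, which would collapse the
matrix); with every weight equal to 1 the weighted model is numerically
identical to ssGBLUP (tested).

The scan population is the genotyped animals with phenotypes (females, for
the sex-limited simulated trait), with K = unweighted `Gu` on those
animals, allele frequencies taken from the current genotyped set, and
p-values from the standard normal. Untestable markers (monomorphic or
collinear with X) carry LR = 0 into the smoothing.

## Pseudo-QTN selection

Markers are ranked by p-value and greedily pruned so every kept candidate
has composite LD r² < 0.3 (squared Pearson correlation of 0/1/2 codes on
the reference genotyped animals) with all previously kept ones, stopping
at 15. Candidates are then vetted in rank order by 5-fold cross-validation
on the reference records: a candidate is accepted when the fold-mean
correlation between held-out predicted `g` and the held-out response beats
the current best model by at least 0.001. The folds are fixed once
(seeded); the baseline is the best model so far (greedy hill-climb); every
candidate is evaluated even after rejections; accepted markers stay in `G`.
Selection runs once per dataset against the plain (unweighted) single-step
base model — the pseudo-QTN set is a property of the data, decided before
marker weighting enters, and both pQTN models share it; a weighted-base
mode is available.

Two selection-CV choices deserve emphasis:

* **Response.** In real-data use the response is the fixed-effect-adjusted
  phenotype. In simulation mode the response is the true breeding value.
  This is not cosmetic: under the phenotype-driven truncation selection the
  simulator applies, held-out polygenic predictions are *negatively*
  correlated with the phenotype residuals (selected parents trade genetic
  for environmental advantage, and contemporary-group means are estimated
  from the same relatives that drive the predictions), so phenotype-based
  CV systematically understates the polygenic baseline and over-accepts
  marginal covariates. Scoring against TBV removes that bias; the package
  exposes both paths.
* **Covariate coding.** pQTN covariates are the centred codes `M - 2p`.
  Centring leaves estimates, correlations and dispersion untouched (it
  moves a constant between intercept and `P q`), but it anchors
  `g = P q + u` at the population mean — raw codes would shift every
  animal's GEBV by `sum_j 2 p_j q_j`, polluting the bias metric — and it
  makes the pedigree imputation `P_n = Ang Agg^-1 P_g` send animals
  unrelated to the genotyped set to the mean rather than to an arbitrary
  corner of the code space.

## Mixed-model equations

The 3×3-block MME is symmetric; pQTN effects sit in the fixed block
(fitting them there is algebraically identical to appending them to X —
tested as an exact identity). Variance components for prediction are the
simulation truth (su2 = h², se2 = 1 − h² on the phenotypic scale) in
simulation mode and REML estimates otherwise; at desk scale, per-replicate
REML of a h² = 0.1 trait has sampling error of the same order as the
estimate itself and occasionally returns 0, which would turn the model
comparison into a lottery of shrinkage constants.

The solver exploits structure rather than brute force: the animal block
`W'W + λA^-1` is sparse and SPD and factorizes with near-zero fill under a
symmetric minimum-degree ordering; the dense genomic correction enters via
the Woodbury identity (one dense factorization of the genotyped-block
capacity matrix, cached inverse of the correction); the handful of dense
fixed-effect rows are solved by a Schur complement over the animal block.
Treating the whole coefficient matrix as one sparse system is 10–50×
slower because the dense rows and the genotyped block destroy the
sparsity. During forward selection each fold's base system is factorized
once and every trial candidate enters through a growing bordered block, so
evaluating 15 candidates costs 15 cheap solves, not 15 factorizations.
Solutions are verified against the assembled system (relative residual
< 1e-6 enforced; typical 1e-12).

Fixed effects in simulation mode are an intercept plus generation
(contemporary-group) dummies — standard for populations under selection;
without them, markers whose allele frequencies trend across generations
can masquerade as trait-associated through the genetic trend, a signal
that evaporates on the single-generation validation set.

## The simulator

The simulator produces the data structure the method needs — deep
pedigree, partial genotyping, sex-limited trait, known TBV — via a
discrete-generation Wright–Fisher history followed by a selected breeding
phase. All loci start at frequency 0.5; recombination follows a Haldane
map (1 crossover per Morgan, implemented by sparse switch sampling and
parity masks); mutation flips alleles at 2.5e-5 per locus per meiosis.
Historical size declines linearly into a bottleneck and re-expands,
building LD (verified against a constant-size control). The recent phase
mates each dam to a random sire (one offspring per dam per generation,
sexes equiprobable) and replaces 80 % of sires / 30 % of dams per
generation by the top candidates ranked on pedigree-BLUP EBV (random mode
available). Causal SNPs are drawn uniformly from markers segregating among
the recent founders; effects are gamma(0.4) magnitudes with random signs
(architectures of 10/100/500 loci) or two normal pools
(N(0, 0.1) × 10 + N(0, 0.001) × 500); effects are rescaled once so founder
TBV variance equals h² = 0.1 of a unit phenotypic variance. Phenotypes
(females only) are TBV plus normal noise. Finally 50 % of the last four
generations is flagged genotyped, 5 % of non-founders lose both recorded
parents, and the last generation becomes the validation set.

### Desk scale

Defaults are a deliberately scaled-down study: 3 chromosomes × 100 cM with
600 markers each, history 150 → 25 → 1000 over 100 generations, and
50 sires × 750 dams × 6 generations (≈ 5300 animals, ≈ 1500 genotyped,
≈ 560 genotyped phenotyped females in the association scan). A replicate
runs in ≈ 15 s, so the replicated experiments finish in minutes. The two
scale knobs were set jointly so that the method operates in the regime the
model family targets rather than in a noise-dominated one:

* the association scan must be able to rank markers tagging major causal
  loci above the genome-wide noise floor (non-centrality ≈ 20 for a
  typical scenario-1 top QTL at this reference size — comfortably
  detectable, as at full scale);
* the polygenic term must carry real information, i.e. the reference size
  must not be dwarfed by the number of independent chromosome segments
  (≈ 2 Nₑ L), which is why the genome is short and the bottleneck deep.

What desk scale cannot preserve: absolute accuracies and counts shift with
scale. Fewer reference animals mean fewer distinctly detectable QTL (so
fewer accepted pseudo-QTNs in the sparse architectures than a full-scale
study finds), and each marker tags a larger fraction of a short genome (so
polygenic architectures reject covariates a little less decisively).
Passing tests therefore demonstrate the directional claims — weighting
helps, pseudo-QTNs help most when major genes exist, their usefulness and
their correlation with TBV decay as polygenicity grows — not the absolute
numbers of a full-scale study. A `SimulationConfig.full_scale()` preset
exists but takes hours per replicate.

Other simulator choices: unknown parents are treated as unrelated
non-inbred founders (no genetic groups); the gamma scale parameter is
irrelevant because effects are rescaled to h²; EBV-based selection uses
pedigree-only BLUP with the true h²; each stage draws from a named
substream of the master seed so stages are independently reproducible.

## Numerical details

* Tabular A with inbreeding; Henderson's A^-1 rules with Meuwissen–Luo
  inbreeding coefficients (never dense inversion); dense A only below
  20 000 animals.
* HWE is a 1-df chi-square on observed vs expected genotype counts among
  non-missing calls, no continuity correction; missing genotypes are
  mean-imputed (to 2p) after QC so they contribute zero to Z.
* Agg and G_omega are inverted by Cholesky; a non-PD matrix raises an
  error pointing at the 0.95/0.05 blend rather than silently regularizing.
* REML maximizes the profiled restricted likelihood over log variance
  ratio (coarse grid + bounded Brent, tolerance 1e-8) after one
  eigendecomposition of K.
* Ties in the p-value ranking break by (chromosome, position, marker id);
  fold splits and candidate evaluation are deterministic given the seed.

## Known limitations

Single trait, no dominance or maternal effects, no repeated records, no
reliabilities/PEV, no genetic groups or metafounders, no APY-style sparse
G approximations. The simulator is a study-design generator, not a QMSim
replacement: its historical demography is stylized, and real genotyping
error, pedigree error beyond missingness, and multi-breed structure are
out of scope.
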