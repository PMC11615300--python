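# Methods

This note records the models, estimators, numerical choices and known
limitations behind `popepigen`, in the spirit of the model documentation
of packages like statsmodels or msprime.

## Epi-allele calling

A cytosine's per-accession methylation fraction mC = C/(C+T) is defined
only where total coverage meets `min_coverage` (default 5 reads); below
that the cell is missing, which is distinct from covered-but-
unmethylated. Discretization into UU/MU/MM uses closed upper bounds
(mC = 0.3 -> UU, mC = 0.7 -> MU): the boundary belongs to the lower
class. The additive 0/1/2 coding mirrors SNP dosage so one statistical
engine serves both marker types. QC removes sites missing in more than
30% of accessions and sites whose position coincides with a filtered
SNP (exact-position masking by default; a window mode exists for
trinucleotide-context masking). Symmetric CG strand pairs are kept
separate; a merge is deliberately not the default because the epi-allele
is defined at a single cytosine position.

Epi-allele frequencies count two alleles per called accession
(p_M = (2 n_MM + n_MU) / (2 n_called)); a genotype-frequency mode is
available. Common SMPs are those with MAF >= 0.05 (inclusive).

## Methylation disequilibrium

The haplotype-level definitions are

    MD  = p_M1M2 - p_M1 p_M2,      Mr2 = MD^2 / (p_M1 p_U1 p_M2 p_U2).

Unphased diploid-like codes leave the double-heterozygote phase unknown,
so two estimators are provided and agree exactly on data without
heterozygotes:

- **composite** (default): Burrows' composite disequilibrium on 0/1/2
  codes. The reported Mr2 uses the Zaykin homozygosity-corrected
  denominator, which is algebraically the squared Pearson correlation
  of the codes — no phasing or Hardy–Weinberg assumption. MD is
  reported as half the composite Delta.
- **em_phase**: EM to maximum-likelihood haplotype frequencies; MD and
  Mr2 then satisfy the haplotype identities exactly. Convergence
  tolerance 1e-12, cap 2000 iterations.

Pairs need >= 20 jointly called accessions by default; monomorphic
sites give undefined (NaN) Mr2. Decay profiles bin all within-
chromosome pairs up to `max_distance` (default 2 kb, 10 bp bins),
subsampling above a 2x10^6-pair budget with a seeded RNG, and report
both mean and median Mr2 per bin. The half-decay distance is the
smallest bin midpoint whose mean drops to (max bin mean + far-distance
plateau)/2, with the plateau estimated from the farthest quarter of
bins — more robust than max/2 against the finite-sample r^2 floor
(about 1/n per pair). Decay analyses are intended for common SMPs:
near-monomorphic sites contribute only noise and flatten the curve.
MD blocks chain consecutive sites greedily while adjacent Mr2 >= 0.1
and the gap <= 10 kb (both configurable).

## Mixed-model association engine

All scans share y = X b + g beta + u + e with u ~ N(0, sigma_g^2 K),
e ~ N(0, sigma_e^2 I):

- **Quantile normalization** maps ranks (average ties) through
  Phi^-1(rank/(n+1)); missing values are preserved, and constant
  vectors normalize to zeros with a warning. Pipelines mean-impute the
  (centered) scores at 0 afterwards, as complete phenotypes are
  required by the REML fit.
- **Kinship** is VanRaden-type: K = ZZ'/sum(2p(1-p)) with columns
  centered at 2p, missing cells mean-imputed, monomorphic markers
  dropped. The same construction serves SNP dosages and SMP codes.
- **REML** maximizes the restricted likelihood over the variance ratio
  delta = sigma_e^2/sigma_g^2 via the eigendecomposition of the
  covariate-projected kinship: a 41-point grid on log delta in
  [-10, 10] followed by bounded Brent refinement. delta at the upper
  boundary flags an effective fall-back to OLS (with K = I the
  likelihood is flat in delta and the scan reduces exactly to OLS —
  verified to 1e-10 against the textbook t-test).
- **Scan (EMMAX approximation)**: variance components from the null
  model are held fixed; markers are whitened by (Lambda + delta)^-1/2
  U', covariates projected out by QR, and each marker tested by the
  GLS t statistic with n - p - 1 degrees of freedom. Missing dosages
  are mean-imputed per marker; monomorphic markers return NaN.
- **Permutation empirical p**: the whitened, covariate-residualized
  phenotype is permuted (seeded generator, bit-reproducible), the
  window rescanned via one matrix product per batch, and
  p_emp = (1 + #{perm min-p <= observed})/(1 + B). This keeps the
  fitted covariance fixed across permutations — an approximation in
  the fastQTL tradition; its null uniformity is verified empirically.
  The optional Beta approximation fits Beta(a, b) to the permutation
  minima by ML (floc=0, fscale=1) and reports its CDF at the observed
  minimum; it is used for cross-target FDR when enabled (default on).
- **Effective tests**: Li–Ji eigenvalue counting
  (sum of I(lambda >= 1) + frac(lambda)) on sliding 1000-marker
  correlation blocks; eigenvalues are rounded at 1e-8 to guard floating
  fuzz. The resulting threshold was checked against a 1000-permutation
  min-p oracle (within a factor of two, on the anti-conservative side
  for strongly locally correlated SMP sets).
- **cis/trans**: cis iff same chromosome and distance <= 1 Mb
  (inclusive at exactly 1 Mb). meQTL targets anchor at the SMP
  position, eQTM windows at the gene midpoint; eQTL classification uses
  the distance to the nearest gene edge (0 inside the gene).
- **Locus merging**: single-linkage over significant markers with
  pairwise r^2 > 0.1 on one chromosome; the lead is the smallest p,
  ties broken by position; output order is input-order invariant.

Pipelines: cis-meQTL and eQTM scan windows per target with permutation
lead p and Benjamini–Hochberg across targets (FDR 0.05); trans-meQTL
and eQTL scan genome-wide at 0.05/M_eff; EWAS scans SMP codes per trait
per context at a per-context 0.05/M_eff and merges significant SMPs
along MD blocks, reporting per-epi-allele trait means at each lead.
EWAS kinship and PCs default to the common SMP codes but accept SNP
genotypes (`kinship_source`) — the right choice whenever the
confounding to absorb (polygenic background, structure) is genetic,
and what the calibration experiments use since their simulated traits
have genotype-based polygenic terms. Structure PCs for meQTL/eQTL come
from SNP dosages; confounder PCs from the molecular phenotype matrix.

## Integration

eQTM genes are typed I/II/III by whether their lead SMP has a
significant cis-meQTL, only a trans-meQTL, or none; SMPs never tested
are "unclassified" and reported separately. EWAS x GWAS co-localization
uses absolute lead-distance <= 20 kb within the same trait (an MD/LD
block mode exists); shared loci split further by the meQTL evidence at
the EWAS lead. The regulatory network joins a trait locus to every
regulated gene of any eQTL/eQTM lead in its LD block (r^2 > 0.1).

Elite epi-alleles: at each trait-associated locus the homozygous class
with the more favorable mean trait (declared direction of merit) is
elite; heterozygotes count 0.5 by default (configurable to strict 0/1);
loci with fewer than 3 carriers of either homozygous class are dropped.
The pyramiding trend across elite-count groups uses a hand-implemented
Jonckheere–Terpstra test (normal approximation, ties counted 1/2 in the
pairwise statistic, no-ties variance) since no installed library
provides it.

GBLUP takes precomputed kinships (sklearn "precomputed-kernel" style):
REML variance components on the training block, GLS intercept, and
BLUP of test values through K_cross (K_train + delta I)^-1 residuals,
with a 1e-6 ridge jitter (escalated to 1e-4 on singularity). Weighted
kinship combinations require non-negative weights summing to 1; the
(1, 0) combination is bit-identical to the single-kinship run. Markers
at supplied EWAS/GWAS loci can be masked from kinship construction
before prediction to avoid leakage. Cross-validated accuracy is
reported both pooled and fold-averaged; the fold average is preferred
because the pooled estimator is biased negative under the null (each
fold's near-constant predictions anti-correlate with the held-out fold
mean).

## Synthetic cohorts

The generator emulates the statistical structure the pipeline consumes,
not mechanism:

- **Genotypes**: per subpopulation (default 2, Balding–Nichols
  Fst = 0.15, reflecting a strongly structured germplasm panel),
  founder haplotypes (default 24) are copied along each chromosome
  with a per-bp switch rate (default 2x10^-4), giving block LD and a
  realistic MAF spectrum.
- **Methylome**: clustered cytosine positions (short intra-cluster
  gaps, occasional long jumps) so pairs exist at all MD-relevant
  distances; per-site population M-frequency from context-specific
  Beta priors (CG strongly bimodal and methylated-biased, CHH more
  intermediate, echoing the observed context MAF contrast). Latent
  diploid states follow a per-accession uniform-copula chain: adjacent
  sites retain a shared latent uniform with probability
  exp(-d/lambda_eff) and the state is the site-specific Hardy–Weinberg
  quantile of that uniform. This preserves per-site marginals exactly
  under correlation (plain state-copying would distort them whenever
  neighboring frequencies differ). lambda_eff carries a one-time
  calibration factor (0.8 x 2 lambda / ln 2) so the *measured*
  half-decay — common SMPs, 10 bp bins, the crossing estimator above,
  n = 300 — equals the configured `md_half_decay_bp` (default 50 bp);
  the raw analytic scale overshoots by ~15% through the max-bin offset
  and finite-sample r^2 bias. Planted cis-meQTLs restart the chain and
  shift the per-accession M-frequency by genotype dosage, with the
  slope solved from the target variance-explained (R^2 = 0.3 default);
  a trans hotspot drives many distant sites from one SNP. Observed
  counts: depth ~ Poisson(15) (gamma-Poisson if overdispersed), meth ~
  Binomial(depth, mu) with mu = 0.003/0.5/0.997 for UU/MU/MM — the
  0.003 floor encodes a 99.7% bisulfite conversion rate, and site-level
  distributions are bimodal near 0 and 1.
- **Expression**: log-normal baseline plus linear planted eQTL/eQTM
  effects at configured variance-explained, exponentiated to FPKM-like
  values; a 5% all-zero gene fraction exercises the expression floor.
  Half the planted eQTMs (configurable) sit on cis-meQTL target sites
  so the regulatory typing has true type-I and type-III genes.
- **Phenotypes**: standardized planted SMP/SNP effects at configured
  variance fractions, a polygenic term drawn from the SNP kinship, an
  optional subpopulation mean shift (confounding control), and
  Gaussian noise filling the remainder.

Everything is deterministic given the seed (separate generator streams
per component). Recovery scoring matches discoveries to planted truth
within a distance tolerance (and optionally by target), reporting
power, empirical FDR, and effect-size bias.

### What the simulator does not capture

Read-level correlations (epi-haplotypes within molecules), mechanistic
RdDM/CMT pathways, context-dependent conversion failure, mapping bias,
tetraploid homoeologs, and realistic sequence content. Passing the
suite therefore demonstrates statistical correctness of the estimators
and pipelines under the assumed generative structure, not robustness to
alignment artifacts or biological confounders absent from that
structure.

## Calibration problem sizes

The calibration experiments (shared by the acceptance tests and
`scripts/acceptance.py`) use desk-scale cohorts chosen for stable rates
at interactive runtimes: n = 300 accessions, two 800 kb chromosomes
with 1000 SNPs and 4000 cytosines for recovery scans (200 planted
cis-meQTLs, 40 eQTMs, one 5%-variance EWAS locus over 16 replicate
cohorts); five 500 kb chromosomes with 4000 SNPs for null calibration
(>= 12,000 null marker tests); a 1.8 Mb chromosome with 6000 CG sites
for the decay round trip; and n = 500 with a highly related 8-founder,
long-LD panel for GBLUP (chosen so the theoretical accuracy
sqrt(h^2 n / (n + Me)) sits well above chance, as in a dense cultivar
collection).

### Measured EWAS power at the calibration conditions

At one planted locus explaining 5% of trait variance (n = 300,
polygenic background h^2 = 0.4, per-context Li–Ji threshold ~1.5e-4),
the attainable power of the genome-wide EWAS is about 0.5–0.6 — the
noncentrality is ~n x 0.045 (after measurement attenuation of the
called codes) times a GLS absorption factor of ~1.3, which is the
optimum the mixed model's covariance reweighting can deliver for this
kinship spectrum; the Li–Ji threshold is itself mildly anti-conservative
relative to the exact permutation min-p threshold. The acceptance suite
asserts a 0.6 power floor for this scan, which consequently sits at the
edge of what these study conditions support.

## Known limitations

- The EMMAX approximation understates per-marker variance-component
  uncertainty; exact per-marker REML is out of scope.
- Permutation in the whitened space assumes exchangeability after
  whitening; heavy structure plus tiny samples could distort it (the
  null-uniformity check covers the supported regime).
- Li–Ji effective-test counts on n < m correlation matrices absorb
  sampling eigenvalue spread; thresholds are validated against a
  permutation oracle only within a factor of two.
- md_blocks chains adjacent pairs greedily; it is not a Gabriel-style
  confidence-interval block finder.
- The CLI covers the main flows; programmatic use is the primary
  interface.
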