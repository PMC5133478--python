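# Methods

This note documents the statistical models, the defaults and why they are
what they are, what the synthetic-data generator does and does not emulate,
and the numerical and design choices a user should know before trusting the
output.

## The trio problem

A *trio* is one SNP dosage vector, one expression measure (a probe or a
module eigengene), and one adjusted quantitative phenotype on a common set
of individuals. The question is which causal topology on {SNP, GE, PHEN}
best explains the joint data, under two standing assumptions: the SNP is
exogenous (genotype is not caused by expression or phenotype), and all
effects are linear with Gaussian noise. Under these assumptions there are
exactly 12 admissible DAGs (2 choices for SNP→GE × 2 for SNP→PHEN × 3 for
the GE–PHEN edge: absent, GE→PHEN, or PHEN→GE).

## Structural equation modelling

Each DAG is a recursive linear Gaussian system: GE and PHEN are each an OLS
regression on their parents (intercept-only if parentless), with maximum-
likelihood residual variance (denominator *n*, not *n − p*, so that AIC
comparisons are likelihood-consistent). The joint log-likelihood factorises
into the two per-equation Gaussian log-likelihoods; this factorisation is an
exact property of recursive systems and is enforced by an oracle test
against independent per-equation OLS fits (statsmodels), at 1e-8 relative.

The SNP's marginal distribution is excluded from every model's likelihood:
it is identical across the 12 DAGs (the SNP never has parents), so its
inclusion would shift all AICs by the same constant while requiring a
non-Gaussian (binomial) marginal term.

Parameter counts: each equation contributes 1 intercept + one slope per
parent + 1 variance, so the empty DAG has 4 parameters and the 3-edge DAGs
have 7. Selection is by minimum AIC = 2k − 2 log L.

**Markov equivalence and ties.** DAGs sharing skeleton and v-structures
attain identical maximised likelihood and parameter count on every data
set — here, the two 3-edge DAGs, and GE→PHEN vs PHEN→GE when no SNP edge is
present. Ties (ΔAIC < 1e-6) are therefore expected; the result carries the
full tie set, and the reported label is the tie member with fewest edges,
then lexicographically first. The tie tolerance is absolute 1e-6, far above
accumulated floating-point error (~1e-13 observed) and far below any real
AIC difference at the sample sizes involved.

**What AIC selection can and cannot deliver.** When the generating DAG is
nested inside an admissible DAG with one extra edge, AIC selects the larger
model whenever that edge's likelihood-ratio statistic exceeds 2, which
happens with asymptotic probability P(χ²₁ > 2) ≈ 0.157 under the null. The
recovery rate of a sparse true model is therefore capped near 84% per
nesting competitor (about 60% for the empty DAG, which has three independent
ways to overfit), *regardless of sample size or effect size*. This is a
property of the AIC penalty, not of the implementation; misclassifications
are almost always edge-supersets of the truth (up to Markov equivalence),
never a wrong orientation. Users wanting consistency in n can substitute a
BIC-style penalty, but the default deliberately follows the classical AIC
recipe for this analysis. Measured rates under the default study conditions
(effects 0.5, noise SD 1, MAF 0.3, n = 600) are reported by
`scripts/acceptance.py`.

## Bayesian partition selection

The non-SNP variables are partitioned into γ = (U, D, I) — Unassociated,
Directly associated, Indirectly associated (independent of the SNP given
the D members). An I assignment needs a D conduit, leaving 6 valid
partitions of {GE, PHEN}. The joint law factorises as
p(Y_U) · p(Y_D | Y_U, s) · p(Y_I | Y_D); only the D-regression depends on
the hypothesis, so the Bayes factor of a partition against the all-U null
reduces to a univariate regression Bayes factor with the U members as
covariates, and I members contribute no factor.

The per-regression model is y = Wα + sβ + ε with the conjugate prior
β | σ² ~ N(0, σ_a²σ²) and improper flat priors on (α, log σ²) that cancel
between numerator and denominator. With W projected out (residual vectors
ỹ, s̃; q = ncol(W)):

    BF(σ_a) = (σ_a² A)^(−1/2) (R₁/R₀)^(−(n−q)/2),
    A = s̃ᵀs̃ + σ_a^(−2),  R₀ = ỹᵀỹ,  R₁ = R₀ − (s̃ᵀỹ)²/A.

The genotype is standardised internally so σ_a is interpretable as a
standardised effect size; the default grid {0.1, 0.2, 0.4} spans small to
moderate genetic effects and is averaged on the BF scale with equal
weights. As σ_a → 0 the prior collapses onto the null and BF → 1; the
closed form is verified against brute-force quadrature over β (relative
error < 1e-6 asserted; ~1e-14 observed). Because the prior scales with the
residual SD, every log BF is exactly invariant to affine rescaling of the
response.

For D = {GE, PHEN} the chain-rule factorisation with independent
per-regression priors is not exactly order-invariant; the implementation
averages the two orderings' log₁₀ BFs (a geometric mean of the BFs), which
symmetrises the partition at the cost of being an approximation to either
pure ordering.

Partition → model mapping: all-U → null; D={GE},U={PHEN} → (f);
D={GE},I={PHEN} → (b); D={PHEN},I={GE} → (c); D=both → (a);
D={PHEN},U={GE} has no conventional letter and carries a descriptive label.

**Blind spots and near-ties.** The collider (d) has no partition
representation: on (d)-type data the winner is D={GE},U={PHEN}, i.e. label
(f), while SEM recovers (d) — the methods disagree there by construction,
and the per-trio report exposes this. Conversely, when the phenotype is
truly unrelated to both SNP and expression, the partitions
D={GE},U={PHEN} and D={GE},I={PHEN} differ only in whether an irrelevant
covariate enters W, making their Bayes factors a finite-sample near-tie;
selections between them are close to a coin flip and the result is flagged
(`near_tie`) whenever the top-two margin is below 0.1 log₁₀ units.

## Filtering

Stage 1 regresses the adjusted phenotype on each sex-corrected probe;
stage 2 regresses each passing probe's expression on every SNP dosage
(additively coded, pairwise-complete per SNP). Both are OLS slope t-tests —
algebraically identical to the Pearson-correlation t-test — and a pair
enters causal modelling when −log₁₀ p is strictly greater than the
threshold (default 5.0) at both stages. No multiple-testing correction is
applied at this stage by design; the threshold plays that role. The scans
assume unrelated individuals; for family data a kinship-aware mixed model
would replace them (any scan producing the same result-table shape slots
in). Zero-variance probes and sample-monomorphic SNPs get p = 1 with a
warning rather than an error, so a single degenerate unit cannot abort a
genome-wide scan.

## Coexpression modules

The unsigned weighted network is a_ij = |cor(x_i, x_j)|^β (soft power β,
default 6, the conventional unsigned default; an approximate scale-free
criterion `pick_soft_threshold` is provided — smallest candidate power with
fit R² ≥ 0.8, else the max-R² candidate). Topological overlap is

    TOM_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),

with ℓ_ij the shared-neighbour sum and k_i the connectivity; probes are
clustered by average linkage on 1 − TOM and the tree is cut at a fixed
height (static cut), with clusters below `min_module_size` (default 10)
sent to "grey". Module labels follow the conventional colour ordering by
decreasing size, so a colour has a stable meaning across runs; eigengene
orientation (positive mean correlation with members) makes signs
reproducible.

**Why cut height 0.95.** For a one-factor module with probe–factor loading
L, the within-module TOM concentrates near L^(2β) (≈ |r|^β with
|r| = L²), so the dendrogram merge height is ≈ 1 − L^(2β): about 0.93 at
L = 0.8, β = 6, while unrelated probes merge at ≈ 1.0. A cut at 0.95
separates these regimes and keeps modules with loadings down to ~0.78
intact; cutting at 0.90 would shred genuine modules of that strength into
grey. The static cut is a deliberate simplification of the dynamic hybrid
tree cut used by the full WGCNA toolchain; it recovers planted structure
(ARI ~1.0 at loading 0.8, n = 300) but has no adaptive per-branch height.

The eigengene is the first principal-component score of the standardised
member probes, unit-variance scaled; variance explained is the leading
eigenvalue share. Module–trait association is a Pearson correlation test
with Bonferroni correction over (modules × traits).

## Phenotype adjustment

For each visit separately, the trait is regressed on the covariates
(default age, medication, smoking; sex optional; "age2" available as
squared mean-centred age to reduce collinearity — raw age² by flag), and
residuals are averaged over an individual's observed visits. Per-visit fits
(rather than one pooled regression) let covariate effects differ by visit;
a pooled mode is available. Individuals missing a visit contribute their
observed visits only. A constant covariate column raises a singular-design
error rather than silently dropping the covariate. Medication enters as a
regression covariate, not as a fixed mmHg offset.

## The synthetic cohort generator

`simulate_trio` draws the SNP as Binomial(2, MAF) and generates GE/PHEN in
topological order as linear functions of their parents plus independent
Gaussian noise — effects are raw structural coefficients, so recovery tests
read directly off the spec of the generating DAG. `simulate_cohort` layers
a per-module one-factor expression model (probe = loading × factor + noise
with noise SD √(1 − loading²), so loading = probe–factor correlation and
probes have unit variance), i.i.d. SNPs, and a longitudinal trait: a
covariate linear predictor (age ~ U(20, 80) constant across visits,
sex ~ Bern(0.5), medication and smoking ~ Bern(0.2)) plus coupling × the
causal module's factor plus per-visit noise. Exactly one causal chain
SNP → factor → trait is planted when coupling is nonzero. Trait units are
arbitrary; effects are calibrated against per-visit noise SD 1. Default
study conditions used throughout calibration: n = 600, structural effects
0.5, MAF 0.3, three visits, module loading 0.8, coupling 0.3.

Deliberately not emulated: family relatedness/kinship, linkage
disequilibrium between SNPs, non-Gaussian expression noise, age drift
across visits, and probe-level technical covariates. Passing tests
therefore demonstrate correctness of the machinery and its calibration on
unrelated, LD-free, Gaussian data — not robustness to pedigree structure or
expression artefacts.

An important subtlety of the cohort design: at the probe level the planted
chain is SNP → latent factor → trait, with probes as noisy indicators of
the factor. A probe-level trio is therefore only approximately mediation
(b) — the residual partial association of SNP and trait given one probe
scales with the probe's measurement error, ~(1 − L²). At loadings ≥ 0.95 it
is negligible at n = 600; eigengene trios average it away almost entirely.

## Numerical choices

- OLS everywhere via QR/lstsq; scans vectorised with pairwise-complete NaN
  masking; p-values from the t log-survival function so −log₁₀ p stays
  finite when p underflows (p is clipped to the smallest positive double).
- Bayes factors averaged on the BF scale via logsumexp.
- Linkage ties follow scipy's deterministic ordering; module colours are
  assigned by (size, lowest member index), making dendrograms and labels
  run-reproducible. Reports format floats at 6 significant digits; JSON
  carries full precision; identical config + seed reproduces every output
  byte.
- Degenerate inputs fail loudly where silence would corrupt inference
  (constant covariate, collinear GE/PHEN, monomorphic SNP used as a parent,
  zero-variance probe in the network) and degrade gracefully where a scan
  should continue (per-unit p = 1 with a warning).

## Known limitations

- AIC's irreducible overfit rate bounds sparse-model recovery (~84% per
  nesting competitor; ~60% for the empty DAG) — see above.
- The Bayes-factor prior family and grid are this package's choice of a
  standard conjugate construction; numerical agreement with other
  implementations of partition-based Bayesian model selection is not
  claimed.
- The D=both partition's order-symmetrisation is an approximation.
- Static tree cut; no dynamic hybrid cutting, signed networks, bicor, or
  block-wise computation for very large probe sets.
- OLS scans assume unrelated individuals (no kinship correction).
- Only the two-variable (single trio) case of the partition framework is
  implemented.
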