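# Methods

This note records the models implemented in `culmat`, the assumptions they
make, the defaults chosen where the design was open, and the limits of
what the synthetic-panel tests demonstrate.

## Bend-test mechanics

A dried internode section rests on supports a span L = 25 mm apart and is
loaded centrally, so the half-span is a = L/2 by construction (the code
enforces this to 1e-9).  Cross-section areas from image analysis are
converted to equivalent circular diameters, D = 2√(A/π), and the annular
second moment of area is I = π(D2⁴ − D1a⁴)/64.  Material strength is then
MOR = Fmax·a·D2/I and MOE = (F/V)·(a²/12)(3L − 4a)/I, which with a = L/2
equals (F/V)·L³/(48I).

Two conventions deserve note.  First, `F/V` is consumed exactly in the
instrument's recorded slope units (force per unit time at a constant 2
mm/s probe speed, hence proportional to force per unit deflection); no
unit conversion is applied, so MOE stays on the reporting scale
conventional for this assay even though a strict dimensional reading of
the formula would require a deflection slope.  Second, the MOR expression
is implemented as written above even though it differs by a constant
factor from the textbook three-point flexure stress σ = F·L·D/(8I);
fidelity to the assay's established formula wins over the textbook
constant, and since the factor is common to all specimens it does not
affect association results.

Per-specimen geometry feeds per-specimen moduli (an alternative —
accession-mean geometry — was not adopted; replicate-level moduli are
aggregated afterwards instead).  Replicates are combined by the additive
fixed-effects least-squares model `value = μ + genotype + year + ε` with a
sum-to-zero year constraint, returning μ + genotype per accession.  On
balanced data this equals the arithmetic mean and it absorbs any uniform
year shift; it stands in for a REML prediction whose variance-component
specification would otherwise be arbitrary, and the two coincide on
balanced designs.  The correlation table reports pairwise-complete Pearson
r, R², and the two-sided P from t = r√((n−2)/(1−r²)), starred at the
conventional 0.05/0.01/0.001 levels.

## Marker scoring

SNP calling from allele read depths applies the 0.15 noise threshold at
two levels, since a single stated value must police both sequencing noise
and paralogy:

* panel-wide, an allele is *real* only if it carries ≥ 15 % of the pooled
  reads at the site; sites with more than two real alleles (likely
  homoeologue collapse) or fewer than two (monomorphic) are excluded;
* within an accession, the minority fraction among the two real alleles
  must be < 15 % for a homozygous call — the panel is fully inbred, so a
  genuinely mixed signal is evidence of artefact and is scored missing.

Accessions with fewer than `min_depth = 4` reads at a site are missing;
the value is a package default (no depth rule is inherited from the
assay description) and is exposed as a flag.  Genotypes are coded as
minor-allele dosage {0, 2}: hexaploid bread wheat lines are inbred and the
genome-specific transcriptome reference makes markers behave
diploid-homozygous, so no heterozygote class exists.

MAF is computed on called accessions only and the < 5 % removal is a
strict inequality (MAF exactly 0.05 is retained); markers whose stored
coding no longer counts the rarer allele after missing-data handling are
re-oriented.  RPKM is 1e9·c/(N·l); the < 0.4 abundance filter is read as
*mean* across accessions (the natural summary when the filter is meant to
remove unexpressed transcripts), with `statistic="max"` available since
the phrase "across accessions" also admits that reading.

## Population structure

Kinship defaults to the IBS proportion — the fraction of pairwise
non-missing markers with identical calls — matching the era's common
association-tool default; a centred VanRaden GRM is available behind a
flag.  Admixture is the standard model with independent allele
frequencies: accession i's allele at site j is drawn with probability
Σ_k q_ik p_kj, and for inbreds the dosage/2 is a single Bernoulli draw.
The original Bayesian MCMC sampler is replaced by a maximum-likelihood EM
fit (3 random restarts per K by default; the EM log-likelihood is monotone
and is asserted so in tests); replicate-fit spread substitutes for MCMC
run-to-run spread in the Evanno denominator,

    ΔK = |mean L(K+1) − 2 mean L(K) + mean L(K−1)| / sd(L(K)),

with the best K the ΔK argmax over the interior of the grid.  Missing
genotypes are mean-imputed inside the E-step only, never in the stored
matrix.  Q rows sum to one, so the covariate matrix passed to association
drops the last ancestry column to avoid collinearity with the intercept.

## Mixed-model association

The SNP scan fits y = Xβ + u + e with u ~ N(0, σ²g K), e ~ N(0, σ²e I).
REML profiles the ratio δ = σ²e/σ²g on the spectrum of K projected off the
null design (the EMMA device): log10 δ is gridded on [−5, 5] with 61
points and refined by bounded golden-section search (tolerance 1e-8 on the
log-likelihood); a maximiser pinned to the grid edge is returned flagged.
By default the null components are reused for every marker (P3D); exact
per-marker re-estimation is available and agrees within |Δlog10 P| < 0.2
on moderate-effect panels.  Each marker enters as a single continuous
dosage covariate (1-df F-test; no dominance term — the panel is inbred).
Missing genotypes drop the accession for that marker (casewise deletion),
preserving per-marker sample sizes; complete-data markers are scanned in
one whitened, vectorised pass.

GEM association regresses RPKM (response) on the trait (predictor), per
the method's published orientation; the two-sided P is symmetric in the
two roles, so the orientation only fixes the reported slope's meaning.  No
structure correction is applied by default — mirroring the original
analysis — but Q covariates can be added by flag (the residual degrees of
freedom then ignore the covariate count, a deliberate simplification at
panel sizes of ~100).  `gem_as_trait` feeds one unigene's RPKM vector into
the SNP scan unchanged.

Association tables are ordered by natural chromosome label sort (1A, 1B,
1D, 2A, …, unplaced last) with ordinal map positions and a cumulative x
coordinate; ties break on marker id.  Bonferroni and Benjamini–Hochberg
columns are informational — peak declaration in this tradition is by
inspection of the −log10 P profile, and no hard threshold is imposed.

## Validation

Test-panel accessions are selected greedily, round-robin across the
observed allele-class combinations at the target loci (monomorphic loci
are excluded with a warning; a fully monomorphic panel is an error),
deterministic given input order, so selection uses genotype information
only.  The segregation test is a pooled-variance Student t, one-sided in
the direction "increasing-allele carriers score higher", matching the
original software's default; Welch and two-sided variants sit behind
flags.  Two constant identical classes return P = 0.5 by convention.
Effect sizes are quoted per allele copy, so homozygous classes sit two
copies apart; at that convention a 0.5-sd-per-copy marker gives ~85 %
one-sided power at n = 30 balanced.

## Synthetic panel

Genotypes follow the Balding–Nichols construction (ancestral frequencies
Uniform(0.05, 0.95); population frequencies Beta with drift parameter
F = fst; Dirichlet(α) admixture; one allele draw doubled).  Defaults
mirror the analysed panel where its design is known and plausible values
elsewhere: 100 accessions, two years with 10 and 5 replicate plants and a
0.5-unit year offset, mean read depth 6 (the study reports ≈5.9× average
coverage), 1 % sequencing error, K_true = 3 ancestral groups at fst = 0.3
with α = 0.2 (strong but admixed structure), 2,000 SNPs and 1,000 unigenes
at desk scale, polygenic heritability 0.5 with unit replicate noise.  No
effect sizes or heritabilities are reported for the real panel, so these
are working values, not estimates of it.  Trait baselines put MOR near 4
N mm⁻² and MOE near 800 N mm⁻², inside the reported trait ranges; MOE
shares the latent strength signal through an affine transform plus noise
so the two moduli correlate positively as observed.  Replicate moduli are
floored at small positive values before specimen inversion, as the
inversion requires positive latent strength.

Expression counts are Poisson around 2^(baseline + cis·dosage/2 + noise)
× length × library factor (negative-binomial overdispersion was considered
and left out; Poisson suffices for the properties tested, and an exact
no-noise mode exists for algebraic checks).  Read depths are Poisson
totals with uniform misreads.  Specimens are generated by algebraically
inverting the mechanics formulas from the latent moduli, so the derivation
chain is exact to numerical precision — a designed-in oracle.

What the generator does **not** emulate: linkage disequilibrium along
chromosomes (markers are exchangeable given structure), homoeologous read
misassignment, GC/length biases in expression, genotype–environment
interaction beyond additive year offsets, and measurement error in the
cross-section images.  Passing tests therefore demonstrate the statistical
machinery — calibration, recovery, exact rule application — not robustness
to those artefacts in real data.

## Problem sizes in the acceptance experiments

The from-scratch experiments use 20 replicate panels of n = 100 accessions
with m = 2,000 markers for calibration and SNP recovery, m = 500 markers
for the ΔK study (sufficient to separate the groups while keeping the
replicate EM fits brisk), 500 unigenes for GEM recovery, and 1,000 random
geometries for the mechanics oracles.  All randomness in
`scripts/acceptance.py` derives from the `--seed` argument through spawned
child streams.

## Known limitations

* The EM admixture fit finds local maxima; restarts mitigate but do not
  guarantee the global optimum, which is also why replicate spread is a
  usable ΔK denominator.
* IBS kinship has a high baseline in structured panels; REML absorbs the
  scale, but reported σ²g is only meaningful relative to the chosen
  kinship normalisation.
* P3D slightly misstates per-marker variance components for markers with
  substantial missingness (the sub-panel spectrum is recomputed but δ is
  not re-estimated); exact mode exists where that matters.
* The GEM regression inherits RPKM's mean–variance coupling; no variance
  stabilisation is applied, matching the original method.
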