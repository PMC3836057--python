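# Methods

## Setting and estimands

Data are n complete trios: father, mother and offspring genotyped at one or
more biallelic markers (genotypes coded additively as minor-allele counts
0/1/2), with the offspring phenotyped for a continuous primary outcome Y, a
continuous secondary phenotype K, and measured covariates L that are common
risk factors of K and Y. The null hypothesis of interest, per marker, is
that the marker X has **no direct effect on Y**: any X–Y association is
mediated entirely by K.

Conditioning on the parental genotype pair S = (father, mother), Mendelian
transmission fixes the offspring genotype distribution exactly:
E(X|S) = (father + mother)/2 and Var(X|S) = (number of heterozygous
parents)/4. Trios without a heterozygous parent are uninformative for the
within-family contrast.

## The two statistics

**Confirmatory direct-effect FBAT.** γ₁ (the K→Y effect) is estimated by
OLS from model (1), E[Y|X,K,L] = γ₀ + γ₁K + γ₂X + γ₃L. The adjusted
phenotype Ỹᵢ = Yᵢ − ȳ − γ̂₁(Kᵢ − k̄) removes the estimated mediated
component; L is deliberately *not* subtracted because L may itself be
affected by the marker, and subtracting it would re-introduce a genotype
signal into the "null" phenotype. Per-subject contributions are
Tᵢ = (Xᵢ − E(Xᵢ|Sᵢ))Ỹᵢ. Because γ̂₁ is estimated, each contribution is
corrected,

    T̃ᵢ = Tᵢ − Ê[(X − E(X|S))(K − k̄)] · (Kᵢ − μ_k⁽ⁱ⁾)/σ²_k · εᵢ ,

where μ_k⁽ⁱ⁾ and σ²_k come from an OLS nuisance regression of K on
(1, L, X, E(X|S)), εᵢ is the model-(1) residual, and the expectation is the
plug-in sample average. The statistic (Σᵢ Tᵢ)² / (n·s²(T̃)) is referred to
χ²₁; s² is the centered, unbiased sample variance (an uncentered Σ T̃ᵢ²
variant, the classical FBAT empirical variance, is available via
`variance="uncentered"`; the two coincide asymptotically under the null).

**Screening statistic.** The same construction from model (2),
E[Y|K,L,S] = β₀ + γ₁*K + β₂L + β₃E(X|S), which replaces X by its Mendelian
expectation and therefore never reads offspring genotypes. Contributions
are T*ᵢ = (E(Xᵢ|Sᵢ) − mean)·Ỹ*ᵢ with the analogous correction from the
nuisance regression of K on (1, L, E(X|S)).

Two deliberate numerical choices, both invisible asymptotically:

- **Centering of the expected score.** T*ᵢ uses E(X|S) centered at its
  sample mean. The sum Σ T*ᵢ is identical either way (Σ Ỹ*ᵢ = 0 exactly),
  but an uncentered per-subject variance would include the large squared
  mean of E(X|S) (≈ (2p)² against Var = p(1−p)) and make the test severely
  conservative — rejection rates near zero instead of the nominal 5%.
- **Centering of K in the correction expectation.** The direct test uses
  Ê[(X−E(X|S))(K − k̄)]. The uncentered form differs by k̄·mean(X−E(X|S)),
  an O(n^−1/2) term that would break exact invariance of the statistic to
  the location and scale of K. With centering, replacing Y by aY+b or K by
  cK+d leaves both statistics unchanged to machine precision.

Degenerate inputs: a marker with no informative trio (or a monomorphic
offspring column, or zero variance of T̃) yields `defined=False` and is
treated as a non-rejection; a constant expected-score column is dropped
from model (2) and the screen statistic is exactly 0, ranking behind any
informative marker. Trios with a missing genotype or phenotype are dropped
per marker (complete-case), with counts logged. Screening ties break by
ascending marker index; undefined statistics rank last.

## The two-stage procedure

Stage 1 computes the screening statistic for all M markers and keeps the
top m = ⌈0.05·M⌉ (3 of 50, 5 of 100; an explicit m can override). Stage 2
runs the direct-effect FBAT on those m markers and rejects at p < α/m
(Bonferroni over the screened-in set; Sidak over m optional). The screen
conditions only on parental genotypes and phenotypes, the FBAT only on the
within-family transmissions given S, so stage 1 spends no α — redrawing the
transmissions changes every stage-2 p-value but leaves the stage-1 ranking
bit-identical (this independence surrogate is asserted in the tests). The
screen itself assumes no population substructure; the confirmatory FBAT
remains valid under stratification. The number m must be fixed in advance —
scanning m until something is significant inflates the type-1 error.

The single-stage comparator tests every marker and rejects at the Sidak
level 1 − (1−α)^(1/M).

## The synthetic-data generator

Phenotypes follow a linear structural model driven by the causal marker's
offspring genotype X and a latent standard-normal confounder U:

    L₁ = c·X + δ·U + e_L         L₂ = e_age
    K  = a·X + b₁L₁ + b₂L₂ + η·U + e_K
    Y  = d·X + γ₁K + f₁L₁ + f₂L₂ + ζ·U + e_Y

Noise variances are solved exactly (via the loadings on the independent
sources) so L₁, K and Y each have unit total variance; slopes are therefore
in SD units and variance fractions are exact, not approximate. Defaults:

| parameter | meaning | default |
|---|---|---|
| `h2_k`, `h2_l` | locus heritability of K and L₁ | 0.01 |
| `var_y_k` | fraction of Var(Y) explained by K (γ₁ = 0.1) | 0.01 |
| `direct_slope` | per-allele direct X→Y effect (power runs) | √0.025 ≈ 0.158 |
| `var_y_direct` | direct effect as a variance fraction (alternative) | 0 |
| `l1_to_k`, `l2_to_k` | covariate effects on K | 0.5, 0.2 |
| `l1_to_y` | *causal* L₁→Y slope | 0 |
| `l2_to_y` | causal L₂→Y slope (L₂ never genotype-dependent) | 0.2 |
| `u_to_l`, `u_to_y`, `u_to_k` | confounder loadings | 0.5, 0.3, 0 |

Scenarios: 1 = {X→K, X→L, K→Y}; 2 = scenario 1 without X→L; 3 = scenario 1
without K→Y; 4 = scenario 2 without X→K. Setting an edge flag false is
byte-identical to setting its variance fraction to zero under the same
seed.

Two defaults deserve justification:

- **The L₁–Y association is confounding, not causation.** A causal L→Y
  slope combined with the X→L edge would create an unmediated X→L→Y path,
  so the "no direct effect" null would be false by construction in
  scenarios 1 and 3 (the type-I error of the FBAT would sit near 0.11
  rather than 0.05 at MAF 45%). L₁ and Y are therefore associated through
  U only. A consequence worth knowing: with the X→L edge present, γ̂₁*
  from model (2) retains a small residual confounding bias (≈1% of γ₁ in
  scenario 1) that model (1) avoids by conditioning on X; without X→L the
  two estimands coincide exactly. This gap is far too small to disturb the
  screening statistic's calibration, whose variance correction accounts
  for estimating γ₁* whatever its limit.
- **Power runs use a fixed per-allele slope.** A constant locus
  heritability makes the FBAT noncentrality n·d²·p(1−p)/Var(Ỹ) flat in
  allele frequency; a fixed allelic slope makes it grow with p(1−p),
  which is the profile single-SNP power follows in this design (≈0.2 at
  MAF 5% rising to ≈0.7 at 45% for n = 1000 at α = 0.05). The default
  d = √0.025 corresponds to ≈1% locus heritability at mid-grid
  frequencies. The heritability parameterization remains available
  (`var_y_direct`), as does a correlation parameterization via
  `correlation_to_coefficient`.

Stratification designs split the trios into two populations with different
allele frequencies at *every* marker and shift population 2's phenotype
means (default 0.5 SD for both Y and K) — a concrete realization of U.
Slopes are derived from the exact mixture variance of X. With equal
frequencies and zero shift the stratified generator reproduces the
unstratified stream bit-for-bit under the same seed.

**What the generator does not emulate:** linkage disequilibrium between
markers (markers are independent), ascertainment bias, binary or censored
phenotypes, non-Gaussian noise, assortative mating, and missing parental
genotypes. Passing tests therefore demonstrate calibration and power under
an idealized trio design, not robustness to these real-data features.

## Monte Carlo harness

Tables are produced per (scenario, allele frequency) cell with replicate
seeds derived deterministically from (master seed, scenario, frequency,
replicate index), so any replicate can be replayed in isolation and a
table re-run is bit-exact. Every rate carries its binomial Monte Carlo SE.
Defaults mirror the study conditions (1000 trios, 5000 replications,
frequencies 5–45% in 5% steps, α = 0.05); the test suite and CLI default
to reduced replication counts (300–1000) with correspondingly widened
tolerances, and the acceptance script uses 10000 replicates per type-I
cell and 5000 per power cell. Multi-SNP runs rank 50 (or 100) markers per
replicate and confirm the top 3 (or 5); the single-stage comparator rate
for the causal SNP is computed from the causal marker's FBAT against the
Sidak threshold, which is equivalent to running the full single-stage
procedure for that metric.

## Known limitations

- Complete trios only: the sufficient-statistic generalization to missing
  parents is out of scope (the PED reader simply skips incomplete
  families, and `TrioMarker` leaves the hook).
- The screening step has no built-in stratification correction (e.g. no
  principal-component adjustment); the harness can simulate stratified
  panels to quantify the impact, and the procedure warns when a panel
  carries population labels.
- Direct-effect testing only — no effect-size estimate or confidence
  interval, and no binary-trait support.
- Panels are expected at candidate-region scale (tens to hundreds of
  markers), not GWAS scale.
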