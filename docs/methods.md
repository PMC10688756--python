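# Methods

This note documents the models, the numerical choices, and what the
synthetic study systems do and do not emulate.

## Composition-controlled proportion of direct developers

The raw per-site proportion of direct-developing species confounds the
trait with species composition: under random membership a site's
expected proportion is simply the pool fraction of direct developers.
The null model therefore permutes the species → development-type map
over the entire regional pool (the D matrix), holding incidence fixed,
and recomputes all site proportions per replicate.  One seeded
`numpy.random.Generator` stream drives all replicates (replicate *r*
uses the *r*-th permutation), so SES tables are bit-reproducible; the
species axis is sorted into canonical order before permutations are
drawn, making results invariant to input column order.  Sites where
the null SD is zero (e.g. a constant trait vector) are flagged
`defined = False` and their SES reported as NaN, never as 0; the zero
test is scale-aware (SD below 1e-10 of the null-mean magnitude), since
a relabelling-invariant statistic produces rounding-level jitter
rather than exact zeros.  Defaults: 999 randomizations.

## Phylogeny-weighted composition and PCPS

Similarity is `S = 1 − D/max(D)` on patristic distances (unit
diagonal); each site row of `incidence × S` is renormalized to sum
to 1.  PCPS ordinates square-root Bray–Curtis dissimilarities among
P-matrix rows by classical (Gower) PCoA: double-centre
`B = −½·J·D²·J`, eigendecompose, scale axes by √λ.  Negative
eigenvalues are reported but excluded from the fraction-of-variation
denominator, and no Cailliez/Lingoes correction is applied — the
convention of the reference PCPS implementation; the square-root
transform keeps them negligible in practice.  Eigenvalues within
1e-10 of zero (relative to the largest) are treated as null axes.

Phylogenetically uncertain taxa are attached at the crown node of
their MDCC with a pendant branch equal to the clade height (mean
root-to-tip distance within the clade — exact for ultrametric trees).
Attaching at the crown node leaves all existing path lengths
untouched, so insertion followed by pruning is an exact inverse; the
named tip set must be exactly monophyletic or the conflict is named in
the error.

## Trait imputation under multivariate Brownian motion

Continuous traits are modelled as correlated Brownian motions along
the tree: the stacked trait vector is multivariate normal with
covariance `C ⊗ R`, where `C` holds shared branch lengths
(root-to-MRCA depths) and `R` is the evolutionary trait covariance.
Root means and `R` are estimated by EM over the missing entries
(conditional-normal E-step on the observed/missing partition;
closed-form GLS mean and `C⁻¹`-weighted scatter M-step including the
conditional-covariance correction).  Convergence: relative
observed-data log-likelihood change below 1e-6, at most 500
iterations; `R` is initialized from complete cases when at least
`p + 2` exist, otherwise from observed marginal variances.  A
non-positive-definite `C` (duplicate zero-length tips) is refused with
an explicit message rather than silently jittered.  Observed entries
are returned unchanged; categorical traits are never imputed.

## PVR, functional dendrogram, FD, SES.FD

PVR is the PCoA of the cophenetic-distance matrix; the retained axis
count is the smallest whose cumulative share of positive eigenvalues
reaches the variance fraction (default 0.95).  Features (z-scored
continuous traits + one-hot categorical traits, already unit range)
are regressed on the retained axes and the residuals carried forward.
Development-related traits stay in the matrix by default (excluding
them is a switch, `include_development=False`), reflecting the
observation that their removal does not change the results.

The dendrogram is UPGMA on Euclidean feature distances.  Node depths
are merge-height/2, so cophenetic tree distance equals merge height
and the tree is ultrametric by construction.  FD of a species set is
the summed length of all edges on the union of tip-to-root paths —
root-inclusive, so a single species scores its tip-to-root length and
the full pool scores the total tree length.  Internally edges carry a
tips × edges descent indicator, making per-site FD one boolean matrix
product; the label-shuffling null (999 randomizations) permutes tip
rows of that indicator.  SES.FD uses the same SES machinery as %DD:
negative = functional clustering, positive = overdispersion.

## Spatial GLS

Errors are correlated as `exp(−d/ρ)` with planar Euclidean distances
on (longitude, latitude) degrees — the convention of the standard
corExp structure; no nugget.  Estimation is maximum likelihood (never
REML), because the SEM's d-separation tests compare likelihoods across
fixed-effect structures.  ρ is profiled on a 19-point log grid from
dmin/10 to 10·dmax (with ρ = 0, i.e. OLS, always a candidate) and
refined by bounded scalar minimization; β̂ is the GLS solution at the
optimum.  Wald t-tests use the df-adjusted variance `σ̂²·n/(n−p)` with
`n − p` degrees of freedom.  `AIC = −2·logLik + 2·(p_fixed + 2)`
(fixed effects + variance + range).  Duplicate coordinates are handled
by a 1e-10 ridge on the correlation matrix.  Moran's I uses
inverse-distance weights with zero diagonal and a 999-permutation
p-value (two-sided by default around `E[I] = −1/(n−1)`).

Calibration was checked by simulation: with residuals drawn from the
exponential family the t-test of a null predictor rejects at the
nominal 5% rate (±1%) whether ρ is estimated or fixed at truth
(400 replicates, n = 400).

## Piecewise SEM

The causal hypothesis is an edge list; each endogenous node is fitted
by the spatial GLS on its parents.  The basis set contains one claim
per non-adjacent pair, excluding exogenous–exogenous pairs (treated as
freely correlated), directed at the variable later in topological
order, conditioned on the union of both variables' parents; the claim
is tested by adding the independent variable to the response's
submodel and reading its coefficient p-value.  Fisher's
`C = −2·Σ ln pᵢ` is referred to χ²(2k); the model is "valid" when
`p > 0.05`.  A claim p of exactly 0 is refused (log divergence) with
guidance to report the claim directly.  Standardized coefficients are
`β̂·SD(x)/SD(y)` (the raw β̂ on z-scored data, the default); R² per
endogenous variable is the squared Pearson correlation of fitted and
observed values — a deliberately simple, monotone definition, since no
specific GLS-R² variant is canonical.

For the study DAG — four abiotic gradients into PCPS1 and SES.FD, and
all six into %DD, with no PCPS1–SES.FD edge — the basis set is the
single claim `SES.FD ⟂ PCPS1 | {BIO4, BIO12, ET0, slope}`, hence
df = 2.

## Synthetic study systems

Two generators with different purposes:

**Mechanistic** (`make_scenario`): birth–death tree conditioned on the
tip count (extinct lineages pruned; every pendant edge is extended by
0.1% of tree depth because the simulator stops exactly at the n-th
birth, which would leave a zero-length cherry and a singular C
matrix).  Direct development is painted onto a few disjoint clades
chosen to total ≈ the target fraction (error if no combination lands
within ±50%).  Morphometrics are correlated BM (tip-level SDs 12/4/6
mm around means 45/15/20 mm, correlation 0.8 — strong, as real
morphometrics are — floored at 0.5 mm); categoricals follow
latent-BM thresholds so they carry phylogenetic signal; missingness is
completely at random.  Environments are unit-variance Gaussian
processes with exponential covariance (range 3° over a 20° × 25°
domain, climate variables cross-correlated at 0.2) put on realistic
raw scales.  Communities arise from a logistic Gaussian-niche model
whose optima are BM along the tree (clade-structured composition, so
PCPS axes are meaningful); direct developers receive an occupancy
penalty (−2 logits, keeping them rare, as observed) and an
environmental-filter term `−1.5·(z_ET0 + z_BIO4 − z_slope)/√3`
implanting the abiotic → %DD link; sites with expected richness < 3
get a suitability boost and sub-2-species draws are redrawn.  Default
sizes are the study conditions: 766 sites, 464 species, ≈ 49 direct
developers in 3 clades, missingness 139/464 and 146/464 for the two
morphometrics.

**Linear-Gaussian** (`simulate_sem_dataset`): site variables generated
directly from the declared path structure with unit population
variances, so the declared standardized coefficients are exact ground
truth.  Default paths use the study's reported values where available
(ET0 → %DD = −0.451, BIO4 → %DD = −0.305, SES.FD → %DD = +0.231) and
once-chosen values for the remainder, sized to give endogenous R² near
the reported magnitudes (≈ 0.15 for PCPS1, ≈ 0.10 for SES.FD, ≈ 0.4
for %DD).  Residuals are pure exponential-correlated fields
(range 1°) — exactly the family the GLS fits, which has no nugget —
so inference is exercised under a correctly specified model.

What the generators do **not** emulate: dispersal limitation and biome
boundaries, observation error in occurrences, non-random trait
missingness, and any feedback from communities to environment.  The
mechanistic generator induces the causal structure qualitatively but
its emergent standardized paths are not controlled; exact-coefficient
recovery claims therefore always refer to the linear-Gaussian
generator.  Consequently, passing tests show that the estimators
recover what they are defined to estimate under the stated sampling
models — not that the fitted values for any particular empirical
dataset are correct.

## Problem sizes and determinism

All tests and the acceptance script run on generated data: the full
766 × 464 system for descriptive, PCPS, PVR, and SES stages; the
SEM recovery check uses 20 replicate site tables at n = 766 (reported
coefficients in the acceptance script average 5 replicates).  Every
random stage takes an explicit seed and is bit-reproducible; child
seeds are small fixed offsets of the master seed.

## Known limitations

- The MDCC crown-height rule is one reasonable convention; stem-ward
  insertion points would shorten new-tip distances.
- The EM imputation builds the full kron(C, R) covariance; fine for
  hundreds of species × a few traits, not for thousands.
- SES of %DD does not remove clade-level niche effects: a clade that
  happens to prefer one end of a gradient produces SES–environment
  correlation even without a causal trait-environment link.  This is a
  property of the D-matrix null itself, visible in the mechanistic
  generator at `dd_env_effect = 0`, where only the across-scenario
  mean correlation vanishes.
- Distances are planar degrees by design (matching the reference GLS
  convention); at the study extent the lon/lat anisotropy is absorbed
  by ρ but geodesic distances would differ.
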