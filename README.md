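# anurasem

Community-phylogenetic analysis of **direct development** in anuran
(frog) assemblages: which abiotic gradients and community-level biotic
properties explain the proportion of species that skip the free-living
tadpole stage?

The package implements the full analysis chain for a sites × species
incidence dataset with coordinates, a species trait table, a dated
phylogeny, and per-site environmental predictors:

1. **Composition-controlled %DD** — the observed per-site proportion of
   direct developers is standardized against a D-matrix null model
   (the species → development-type map is permuted over the whole
   regional pool, 999 randomizations):
   `SES = (obs − mean_null) / sd_null`.
2. **Phylogenetic composition (PCPS)** — incidences are smoothed by
   phylogenetic similarity `S = 1 − D/max(D)` into the row-normalized
   **P matrix**; a principal coordinates analysis of square-root
   Bray–Curtis dissimilarities among its rows yields orthogonal axes of
   phylogenetic structure (axis 1 = deepest splits).  Taxa missing from
   the reference tree are inserted at their most derived consensus
   clade (MDCC), ultrametrically at the crown node.
3. **Functional diversity (SES.FD)** — missing continuous traits are
   imputed by maximum likelihood under multivariate Brownian motion
   (EM over the C ⊗ R tip covariance); traits are freed of phylogenetic
   autocorrelation by regression on the leading phylogenetic
   eigenvectors (PVR, 95% of cophenetic variation); the residual
   feature matrix is clustered (UPGMA) and per-site FD is the summed
   branch length of the dendrogram subtree (root-inclusive, Petchey &
   Gaston), standardized against a tip-label-shuffling null.
4. **Spatial GLS and piecewise SEM** — every submodel of the declared
   causal DAG (BIO4, BIO12, ET0, slope → PCPS1, SES.FD → %DD, plus
   direct abiotic → %DD paths) is fitted by maximum-likelihood GLS with
   exponential spatial correlation `corr(d) = exp(−d/ρ)`; the DAG's
   missing edge implies one conditional-independence claim, tested by
   d-separation and summarized by Fisher's `C = −2·Σ ln pᵢ ~ χ²(2k)`.

A first-class synthetic-data module generates study systems with known
ground truth — a birth–death phylogeny, a clade-concentrated binary
development trait, correlated Brownian morphometrics with missingness,
spatially autocorrelated environments, and niche-based community
assembly — so every stage is verifiable without external downloads.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
default synthetic system (766 communities, 464 species, 49 direct
developers in 3 clades):

```sh
python analysis/01_simulate_study_system.py
python analysis/02_descriptive_and_ses_dd.py
python analysis/03_phylogenetic_composition.py
python analysis/04_functional_diversity.py
python analysis/05_spatial_models.py
python analysis/06_piecewise_sem.py
```

Output of step 02 (descriptives):

```
766 communities, 464 species
direct developers in pool: 49
communities with direct developers: 266
richness mean 12.64 (SD 5.23), range 2-27
%DD mean 4.90 (SD 9.25), max DD richness 6
```

Step 06 fits the piecewise SEM on the assembled site table and prints
the standardized paths, per-endogenous R², and the d-separation
verdict:

```
      BIO4 -> %DD      -0.335 (SE 0.036, p = 0.0000)*
       ET0 -> %DD      -0.353 (SE 0.032, p = 0.0000)*
     slope -> %DD      +0.286 (SE 0.036, p = 0.0000)*
  R²(%DD) = 0.364
Fisher's C = 1.246, df = 2, p = 0.536  (consistent with the data)
```

i.e. communities in cool-stable, low-evapotranspiration, steep sites
carry an excess of direct developers — the causal structure implanted
by the generator — and the declared DAG is not rejected.  The same
numbers can be produced programmatically via
`anurasem.data_io.run_pipeline(config)` from a YAML config naming the
four inputs, the replicate count, the seed, and the DAG edge list.

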