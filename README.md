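# pedqg

Pedigree-based quantitative genetics for colonial breeders: microsatellite
parentage and sibship reconstruction, Bayesian animal models (Gibbs-sampled
variance components with DIC model selection), phenotype statistics, and a
synthetic colony simulator that makes the whole pipeline testable without
any external data.

## What it does

- **`pedqg.pedigree`** — pedigree CSV I/O and validation (acyclicity,
  sex-consistency, auto-added founders), topological ordering, inbreeding
  coefficients, pedigree summary statistics, and the additive (numerator)
  relationship matrix `A` by the tabular method.
- **`pedqg.msat`** — codominant microsatellite tables (wide CSV and GenePop),
  per-locus diagnostics (allele frequencies, observed/unbiased expected
  heterozygosity, exact Hardy-Weinberg tests), EM estimation of null-allele
  frequencies from homozygote excess, parent-exclusion probabilities Q1/Q2
  with multi-locus combination, pairwise relationship likelihoods over the
  IBD categories {U, HS, FS, PO}, likelihood parentage assignment at a 0.99
  posterior threshold, and greedy full-sib partitioning.
- **`pedqg.animal_model`** — univariate and bivariate animal models
  `y = Xb + Z_a a + Z_m m + Z_n n + e` with `a ~ N(0, A sigma2_A)`, Gibbs
  sampling via the mixed-model equations (plus an eigenbasis fast path for
  additive-only fits), scaled-inverse-chi-square / inverse-Wishart variance
  updates, KDE posterior modes with HPD intervals, variance ratios (h²,
  me², ne²), genetic correlations, conditional-focus DIC and Δ<7 model
  selection. Schedules: `fast` presets for testing and `paper` presets
  (1,000,000/100,000/100 univariate; 4,000,000/400,000/1,000 bivariate).
- **`pedqg.phenotypes`** — fledging-weight filter (default > 82 g), Pearson
  trait correlations, ANOVA/MANOVA (Wilks' lambda, Rao's F) sexual
  dimorphism tests, assortative-mating correlations from pedigree-derived
  mate pairs.
- **`pedqg.simulate`** — colony generator (nests with 1–4 chambers, one
  breeding pair per chamber, extra-pair paternity and intra-brood
  parasitism at configurable rates), Mendelian genotype dropping with null
  alleles and missingness, multivariate breeding values, and phenotypes
  with additive + maternal + nest + residual (co)variances; every generator
  is a pure function of (config, seed).
- **`pedqg.pipeline` / CLI** — end-to-end pipeline with manifest, CSV
  artifacts and a rendered report.

## CLI

```sh
pedqg simulate --out sim --seed 1 --null-freq 0.05   # write a synthetic colony
pedqg qc-loci --genotypes sim/genotypes.gen --out loci.csv
pedqg kinship --pedigree sim/pedigree.csv --out A.csv --triplet
pedqg pedigree --pedigree sim/pedigree.csv           # summary JSON
pedqg fit --pedigree sim/pedigree.csv --phenotypes sim/phenotypes.csv \
      --trait weight --terms additive,maternal --schedule fast \
      --out samples.csv
pedqg pipeline --simulate --out results --seed 1 --preset fast
pedqg report --results results
```

`pedqg pipeline` also accepts `--config run.yaml` (keys mirror
`pedqg.pipeline.RunConfig`; explicit flags win). Exit codes: 0 ok, 1 user
error, 2 internal error.

## Notes

- DIC uses the conditional (lowest-level) likelihood focus; DIC focus
  conventions differ across software, and conditional DIC is known to
  under-penalize added random-effect terms.
- The relationship matrix and mixed-model equations are dense — fine for
  colony-scale pedigrees (hundreds of individuals), not for livestock-scale
  ones.
- Sibship partitioning uses pairwise likelihoods with greedy agglomeration,
  a deterministic simplification of full joint-likelihood sibship
  reconstruction; with few/low-diversity loci it can false-merge a
  chance-similar unrelated pair.
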