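# urbanmicro

Statistical toolkit for **urban-microbiome forensics**: given OTU count
tables from city transit-system swabs, it answers three questions —

1. *Which taxa differ between city-year groups?* Pairwise differential
   abundance screening with four count-regression models that address the
   zero-inflation typical of metagenomic counts — Poisson (P), negative
   binomial (NB), zero-inflated Poisson (ZIP) and zero-inflated negative
   binomial (ZINB) — with library-size offsets `log N_i`,
   Benjamini–Hochberg FDR adjustment, and per-(OTU, pair) model arbitration
   by smallest AIC.
2. *Can a sample's city of origin be predicted?* A stratified 5-fold
   cross-validation harness where NB-based feature selection and the
   quantile-normal + z-score transform run strictly on training folds
   (no leakage), pluggable MLP/KNN/SVC classifiers, and macro-F1 scoring.
3. *How do genus compositions respond to city covariates?* Dirichlet
   regression in the mean/precision parametrization,
   `Y ~ Dirichlet(phi * mu)` with multinomial-logit means

   ```
   mu_1 = exp(X b1)/D,   mu_2 = exp(X b2)/D,   mu_3 = 1/D,
   D = exp(X b1) + exp(X b2) + 1,
   Var(Y_c) = mu_c (1 - mu_c)/(phi + 1)
   ```

   for the clinically relevant triple (*Escherichia*, *Klebsiella*,
   *Enterobacter*) against June temperatures, rainfall, population and
   population density, with Wald inference, ternary-plot coordinates and a
   simulator.

A first-class synthetic-data module generates abundance tables, metadata,
covariates and compositions with planted ground truth, so every estimator
is benchmarked against known effects. Intended users: microbiome/
metagenomics analysts who need a tested, scriptable version of this
selection-classification-regression pipeline. See `docs/methods.md` for the
models, assumptions and numerical details.

## Worked example

Simulate a 4-city table (12 samples per city, 40 OTUs, NB counts) with
three 8-fold-change marker OTUs planted per city, screen it, and classify:

```python
import numpy as np
from urbanmicro import run_pairwise, most_differential, select_top_k, run_cv, ClassifierSpec
from urbanmicro.cv import nb_selector
from urbanmicro.simulate import SimConfig, simulate_abundance

planted = {j: (((f"city{j % 4:02d}", "2016"),), np.log(8)) for j in range(12)}
cfg = SimConfig(n_cities=4, samples_per_group=12, n_otus=40, model="NB",
                dispersion=0.3, planted=planted, seed=13)
table, meta, truth = simulate_abundance(cfg)

result = run_pairwise(table, meta, models=("P", "NB"))
top, summary = select_top_k(result, "NB", k=5)
hits = most_differential(result, alpha=0.05, min_pairs=3)

reports = run_cv(table, meta, [ClassifierSpec("SVC", {"kernel": "linear"}, seed=0)],
                 selector=nb_selector(top_k=5), k=5, seed=5)
```

Output (exactly as printed by this configuration):

```
pairs tested: 6
records: 480
NB top-5 union size: 11  never-selected fraction: 0.725
most-differential (>=3 pairs): ['otu0000', 'otu0001', ...] 12 total
planted:                       ['otu0000', 'otu0001', ...] 12 total
SVC macro-F1 per fold: [1.0, 1.0, 1.0, 1.0, 1.0]  mean 1.000 +/- 0.000
```

All six city pairs are tested for every OTU surviving the both-groups-
nonzero rule (480 = 2 models x 6 pairs x 40 OTUs); the screen recovers
exactly the 12 planted markers and none else, and the in-fold-selected SVC
separates the four cities perfectly — the fixture is separable by
construction.

Dirichlet regression recovers realistic-magnitude covariate effects from
simulated compositions (n = 366 over 16 cities, true precision
`phi = 2.06226`):

```python
from urbanmicro.dirichlet import fit_dirichlet
fit = fit_dirichlet(Y, X, term_names=["intercept", "min_temp", "max_temp",
                                      "rainfall", "total_population",
                                      "population_density"])
print(fit.summary())      # estimate / std_error / z / p_value per term
print(fit.phi)            # 2.0987 on this draw
```

The summary table mirrors the conventional two-block layout (one
coefficient block per non-reference genus plus a precision row); e.g. on
this draw `total_population` for *Escherichia* is estimated 1.340e-04
(truth 1.190e-04, z = 7.4) and `min_temp` for *Klebsiella* -9.1e-02
(truth -7.2e-02, z = -2.5).

A thin CLI wraps the same functions:

```sh
urbanmicro simulate --preset small --seed 7 --out demo/
urbanmicro richness  --abundance demo/abundance.tsv --out demo/
urbanmicro select    --abundance demo/abundance.tsv --metadata demo/metadata.csv \
                     --models P,NB,ZIP,ZINB --min-pairs 3 --out demo/sel
urbanmicro classify  --abundance demo/abundance.tsv --metadata demo/metadata.csv --out demo/cv
urbanmicro dirichlet --compositions demo/compositions.csv --covariates demo/covariates.csv --out demo/dir
```

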